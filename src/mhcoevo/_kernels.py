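"""Compiled inner loops for bitstring window bookkeeping.

The simulator spends almost all of its time deriving 16-bit epitope windows
from antigen bitstrings and testing MHC patterns for membership in them, so
these four small kernels are JIT-compiled with numba.  All window values use
the convention that the first bit of a window is the most significant bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def window_scan(bits: np.ndarray, m: int) -> np.ndarray:
    """Rolling scan of all contiguous m-bit windows of ``bits`` (m <= 16).

    Returns a uint16 array of length ``len(bits) - m + 1`` whose o-th entry
    is the integer value of the window starting at offset o.
    """
    n = bits.size - m + 1
    w = np.empty(n, np.uint16)
    mask = np.uint32((1 << m) - 1)
    v = np.uint32(0)
    for k in range(m):
        v = (v << np.uint32(1)) | np.uint32(bits[k])
    w[0] = np.uint16(v)
    for o in range(1, n):
        v = ((v << np.uint32(1)) & mask) | np.uint32(bits[o + m - 1])
        w[o] = np.uint16(v)
    return w


@njit(cache=False)
def apply_flips(bits: np.ndarray, w: np.ndarray, positions: np.ndarray, m: int) -> None:
    """Flip ``bits`` at ``positions`` and patch the affected windows in place.

    A flip at site p only touches windows with offsets in
    [max(0, p-m+1), min(n_windows-1, p)]; those are recomputed directly.
    """
    n_w = w.size
    for i in range(positions.size):
        bits[positions[i]] ^= np.uint8(1)
    for i in range(positions.size):
        p = positions[i]
        lo = p - m + 1
        if lo < 0:
            lo = 0
        hi = p
        if hi > n_w - 1:
            hi = n_w - 1
        for o in range(lo, hi + 1):
            v = np.uint32(0)
            for k in range(m):
                v = (v << np.uint32(1)) | np.uint32(bits[o + k])
            w[o] = np.uint16(v)


@njit(cache=False)
def presence_from_windows(w: np.ndarray, m: int) -> np.ndarray:
    """Boolean table over the 2^m pattern space: True where a window occurs."""
    pres = np.zeros(1 << m, np.bool_)
    for i in range(w.size):
        pres[w[i]] = True
    return pres


@njit(cache=False)
def any_present(presence: np.ndarray, patterns: np.ndarray) -> bool:
    """True iff any of ``patterns`` is flagged in the presence table."""
    for i in range(patterns.size):
        if presence[patterns[i]]:
            return True
    return False
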