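"""Population summary statistics and post-run analyses.

Definitions:

* INV — individual number of variants: distinct MHC patterns in one host's
  diploid genome (N in the fitness function).
* PNV — population number of variants: distinct MHC patterns across all
  hosts of a population.
* CV of host fitness — population standard deviation of fitness divided by
  its mean; undefined (reported as NaN) when the mean is zero.

Run summaries average the per-generation series over the final
``summary_fraction`` of generations, once the coevolutionary dynamics have
stabilised, and attach the final-snapshot regression of per-host
presented-species count on INV.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.spatial.distance import cdist, pdist

from .genome_types import Antigen, HostGenome


def _genome_of(host) -> HostGenome:
    return host if isinstance(host, HostGenome) else host.genome


@dataclasses.dataclass(frozen=True)
class GenerationStats:
    """Per-generation aggregates of the interacting host population."""

    generation: int
    mean_inv: float
    sd_inv: float
    pnv: int
    mean_fitness: float
    sd_fitness: float
    cv_fitness: float          # NaN when mean fitness is zero
    mean_loci_per_genome: float

    #: CSV column names, in output order
    COLUMNS = (
        "generation",
        "mean_INV",
        "sd_INV",
        "PNV",
        "mean_fitness",
        "sd_fitness",
        "cv_fitness",
        "mean_loci_per_genome",
    )

    def as_row(self) -> tuple:
        return (
            self.generation,
            self.mean_inv,
            self.sd_inv,
            self.pnv,
            self.mean_fitness,
            self.sd_fitness,
            self.cv_fitness,
            self.mean_loci_per_genome,
        )


def stats_frame(records: Sequence[GenerationStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.as_row() for r in records], columns=list(GenerationStats.COLUMNS)
    )


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclasses.dataclass(frozen=True)
class RunSummary:
    """Window-averaged run summary plus the final-snapshot regression."""

    mean_inv: float
    mean_pnv: float
    mean_cv: float
    regression_slope: float
    regression_intercept: float
    regression_r_squared: float
    window: int                      # number of trailing generations averaged
    config: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def individual_variant_counts(hosts: Sequence) -> np.ndarray:
    """Per-host count of distinct MHC patterns (the INV of each individual)."""
    hosts = list(hosts)
    if not hosts:
        raise ValueError("host list must be non-empty")
    return np.array([_genome_of(h).n_unique for h in hosts], dtype=np.int64)


def population_variant_count(hosts: Sequence) -> int:
    """Distinct MHC patterns segregating across the whole population (PNV)."""
    hosts = list(hosts)
    if not hosts:
        raise ValueError("host list must be non-empty")
    return int(
        np.unique(np.concatenate([_genome_of(h).all_genes() for h in hosts])).size
    )


def cv_fitness(fitness: Iterable[float]) -> float:
    """Population-SD/mean coefficient of variation; NaN when the mean is 0."""
    f = np.asarray(list(fitness), dtype=float)
    if f.size == 0:
        raise ValueError("fitness vector must be non-empty")
    mean = f.mean()
    if mean == 0.0:
        return math.nan
    return float(f.std(ddof=0) / mean)


def presentation_regression(snapshot) -> RegressionResult:
    """OLS of presented-species count on INV across final-snapshot hosts.

    ``snapshot`` is either the dict written by the engine (with a ``hosts``
    list carrying ``n_unique`` and ``n_presented``) or a pair of arrays
    (inv, presented).  With fewer than 3 hosts or zero variance in INV the
    slope is undefined and NaN is returned.
    """
    if isinstance(snapshot, dict):
        hosts = snapshot["hosts"]
        inv = np.array([h["n_unique"] for h in hosts], dtype=float)
        presented = np.array([h["n_presented"] for h in hosts], dtype=float)
    else:
        inv, presented = (np.asarray(v, dtype=float) for v in snapshot)
    if inv.size < 3 or np.var(inv) == 0.0:
        return RegressionResult(math.nan, math.nan, math.nan)
    # closed-form simple OLS: slope = cov(x, y) / var(x)
    vx = np.var(inv)
    cov = np.mean((inv - inv.mean()) * (presented - presented.mean()))
    slope = cov / vx
    intercept = presented.mean() - slope * inv.mean()
    vy = np.var(presented)
    r2 = 0.0 if vy == 0.0 else float(cov * cov / (vx * vy))
    return RegressionResult(float(slope), float(intercept), r2)


def antigen_similarity(
    species_a: Sequence[Antigen], species_b: Sequence[Antigen] | None = None
) -> np.ndarray:
    """Pairwise Hamming distances between (or within) antigen sets.

    With one argument, all unordered pairs within the set; with two, all
    cross pairs.  Two independent random bitstrings of length n sit at an
    expected distance of n/2.
    """
    mat_a = np.stack([a.bits for a in species_a]).astype(bool)
    n_sites = mat_a.shape[1]
    if species_b is None:
        if len(species_a) < 2:
            return np.empty(0, dtype=np.int64)
        d = pdist(mat_a, metric="hamming") * n_sites
    else:
        mat_b = np.stack([b.bits for b in species_b]).astype(bool)
        if mat_b.shape[1] != n_sites:
            raise ValueError("antigen sets must share a common length")
        d = cdist(mat_a, mat_b, metric="hamming").ravel() * n_sites
    return np.rint(d).astype(np.int64)


def summarize_run(
    stats: pd.DataFrame,
    snapshot,
    summary_fraction: float,
    config: dict | None = None,
) -> RunSummary:
    """Average the trailing window of the per-generation series.

    The window is the last ``floor(summary_fraction * G)`` generations (at
    least one).  The snapshot regression slope is attached unchanged.
    """
    if not 0.0 < summary_fraction <= 1.0:
        raise ValueError("summary_fraction must lie in (0, 1]")
    n = len(stats)
    if n == 0:
        raise ValueError("empty per-generation series")
    window = max(1, int(math.floor(summary_fraction * n)))
    tail = stats.iloc[-window:]
    reg = (
        presentation_regression(snapshot)
        if snapshot is not None
        else RegressionResult(math.nan, math.nan, math.nan)
    )
    return RunSummary(
        mean_inv=float(tail["mean_INV"].mean()),
        mean_pnv=float(tail["PNV"].mean()),
        mean_cv=float(tail["cv_fitness"].mean()),
        regression_slope=reg.slope,
        regression_intercept=reg.intercept,
        regression_r_squared=reg.r_squared,
        window=window,
        config=config,
    )


_RESPONSE_COLUMNS = {"INV": "mean_INV", "PNV": "mean_PNV", "CV": "mean_CV"}


@dataclasses.dataclass(frozen=True)
class InteractionModelResult:
    """OLS fit of a run summary on alpha, mu_A, S and all their interactions."""

    response: str
    table: pd.DataFrame          # Estimate, SE, t value, P columns per term
    model: object                # statsmodels RegressionResults

    def coefficient(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["Estimate"]), float(row["SE"])


def fit_interaction_model(
    summaries: pd.DataFrame, response: str = "INV"
) -> InteractionModelResult:
    """Linear model of a window-averaged response on the design factors.

    ``summaries`` must carry one row per run with numeric columns ``alpha``,
    ``mu_A`` and ``S`` plus the response column (``mean_INV``, ``mean_PNV``
    or ``mean_CV``).  The model includes main effects and all two- and
    three-way interactions; coefficients are tested with two-sided t-tests.
    """
    if response not in _RESPONSE_COLUMNS:
        raise ValueError(f"response must be one of {sorted(_RESPONSE_COLUMNS)}")
    col = _RESPONSE_COLUMNS[response]
    for factor in ("alpha", "mu_A", "S"):
        if factor not in summaries.columns:
            raise ValueError(f"summaries lack the design column {factor!r}")
        if summaries[factor].nunique() < 2:
            raise ValueError(
                f"design factor {factor!r} has a single level; its main effect "
                "and interactions are confounded with the intercept"
            )
    if col not in summaries.columns:
        raise ValueError(f"summaries lack the response column {col!r}")
    formula = f"Q('{col}') ~ alpha * mu_A * S"
    model = smf.ols(formula, data=summaries)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            "rank-deficient design: the terms "
            f"{list(model.exog_names)} are not jointly estimable with the "
            "provided factor combinations"
        )
    fit = model.fit()
    table = pd.DataFrame(
        {
            "Estimate": fit.params,
            "SE": fit.bse,
            "t value": fit.tvalues,
            "P": fit.pvalues,
        }
    )
    return InteractionModelResult(response=response, table=table, model=fit)
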