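import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mhcoevo.genome_types import Antigen, make_random_antigen
from mhcoevo.stats import (
    antigen_similarity,
    cv_fitness,
    fit_interaction_model,
    individual_variant_counts,
    population_variant_count,
    presentation_regression,
    summarize_run,
)

from conftest import make_genome


class TestVariantCounts:
    def test_monomorphic_population(self):
        hosts = [make_genome([42], [42]) for _ in range(5)]
        assert individual_variant_counts(hosts).tolist() == [1] * 5
        assert population_variant_count(hosts) == 1

    def test_known_mixture(self):
        hosts = [
            make_genome([1], [1]),
            make_genome([1, 2], [2]),
            make_genome([1, 2], [3]),
        ]
        assert individual_variant_counts(hosts).tolist() == [1, 2, 3]
        assert individual_variant_counts(hosts).mean() == 2.0

    def test_disjoint_union(self):
        hosts = [make_genome([1, 2], [2]), make_genome([3], [3])]
        assert population_variant_count(hosts) == 3

    def test_matches_brute_force(self, rng):
        hosts = [
            make_genome(
                rng.integers(0, 30, size=int(rng.integers(1, 6))),
                rng.integers(0, 30, size=int(rng.integers(1, 6))),
            )
            for _ in range(20)
        ]
        counts = individual_variant_counts(hosts)
        brute = [len({int(x) for x in h.all_genes()}) for h in hosts]
        assert counts.tolist() == brute
        union = set()
        for h in hosts:
            union |= {int(x) for x in h.all_genes()}
        pnv = population_variant_count(hosts)
        assert pnv == len(union)
        assert pnv >= counts.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            individual_variant_counts([])
        with pytest.raises(ValueError):
            population_variant_count([])


class TestCVFitness:
    def test_constant_fitness_zero_cv(self):
        assert cv_fitness([3.0, 3.0, 3.0]) == 0.0

    def test_two_point_case(self):
        assert cv_fitness([0.0, 2.0]) == pytest.approx(1.0)

    def test_zero_mean_is_missing(self):
        assert math.isnan(cv_fitness([0.0, 0.0]))

    def test_matches_textbook_formula(self, rng):
        f = rng.gamma(2.0, 1.5, size=200)
        assert cv_fitness(f) == pytest.approx(
            f.std(ddof=0) / f.mean(), abs=1e-14
        )

    def test_scale_invariant(self, rng):
        f = rng.gamma(2.0, 1.5, size=50)
        assert cv_fitness(5.0 * f) == pytest.approx(cv_fitness(f), abs=1e-12)


class TestPresentationRegression:
    def test_perfect_line(self):
        r = presentation_regression(([1, 2, 3], [1, 2, 3]))
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        r = presentation_regression(([1, 2, 3, 4], [5, 5, 5, 5]))
        assert r.slope == pytest.approx(0.0)

    def test_zero_variance_in_inv_is_missing(self):
        r = presentation_regression(([2, 2, 2], [1, 2, 3]))
        assert math.isnan(r.slope)

    def test_matches_independent_least_squares(self, rng):
        inv = rng.integers(1, 12, size=60).astype(float)
        presented = 0.7 * inv + rng.normal(0, 1.0, size=60)
        ours = presentation_regression((inv, presented))
        ref = sps.linregress(inv, presented)
        assert ours.slope == pytest.approx(ref.slope, abs=1e-10)
        assert ours.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert ours.r_squared == pytest.approx(ref.rvalue**2, abs=1e-10)

    def test_snapshot_dict_interface(self):
        snap = {
            "hosts": [
                {"n_unique": 1, "n_presented": 1},
                {"n_unique": 2, "n_presented": 2},
                {"n_unique": 3, "n_presented": 3},
            ]
        }
        assert presentation_regression(snap).slope == pytest.approx(1.0)


class TestAntigenSimilarity:
    def test_identical_antigens(self, rng):
        ag = make_random_antigen(rng, 100)
        assert antigen_similarity([ag], [ag]).tolist() == [0]

    def test_complementary_antigens(self, rng):
        ag = make_random_antigen(rng, 6000)
        comp = Antigen(1 - ag.bits)
        assert antigen_similarity([ag], [comp]).tolist() == [6000]

    def test_random_pairs_near_half_length(self, rng):
        # independent random strings differ at n/2 sites on average
        a = [make_random_antigen(rng, 6000) for _ in range(6)]
        b = [make_random_antigen(rng, 6000) for _ in range(6)]
        d = antigen_similarity(a, b)
        se = math.sqrt(6000 * 0.25 / len(d))
        assert abs(d.mean() - 3000) < 4 * se

    def test_within_set_pair_count(self, rng):
        ags = [make_random_antigen(rng, 64) for _ in range(5)]
        assert len(antigen_similarity(ags)) == 10  # C(5, 2)


def ramp_frame(g):
    return pd.DataFrame(
        {
            "mean_INV": np.arange(g, dtype=float),
            "PNV": np.arange(g, dtype=float),
            "cv_fitness": np.arange(g, dtype=float),
        }
    )


class TestSummarizeRun:
    def test_constant_series(self):
        frame = pd.DataFrame(
            {"mean_INV": [2.0] * 8, "PNV": [5.0] * 8, "cv_fitness": [0.3] * 8}
        )
        s = summarize_run(frame, None, 0.5)
        assert (s.mean_inv, s.mean_pnv, s.mean_cv) == (2.0, 5.0, 0.3)
        assert s.window == 4

    def test_ramp_mean_of_last_quarter(self):
        # generations 0..99, last 25 values are 75..99, mean (75+99)/2 = 87.0
        s = summarize_run(ramp_frame(100), None, 0.25)
        assert s.mean_inv == pytest.approx(87.0)
        assert s.window == 25

    def test_matches_independent_recomputation(self, rng):
        frame = ramp_frame(40)
        frame["mean_INV"] = rng.normal(5, 1, size=40)
        s = summarize_run(frame, None, 0.25)
        assert s.mean_inv == pytest.approx(frame["mean_INV"].iloc[-10:].mean())

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            summarize_run(ramp_frame(0), None, 0.25)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            summarize_run(ramp_frame(10), None, 1.5)


def synthetic_summaries(rng, n, truth):
    """Run summaries from a planted linear truth over the design grid."""
    alpha = rng.choice([0.02, 0.08], size=n)
    mu = rng.choice([1e-5, 5e-5], size=n)
    S = rng.choice([2, 8, 32], size=n).astype(float)
    y = truth(alpha, mu, S) + rng.normal(0, 0.5, size=n)
    return pd.DataFrame(
        {"alpha": alpha, "mu_A": mu, "S": S, "mean_INV": y,
         "mean_PNV": y, "mean_CV": y}
    )


class TestInteractionModel:
    def test_planted_main_effect_recovered_exactly(self, rng):
        df = synthetic_summaries(rng, 100, lambda a, m, s: 1 + 2 * s)
        df["mean_INV"] = 1 + 2 * df["S"]  # noise-free
        result = fit_interaction_model(df, response="INV")
        est, se = result.coefficient("S")
        assert est == pytest.approx(2.0, abs=1e-8)
        for term in result.table.index:
            if term not in ("Intercept", "S"):
                assert result.table.loc[term, "Estimate"] == pytest.approx(
                    0.0, abs=1e-6
                )

    def test_planted_interaction_recovered_within_2_se(self, rng):
        beta = 40.0
        df = synthetic_summaries(rng, 200, lambda a, m, s: 3 + beta * a * s)
        result = fit_interaction_model(df, response="INV")
        est, se = result.coefficient("alpha:S")
        assert abs(est - beta) < 2 * se

    def test_permuted_response_rarely_significant(self, rng):
        df = synthetic_summaries(rng, 200, lambda a, m, s: 3 + 0.5 * s)
        clean = 0
        for _ in range(100):
            shuffled = df.copy()
            shuffled["mean_INV"] = rng.permutation(df["mean_INV"].values)
            result = fit_interaction_model(shuffled, response="INV")
            pvals = result.table.drop(index="Intercept")["P"]
            if (pvals > 0.01).all():
                clean += 1
        assert clean >= 95

    def test_single_level_factor_rejected(self, rng):
        df = synthetic_summaries(rng, 50, lambda a, m, s: s)
        df["alpha"] = 0.02
        with pytest.raises(ValueError, match="alpha"):
            fit_interaction_model(df, response="INV")

    def test_unknown_response_rejected(self, rng):
        df = synthetic_summaries(rng, 50, lambda a, m, s: s)
        with pytest.raises(ValueError):
            fit_interaction_model(df, response="XYZ")
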