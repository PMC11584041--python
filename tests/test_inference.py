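"""Goodness-of-fit tests, acceptance regions, and map fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from trioecy.crosses import CrossType
from trioecy.genetics import INDEPENDENT_MAP, RecombinationMap, SegregationMode
from trioecy.inference import (
    CrossRecord,
    acceptance_region,
    bonferroni_alpha,
    chisq_gof,
    effective_recombination,
    fit_recombination_map,
    multinomial_llr,
    multinomial_llr_test,
)
from trioecy.synthetic import CrossPanelSpec, simulate_cross_panel


class TestChisqGof:
    @pytest.mark.parametrize(
        "counts, probs, expected_chi2",
        [
            # printed worked examples: observed (f, h, Y-carrier) triples
            ((3, 22, 8), (0.25, 0.25, 0.5), 30.6),
            ((3, 22, 8), (0.125, 0.375, 0.5), 12.2),
            ((29, 14, 21), (0.25, 0.25, 0.5), 14.6),
            ((26, 5, 25), (0.25, 0.25, 0.5), 16.4),
        ],
    )
    def test_worked_examples(self, counts, probs, expected_chi2):
        chi2, df = chisq_gof(counts, probs)
        assert chi2 == pytest.approx(expected_chi2, abs=0.05)
        assert df == 2

    def test_perfect_fit_zero(self):
        chi2, df = chisq_gof([10, 10, 20], [0.25, 0.25, 0.5])
        assert chi2 == 0.0
        assert df == 2

    def test_impossible_class_infinite(self):
        chi2, df = chisq_gof([5, 1], [1.0, 0.0])
        assert math.isinf(chi2)
        assert df == 0

    def test_two_class_equals_squared_z(self):
        """For two classes the Pearson statistic is the squared normal
        z-statistic for a proportion (algebraic identity)."""
        counts, p0 = (37, 63), 0.3
        n = sum(counts)
        z = (counts[0] / n - p0) / math.sqrt(p0 * (1 - p0) / n)
        chi2, df = chisq_gof(counts, (p0, 1 - p0))
        assert chi2 == pytest.approx(z**2)
        assert df == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            chisq_gof([1, 2], [0.5, 0.4])  # probs don't sum to 1
        with pytest.raises(ValueError):
            chisq_gof([1], [1.0])  # single class


class TestMultinomialLlr:
    def test_perfect_fit(self):
        llr, p = multinomial_llr_test([5, 5, 10], [0.25, 0.25, 0.5])
        assert llr == 0.0
        assert p == pytest.approx(1.0)

    def test_llr_nonpositive_and_zero_iff_exact(self):
        assert multinomial_llr([8, 8, 16], [0.25, 0.25, 0.5]) == 0.0
        assert multinomial_llr([9, 7, 16], [0.25, 0.25, 0.5]) < 0.0

    def test_zero_probability_class_observed(self):
        llr, p = multinomial_llr_test([3, 1], [1.0, 0.0])
        assert llr == -math.inf
        assert p == 0.0

    def test_flagged_cross_significant(self):
        """The hermaphrodite-excess cross (3:22:8) is firmly rejected
        against the 1:1:2 expectation by the exact test."""
        llr, p = multinomial_llr_test([3, 22, 8], [0.25, 0.25, 0.5])
        assert p < 0.001

    def test_exhaustive_probabilities_sum_to_one(self):
        # p-value of the least extreme outcome is exactly 1
        counts = [2, 2, 4]
        _, p = multinomial_llr_test(counts, [0.25, 0.25, 0.5])
        assert p == pytest.approx(1.0)

    def test_exhaustive_matches_montecarlo(self):
        """Monte-Carlo tail estimate agrees with exact enumeration within
        three binomial standard errors."""
        counts, probs = [0, 2, 4], [0.25, 0.25, 0.5]
        llr, p_exact = multinomial_llr_test(counts, probs, method="exhaustive")
        n_resample = 100_000
        _, p_mc = multinomial_llr_test(
            counts, probs, method="montecarlo", n_resample=n_resample, seed=5
        )
        se = math.sqrt(p_exact * (1 - p_exact) / n_resample)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_montecarlo_reproducible(self):
        out1 = multinomial_llr_test([3, 9, 8], [0.25, 0.25, 0.5],
                                    method="montecarlo", n_resample=2000, seed=42)
        out2 = multinomial_llr_test([3, 9, 8], [0.25, 0.25, 0.5],
                                    method="montecarlo", n_resample=2000, seed=42)
        assert out1 == out2

    def test_exhaustive_guard(self):
        with pytest.raises(ValueError, match="guard"):
            multinomial_llr_test(
                [500] * 4, [0.25] * 4, method="exhaustive", max_outcomes=1000
            )


class TestAcceptanceRegion:
    def test_chisq_symmetric_about_half(self):
        lo, hi = acceptance_region(0.5, 60, alpha=0.05, n_tests=18)
        assert lo + hi == pytest.approx(1.0)
        assert lo < 0.5 < hi

    def test_exact_binomial_stepwise_and_contains_p0(self):
        n = 60
        lo, hi = acceptance_region(0.25, n, alpha=0.05, n_tests=18,
                                   method="exact_binomial")
        assert (lo * n) == pytest.approx(round(lo * n))
        assert (hi * n) == pytest.approx(round(hi * n))
        assert lo <= 0.25 <= hi
        # bounds are exactly the first non-rejected counts
        alpha_c = 0.05 / 18
        k_lo, k_hi = int(round(lo * n)), int(round(hi * n))
        assert stats.binomtest(k_lo, n, 0.25).pvalue >= alpha_c
        if k_lo > 0:
            assert stats.binomtest(k_lo - 1, n, 0.25).pvalue < alpha_c
        assert stats.binomtest(k_hi, n, 0.25).pvalue >= alpha_c
        if k_hi < n:
            assert stats.binomtest(k_hi + 1, n, 0.25).pvalue < alpha_c

    def test_chisq_and_exact_converge_large_n(self):
        lo_c, hi_c = acceptance_region(0.5, 500, 0.05, 1, method="chisq")
        lo_e, hi_e = acceptance_region(0.5, 500, 0.05, 1, method="exact_binomial")
        assert abs(lo_c - lo_e) < 0.01
        assert abs(hi_c - hi_e) < 0.01

    def test_bonferroni(self):
        assert bonferroni_alpha(0.05, 18) == pytest.approx(0.05 / 18)
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 40) == pytest.approx(0.00125)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestEffectiveRecombination:
    def test_fitted_map(self, fitted_map):
        assert effective_recombination(fitted_map) == pytest.approx(0.37)

    def test_complete_linkage(self):
        assert effective_recombination(RecombinationMap(0.0, 0.0)) == 0.0

    def test_matches_parental_gamete_computation(self):
        """r12 + r23 equals 1 - 2 P(parental gamete) from the gamete table."""
        from trioecy.genetics import PlantGenotype, gamete_distribution

        rmap = RecombinationMap(0.2, 0.2)
        g = PlantGenotype.from_string("RXR/rXr;N")
        p_parental = gamete_distribution(g, rmap)[g.hap_a]
        assert effective_recombination(rmap) == pytest.approx(1 - 2 * p_parental)
        assert effective_recombination(rmap) == pytest.approx(0.4)

    def test_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert effective_recombination(RecombinationMap(0.4, 0.3)) == 0.5

    def test_independent_mode_half(self):
        assert effective_recombination(INDEPENDENT_MAP) == 0.5


class TestFitRecombinationMap:
    def test_perfect_fit_cross_attains_zero(self):
        """Counts exactly proportional to a scenario expectation at
        (0.10, 0.20) make that grid point a C_LLR = 0 maximum."""
        # coupling sire at (0.10, 0.20): (0.5, 0, 0.35, 0.15) over 200
        rec = CrossRecord("exact", CrossType.FxM, 100, 0, 70, 30)
        fit = fit_recombination_map([rec], grid_step=0.05)
        i = np.argmin(np.abs(fit.r12_grid - 0.10))
        j = np.argmin(np.abs(fit.r23_grid - 0.20))
        assert fit.c_llr_surface[i, j] == pytest.approx(0.0, abs=1e-12)
        assert fit.c_llr == pytest.approx(0.0, abs=1e-12)

    def test_surface_invariant_to_cross_order(self):
        spec = CrossPanelSpec(n_crosses=8, seed=3)
        recs, _ = simulate_cross_panel(spec)
        fit_fwd = fit_recombination_map(recs, grid_step=0.1)
        fit_rev = fit_recombination_map(recs[::-1], grid_step=0.1)
        assert np.allclose(fit_fwd.c_llr_surface, fit_rev.c_llr_surface)
        assert (fit_fwd.best_r12, fit_fwd.best_r23) == (
            fit_rev.best_r12, fit_rev.best_r23,
        )

    def test_rejects_wrong_cross_type_and_empty(self):
        bad = CrossRecord("h1", CrossType.FxH, 0, 0, 10, 30)
        with pytest.raises(ValueError, match="FxM"):
            fit_recombination_map([bad])
        with pytest.raises(ValueError, match="eligible"):
            fit_recombination_map([])

    def test_small_families_excluded(self):
        small = CrossRecord("tiny", CrossType.FxM, 3, 0, 3, 3)
        with pytest.raises(ValueError, match="eligible"):
            fit_recombination_map([small])

    def test_weight_modes_differ_only_in_combination(self):
        spec = CrossPanelSpec(n_crosses=6, seed=9)
        recs, _ = simulate_cross_panel(spec)
        fits = {
            mode: fit_recombination_map(recs, grid_step=0.1, weight_mode=mode)
            for mode in ("sum", "n_weighted", "mean")
        }
        for fit in fits.values():
            assert fit.c_llr <= 1e-12
        # per-cross best scenarios at a common best map are weight-free
        assert set(fits["sum"].per_cross_best) == {r.cross_id for r in recs}
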