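"""Unit and oracle tests for the inferential layer."""

import itertools

import numpy as np
import pytest

from stopgc.genome_io import GeneRecord
from stopgc.stats import (
    LinearFit,
    LogisticFit,
    bin_by_gc,
    binomial_exceedance,
    compare_slopes,
    count_coefficient_signs,
    fit_linear,
    gc_match,
    logistic_stop_vs_gc,
    spearman,
)
from stopgc.synthetic import sample_logistic_genes


class TestSpearman:
    def test_monotone_increasing(self):
        r = spearman([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert r.rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        r = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_hand_rank_value(self):
        r = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.rho == pytest.approx(0.8)

    def test_constant_input_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 2, 3, 4], [5, 5, 5, 5])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestFitLinear:
    def test_exact_line(self):
        x = [0.0, 1.0, 2.0, 3.0]
        fit = fit_linear(x, [2 * v + 1 for v in x])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_zero_slope(self):
        fit = fit_linear([0, 1, 2], [7, 7, 7])
        assert fit.slope == pytest.approx(0.0)

    def test_hand_ols(self):
        fit = fit_linear([0, 1, 2], [0, 0, 3])
        assert fit.slope == pytest.approx(1.5)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant x"):
            fit_linear([1, 1, 1], [0, 1, 2])

    def test_ci_covers_slope(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        fit = fit_linear(x, 3 * x + rng.normal(0, 0.1, 50))
        lo, hi = fit.ci()
        assert lo < 3 < hi


class TestCompareSlopes:
    def test_identical_fits(self):
        fit = fit_linear([0, 1, 2, 3], [0.1, 1.2, 1.9, 3.1])
        cmp = compare_slopes(fit, fit)
        assert cmp.z == 0.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_closed_form_z(self):
        a = LinearFit(slope=0.012, intercept=0, slope_se=0.001, n=100)
        b = LinearFit(slope=0.000, intercept=0, slope_se=0.001, n=100)
        cmp = compare_slopes(a, b)
        assert cmp.z == pytest.approx(0.012 / np.sqrt(2e-6), rel=1e-9)
        assert cmp.z == pytest.approx(8.485, abs=1e-3)

    def test_antisymmetry(self):
        a = LinearFit(0.01, 0, 0.002, 50)
        b = LinearFit(0.03, 0, 0.004, 50)
        assert compare_slopes(a, b).z == pytest.approx(-compare_slopes(b, a).z)
        assert compare_slopes(a, b).p_value == pytest.approx(
            compare_slopes(b, a).p_value
        )

    def test_zero_pooled_se_errors(self):
        a = LinearFit(1.0, 0, 0.0, 10)
        with pytest.raises(ValueError):
            compare_slopes(a, a)


class TestLogistic:
    def test_null_effect_within_2_se(self):
        records = sample_logistic_genes(2000, beta=0.0, seed=42)
        fit = logistic_stop_vs_gc(records, "TAA")
        assert fit.converged
        # beta=0: estimate should be within a few SE of zero; 2 SE at the
        # fitted scale corresponds to |coef| < ~1 here
        se_scale = 2 / (0.09 * np.sqrt(2000 * 0.25))
        assert abs(fit.coefficient) < 2 * se_scale

    def test_recovers_generator_beta(self):
        records = sample_logistic_genes(2000, beta=8.0, seed=43)
        fit = logistic_stop_vs_gc(records, "TAA")
        assert fit.converged
        assert fit.coefficient == pytest.approx(8.0, abs=2.0)
        assert fit.p_value < 1e-6

    def test_one_class_outcome_not_converged(self):
        records = [
            GeneRecord(f"g{i}", "ATGAAATAA", "TAA", utr3_gc=0.3 + 0.001 * i)
            for i in range(100)
        ]
        fit = logistic_stop_vs_gc(records, "TAA")
        assert not fit.converged
        assert fit.coefficient is None

    def test_too_few_genes_not_converged(self):
        records = sample_logistic_genes(20, beta=0.0, seed=1)
        assert not logistic_stop_vs_gc(records, "TAA").converged


class TestSignCounts:
    def test_hand_counts(self):
        fits = [
            LogisticFit("TAA", -1.0, 0.01, True, 100),
            LogisticFit("TAA", -2.0, 0.20, True, 100),
            LogisticFit("TAA", +1.0, 0.01, True, 100),
        ]
        sc = count_coefficient_signs(fits)["TAA"]
        assert (sc.negative, sc.negative_significant) == (2, 1)
        assert (sc.positive, sc.positive_significant) == (1, 1)

    def test_empty_input(self):
        assert count_coefficient_signs([]) == {}

    def test_non_converged_excluded(self):
        fits = [LogisticFit("TGA", None, None, False, 10)] * 3
        sc = count_coefficient_signs(fits)["TGA"]
        assert sc.n_excluded == 3
        assert sc.negative == sc.positive == 0

    def test_totals_bounded_by_converged(self):
        rng = np.random.default_rng(5)
        fits = [
            LogisticFit(
                "TAA",
                float(rng.normal()),
                float(rng.random()),
                bool(rng.random() < 0.8),
                100,
            )
            for _ in range(50)
        ]
        fits = [
            f if f.converged else LogisticFit("TAA", None, None, False, 100)
            for f in fits
        ]
        sc = count_coefficient_signs(fits)["TAA"]
        assert sc.negative + sc.positive <= sc.n_converged
        assert sc.negative_significant <= sc.negative
        assert sc.positive_significant <= sc.positive


class TestBinomial:
    def test_all_successes(self):
        assert binomial_exceedance(10, 10, 0.5, "greater") == pytest.approx(
            0.5**10
        )

    def test_no_successes(self):
        assert binomial_exceedance(0, 10, 0.5, "greater") == pytest.approx(1.0)

    def test_exact_tail_sum(self):
        assert binomial_exceedance(5, 10, 0.5, "greater") == pytest.approx(
            0.623046875
        )

    def test_two_sided(self):
        assert binomial_exceedance(5, 10, 0.5, "two_sided") == pytest.approx(1.0)


def gene(gc, stop="TAA"):
    return GeneRecord("g", "ATGAAA" + stop, stop, utr3_gc=gc)


class TestBinByGC:
    def test_even_split(self):
        records = [gene(i / 20) for i in range(20)]
        binned = bin_by_gc(records, n_bins=10)
        assert list(binned.table["n_genes"]) == [2] * 10

    def test_remainder_goes_to_lowest_bins(self):
        records = [gene(i / 21) for i in range(21)]
        binned = bin_by_gc(records, n_bins=10)
        assert list(binned.table["n_genes"]) == [3] + [2] * 9

    def test_bins_ordered_by_gc(self):
        rng = np.random.default_rng(2)
        records = [gene(float(g)) for g in rng.random(57)]
        tbl = bin_by_gc(records, n_bins=10).table
        assert tbl["mean_gc"].is_monotonic_increasing

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            bin_by_gc([gene(0.5)] * 5, n_bins=10)

    def test_per_bin_freqs(self):
        records = [gene(0.1, "TAA"), gene(0.2, "TAA"), gene(0.8, "TGA"), gene(0.9, "TGA")]
        tbl = bin_by_gc(records, n_bins=2).table
        assert tbl.loc[0, "f_TAA"] == 1.0
        assert tbl.loc[1, "f_TGA"] == 1.0


class TestGCMatch:
    def test_nearest(self):
        pairing = gc_match({"q": 0.40}, {"a": 0.30, "b": 0.41, "c": 0.60})
        assert pairing.pairs == [("q", "b", pytest.approx(0.01))]

    def test_with_replacement(self):
        pairing = gc_match({"q1": 0.40, "q2": 0.42}, {"only": 0.41})
        assert pairing.matched_candidates == ["only", "only"]

    def test_exact_match_zero_delta(self):
        pairing = gc_match({"q": 0.5}, {"a": 0.5, "b": 0.6})
        assert pairing.pairs[0][2] == 0.0

    def test_tie_breaks_lexicographically(self):
        pairing = gc_match({"q": 0.5}, {"zzz": 0.49, "aaa": 0.51})
        assert pairing.matched_candidates == ["aaa"]

    def test_pairing_size_equals_query_panel(self):
        queries = {f"q{i}": 0.3 + i / 100 for i in range(7)}
        pairing = gc_match(queries, {"a": 0.1, "b": 0.9})
        assert len(pairing.pairs) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_optimal_against_brute_force(self, seed):
        """NN-with-replacement minimises mean |dGC| over all assignments."""
        rng = np.random.default_rng(seed)
        queries = {f"q{i}": float(g) for i, g in enumerate(rng.random(4))}
        candidates = {f"c{i}": float(g) for i, g in enumerate(rng.random(4))}
        pairing = gc_match(queries, candidates)
        cand_ids = sorted(candidates)
        best = min(
            np.mean(
                [
                    abs(candidates[c] - queries[q])
                    for q, c in zip(sorted(queries), assignment)
                ]
            )
            for assignment in itertools.product(cand_ids, repeat=len(queries))
        )
        assert pairing.mean_abs_delta == pytest.approx(float(best))
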