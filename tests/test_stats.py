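
import numpy as np
import pytest

from palscore.stats import (ContingencyTable, bootstrap_ci, fisher_exact,
                            hodges_lehmann, lin_ccc, lin_ccc_with_ci,
                            median_iqr, proportion_difference,
                            wilcoxon_rank_sum)

from _oracle import oracle_fisher_2x2


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ([[1, 13], [7, 6]], 0.013),
        ([[0, 14], [2, 11]], 0.222),
        ([[10, 4], [13, 0]], 0.098),
        ([[10, 4], [7, 6]], 0.440),
    ])
    def test_two_by_two_reference_values(self, table, expected):
        assert fisher_exact(table).p_value == pytest.approx(expected,
                                                            abs=5e-4)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == 1.0

    @pytest.mark.parametrize("table,expected", [
        ([[13, 10], [12, 14], [16, 14]], 0.7825),         # 3x2
        ([[16, 14], [10, 13], [12, 8], [3, 3]], 0.7504),  # 4x2
    ])
    def test_rxtwo_enumeration(self, table, expected):
        assert fisher_exact(table).p_value == pytest.approx(expected,
                                                            abs=1e-4)

    def test_zero_margin_convention(self):
        res = fisher_exact([[0, 0], [3, 4]])
        assert res.p_value == 1.0
        assert "degenerate" in res.method

    def test_row_and_column_label_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 12, size=(3, 2))
            p = fisher_exact(t).p_value
            assert fisher_exact(t[::-1]).p_value == pytest.approx(p, rel=1e-12)
            assert fisher_exact(t[:, ::-1]).p_value == pytest.approx(
                p, rel=1e-12)
            assert 0 < p <= 1

    def test_matches_hypergeometric_oracle_exhaustively(self):
        # every 2x2 margin with N <= 25, one observed cell per margin
        # (the full N <= 40 sweep runs in the acceptance suite)
        for N in range(2, 26):
            for r1 in range(1, N):
                for c1 in range(1, N):
                    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
                    a = lo + (r1 * 7 + c1 * 3) % (hi - lo + 1)
                    b, c, d = r1 - a, c1 - a, (N - r1) - (c1 - a)
                    p = fisher_exact([[a, b], [c, d]]).p_value
                    assert p == pytest.approx(
                        oracle_fisher_2x2(a, b, c, d), rel=1e-9), (a, b, c, d)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="guard"):
            fisher_exact([[300, 300], [300, 300]])

    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable(((1,),))
        with pytest.raises(ValueError):
            ContingencyTable(((1, -2), (3, 4)))


class TestProportionDifference:
    @pytest.mark.parametrize("k1,n1,k2,n2,expected", [
        (1, 14, 7, 13, 46.7),
        (10, 14, 13, 13, 28.6),
    ])
    def test_reference_estimates(self, k1, n1, k2, n2, expected):
        res = proportion_difference(k1, n1, k2, n2)
        assert res.estimate == pytest.approx(expected, abs=0.05)

    def test_equal_proportions_zero(self):
        assert proportion_difference(3, 10, 6, 20).estimate == 0.0

    @pytest.mark.parametrize("method", ["wald", "newcombe"])
    def test_ci_brackets_estimate(self, method):
        res = proportion_difference(2, 14, 9, 13, method=method)
        assert res.ci_low <= res.estimate <= res.ci_high
        assert method in res.method

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_difference(1, 0, 1, 2)
        with pytest.raises(ValueError):
            proportion_difference(5, 4, 1, 2)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3, 3], [1, 2, 3, 3])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [10, 11])
        assert res.p_value == pytest.approx(1 / 3, rel=1e-12)
        assert "exact" in res.method

    def test_tie_path_uses_normal_approximation(self):
        res = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert "normal" in res.method

    def test_power_on_shifted_lognormals(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            x = rng.lognormal(0.0, 0.5, 30)
            y = rng.lognormal(1.0, 0.5, 30)
            if wilcoxon_rank_sum(x, y).p_value < 0.05:
                hits += 1
        assert hits >= 36   # strong shift detected nearly always


class TestHodgesLehmann:
    def test_identical_samples_zero(self):
        x = [3, 1, 4, 1, 5]
        assert hodges_lehmann(x, x).estimate == 0.0

    def test_small_example_bruteforce_value(self):
        res = hodges_lehmann([1, 2, 3], [4, 5, 7])
        assert res.estimate == 3.0
        assert res.ci_low <= 3.0 <= res.ci_high

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        assert hodges_lehmann(x, x + 2.5).estimate == pytest.approx(2.5)

    def test_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            m, n = rng.integers(2, 31, size=2)
            x = rng.normal(0, 2, m)
            y = rng.normal(1, 2, n)
            est = hodges_lehmann(x, y).estimate
            brute = float(np.median([b - a for a in x for b in y]))
            assert est == pytest.approx(brute, rel=1e-12)

    def test_ci_has_nominal_small_sample_coverage(self):
        # exact inversion CI should cover the true shift ~95% of the time
        rng = np.random.default_rng(21)
        cover = 0
        for _ in range(300):
            x = rng.normal(0, 1, 10)
            y = rng.normal(1, 1, 10)
            r = hodges_lehmann(x, y)
            cover += r.ci_low <= 1.0 <= r.ci_high
        assert 0.90 <= cover / 300 <= 0.995


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2, 3, 5])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_bounded_by_pearson(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(size=15)
            y = 0.5 * x + rng.normal(scale=rng.uniform(0.1, 2), size=15) \
                + rng.uniform(-2, 2)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12

    def test_equals_pearson_under_matched_moments(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        assert lin_ccc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1],
                                              abs=1e-12)

    def test_constant_pairs_undefined(self):
        with pytest.raises(ValueError):
            lin_ccc([2, 2, 2], [2, 2, 2])


class TestBootstrap:
    def test_constant_sample_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda a: float(np.mean(a)),
                              (np.full(10, 3.5),), seed=0)
        assert lo == hi == 3.5

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=27)
        y = x + rng.normal(scale=0.1, size=27)
        a = bootstrap_ci(lin_ccc, (x, y), seed=42)
        b = bootstrap_ci(lin_ccc, (x, y), seed=42)
        assert a == b

    def test_ci_contains_plugin_ccc_and_is_seed_stable(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=27)
        y = x + rng.normal(scale=0.1, size=27)
        est = lin_ccc(x, y)
        r1 = lin_ccc_with_ci(x, y, seed=1)
        r2 = lin_ccc_with_ci(x, y, seed=2)
        assert r1.ci_low <= est <= r1.ci_high
        assert abs(r1.ci_low - r2.ci_low) < 0.05
        assert abs(r1.ci_high - r2.ci_high) < 0.05

    def test_failure_fraction_guard(self):
        def bad(a):
            raise ValueError("always undefined")
        with pytest.raises(ValueError, match="resamples"):
            bootstrap_ci(bad, (np.arange(5.0),), n_resamples=200, seed=0)


class TestMedianIQR:
    @pytest.mark.parametrize("x,expected", [
        ([7], (7, 7, 7)),
        (list(range(1, 10)), (5, 3, 7)),
        ([6, 6, 7, 7, 7, 8, 8], (7, 6, 8)),
    ])
    def test_quantile_rule(self, x, expected):
        m, q1, q3 = median_iqr(x)
        assert (m, q1, q3) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])
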