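from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from calseize.stats import (
    label_significance,
    negbin_count_model,
    normality_gate,
    rank_sum_test,
)


def enumerate_rank_sum_p(a, b):
    """Brute-force exact two-sided Mann-Whitney p by enumerating every
    assignment of the pooled sample into two groups of the given sizes."""
    a, b = list(a), list(b)
    pooled = a + b
    n, m = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    idx = range(n + m)
    for picked in combinations(idx, n):
        ga = [pooled[i] for i in picked]
        gb = [pooled[i] for i in idx if i not in picked]
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    total = comb(n + m, n)
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return min(p, 1.0)


class TestRankSum:
    def test_fully_separated_small_groups_exact_p(self):
        res = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1)
        assert res.test == "rank_sum"
        assert res.effect == pytest.approx(9.0)  # median difference

    @pytest.mark.parametrize("sizes", [(3, 3), (2, 5), (4, 6), (8, 8), (5, 8)])
    def test_matches_enumeration_for_tie_free_small_samples(self, sizes, rng):
        n, m = sizes
        for _ in range(10):
            pooled = rng.permutation(rng.uniform(0, 100, n + m))  # tie-free
            a, b = pooled[:n], pooled[n:]
            res = rank_sum_test(a, b)
            assert res.p_value == pytest.approx(enumerate_rank_sum_p(a, b), abs=1e-12)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        r1, r2 = rank_sum_test(a, b), rank_sum_test(a + 100.0, b + 100.0)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_identical_groups_give_maximal_p(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.significance_label == "ns"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestNormalityGate:
    def test_detects_heavy_tails_with_high_power(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            normality_gate({"g": rng.standard_cauchy(50)})["g"]["p"] < 0.05
            for _ in range(100)
        )
        assert rejections >= 90

    def test_null_rejection_rate_is_calibrated(self):
        # under normal data the test should reject near its nominal level
        rng = np.random.default_rng(11)
        ps = np.array(
            [normality_gate({"g": rng.normal(0, 1, 100)})["g"]["p"] for _ in range(200)]
        )
        assert 0.01 <= np.mean(ps < 0.05) <= 0.12
        ks = sps.kstest(ps, "uniform")
        assert ks.statistic < 0.2  # close to uniform, allowing approximation error

    def test_constant_sample_flagged_degenerate(self):
        out = normality_gate({"g": [3.0, 3.0, 3.0, 3.0]})
        assert out["g"]["degenerate"]

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate({"g": [1.0, 2.0]})


class TestNegbinCountModel:
    def test_identical_groups_give_unit_rate_ratio(self):
        counts = [3, 5, 8, 2, 7, 3, 5, 8, 2, 7]
        labels = ["a"] * 5 + ["b"] * 5
        res = negbin_count_model(counts, labels)
        assert res.effect == pytest.approx(1.0, abs=1e-4)
        assert res.test == "negbin_glm"

    def test_recovers_a_twofold_rate_difference(self):
        rng = np.random.default_rng(3)
        # gamma-Poisson with dispersion 1: means 4 and 8
        y_a = rng.poisson(rng.gamma(1.0, 4.0, 30))
        y_b = rng.poisson(rng.gamma(1.0, 8.0, 30))
        res = negbin_count_model(
            np.concatenate([y_a, y_b]), ["a"] * 30 + ["b"] * 30
        )
        assert 1.2 < res.effect < 3.3
        assert res.group_labels == ("a", "b")

    def test_poisson_data_without_overdispersion_does_not_crash(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([rng.poisson(4, 25), rng.poisson(8, 25)])
        res = negbin_count_model(y, ["a"] * 25 + ["b"] * 25)
        assert 1.4 < res.effect < 2.9
        assert 0.0 <= res.p_value <= 1.0

    def test_wald_and_lrt_p_values_agree_in_order_of_magnitude(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.poisson(rng.gamma(1, 3, 30)),
                            rng.poisson(rng.gamma(1, 9, 30))])
        labels = ["a"] * 30 + ["b"] * 30
        pw = negbin_count_model(y, labels, p_method="wald").p_value
        pl = negbin_count_model(y, labels, p_method="lrt").p_value
        assert (pw < 0.05) == (pl < 0.05)

    def test_all_zero_group_flagged_unstable(self):
        res = negbin_count_model([0, 0, 0, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert any("all-zero" in w for w in res.warnings)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            negbin_count_model([1.5, 2.0], ["a", "b"])

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            negbin_count_model([1, 2, 3], ["a", "b", "c"])


class TestSignificanceLabels:
    @pytest.mark.parametrize(
        "p,label", [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.05, "ns"), (0.5, "ns")]
    )
    def test_threshold_mapping(self, p, label):
        assert label_significance(p) == label

    def test_monotone_in_p(self, rng):
        order = {"***": 0, "**": 1, "*": 2, "ns": 3}
        ps = np.sort(rng.uniform(0, 1, 50))
        labels = [order[label_significance(p)] for p in ps]
        assert labels == sorted(labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_significance(1.5)
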