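import itertools
import math

import numpy as np
import pytest
from scipy import special

from combmetrics.stats import (
    ComparisonResult, StatsError, orientation_ratio, rank_sum_test,
    signed_rank_test, spearman, t_test_unpaired, unwrap_orientation_pairs,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def t_oracle(x, y, variant):
    """Textbook t statistic, df and two-tailed p from explicit formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        se2 = v1 / n1 + v2 / n2
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * special.stdtr(df, -abs(t))
    return t, df, p


def rank_sum_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    U is the Mann-Whitney count of (x, y) pairs with x > y; the null
    distribution comes from enumerating every way to split the pooled
    sample into groups of the observed sizes.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b) + \
            0.5 * sum(1.0 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        in_x = set(comb)
        xs = [pooled[i] for i in in_x]
        ys = [pooled[i] for i in idx if i not in in_x]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(cdf, sf))


def average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


class TestTTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = t_test_unpaired(x, x, "pooled")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_tiny_p(self):
        x = [1.0, 2.0, 3.0]
        y = [1001.0, 1002.0, 1003.0]
        assert t_test_unpaired(x, y).p_value < 1e-6

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_hand_computed_5v5_oracle(self, variant):
        x = [1.2, 2.3, 3.1, 4.8, 5.0]
        y = [2.0, 2.9, 3.5, 4.1, 6.2]
        t, df, p = t_oracle(x, y, variant)
        res = t_test_unpaired(x, y, variant)
        assert res.statistic == pytest.approx(t, abs=1e-9)
        assert res.extras["df"] == pytest.approx(df, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(StatsError, match="zero variance"):
            t_test_unpaired([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(StatsError):
            t_test_unpaired([1.0, 2.0], [3.0, 4.0], "bayes")

    def test_null_rejection_rate_calibrated(self, rng):
        # same-distribution groups: rejection at alpha=0.05 within the 99%
        # binomial interval over 1000 repetitions
        reps, n, alpha = 1000, 15, 0.05
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        from scipy.stats import ttest_ind

        p = ttest_ind(x, y, axis=1).pvalue
        rate = np.mean(p < alpha)
        half = 2.576 * math.sqrt(alpha * (1 - alpha) / reps)
        assert alpha - half <= rate <= alpha + half


class TestRankSum:
    def test_extreme_ordering_gives_zero_u(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0])
        assert res.statistic == 0.0

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (5, 6, 3)])
    def test_exact_branch_matches_enumeration(self, n1, n2, seed):
        g = np.random.default_rng(seed)
        x = np.round(g.uniform(0, 100, n1), 3)
        y = np.round(g.uniform(0, 100, n2), 3)
        u, p = rank_sum_oracle(x, y)
        res = rank_sum_test(x, y)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_p_uniform_over_permutations_3v3(self):
        # splitting 6 fixed distinct values every possible way, the exact
        # two-sided p-values must be uniform at their achievable levels
        values = [3.0, 1.4, 7.7, 0.2, 9.9, 5.5]
        ps = []
        for comb in itertools.combinations(range(6), 3):
            x = [values[i] for i in comb]
            y = [values[i] for i in range(6) if i not in comb]
            ps.append(rank_sum_test(x, y).p_value)
        ps = np.asarray(ps)
        for level in np.unique(ps):
            assert np.mean(ps <= level) == pytest.approx(level)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_paired_shift_detected(self):
        x = np.arange(1.0, 16.0)
        res = signed_rank_test(x + 3.0, x)
        assert res.p_value < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            signed_rank_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_all_zero_differences_rejected(self):
        with pytest.raises(StatsError):
            signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSpearman:
    def test_monotone_pairs(self):
        r, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_reversed_order(self):
        r, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_definitional_pearson_on_ranks(self, rng):
        x = rng.uniform(0, 100, 30)
        y = np.round(rng.uniform(0, 10, 30), 0)  # ties present
        rx, ry = average_ranks(x), average_ranks(y)
        expect = float(np.corrcoef(rx, ry)[0, 1])
        r, _ = spearman(x, y)
        assert r == pytest.approx(expect, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOrientationRatio:
    def test_identity(self):
        pred = [10.0, 50.0, 120.0, 170.0]
        assert orientation_ratio(pred, pred) == pytest.approx(1.0)

    def test_half_slope_no_wrap(self):
        pred = [10.0, 40.0, 80.0]
        built = [5.0, 20.0, 40.0]
        assert orientation_ratio(built, pred) == pytest.approx(0.5)

    def test_wrap_invariance(self):
        # built orientations just across the 180-deg seam from predicted
        pred = [178.0, 179.0, 177.5, 100.0]
        built = [1.0, 0.5, 2.0, 101.0]
        b, t = unwrap_orientation_pairs(built, pred)
        assert np.all(np.abs(b - t) <= 90.0)
        assert orientation_ratio(built, pred) == pytest.approx(1.0, abs=0.02)

    def test_representation_invariance(self, rng):
        pred = rng.uniform(0, 180, 40)
        built = (pred + rng.normal(0, 2, 40)) % 180.0
        r1 = orientation_ratio(built, pred)
        r2 = orientation_ratio(built + 180.0, pred)  # same undirected walls
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert r1 == pytest.approx(1.0, abs=0.05)

    def test_all_zero_predicted_rejected(self):
        with pytest.raises(StatsError):
            orientation_ratio([1.0, 2.0], [0.0, 0.0])


class TestComparisonResult:
    def test_summary_mentions_groups_and_test(self):
        res = ComparisonResult("exp", "metric_x", 10, 12, 1.0, 0.5, 2.0, 0.6,
                               "rank-sum", 33.0, 0.04, extras={"note": "ok"})
        s = res.summary()
        assert "n=10" in s and "n=12" in s and "rank-sum" in s and "note" in s

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            ComparisonResult("e", "m", 2, 2, 0, 0, 0, 0, "t", 0.0, 1.5)
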