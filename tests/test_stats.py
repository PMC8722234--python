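"""Statistics layer: Shapiro screening, correlation, rank tests, log-rank."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from fetadc import SurvivalStratification, km_logrank, pearson_r, rank_test, shapiro_screen
from fetadc.errors import ValidationError
from fetadc.stats import split_by_rule


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p via the Mann–Whitney U pair-count statistic.

    Independent of the implementation under test: enumerates assignments of
    the pooled sample and counts (a > b) pairs with half-credit for ties.
    """

    def u_stat(x, y):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y)

    pooled = list(a) + list(b)
    na = len(a)
    u_obs = u_stat(a, b)
    le = ge = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(le, ge) / total)


def life_table_logrank(times, events, groups):
    """Hand life-table log-rank chi-square (two groups, 1 df)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert labels.size == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestShapiroScreen:
    def test_normal_samples_pass_screen(self):
        """>= 95% of seeded normal samples (n=50) are not rejected at alpha 0.05."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            hits += bool(shapiro_screen({"m": x}).loc["m", "normal"])
        assert hits >= 95

    def test_skewed_samples_fail_screen(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=50)
            hits += not shapiro_screen({"m": x}).loc["m", "normal"]
        assert hits >= 95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            shapiro_screen({"m": np.ones(10)})

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_screen({"m": [1.0, 2.0]})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, n = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r(3.2 * x + 5, 0.7 * y - 2)
        assert r1 == pytest.approx(r0)

    def test_listwise_deletion(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        r, n = pearson_r(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="complete pairs"):
            pearson_r([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRankTest:
    def test_identical_groups_p_one(self):
        comp = rank_test([1, 2, 3], [1, 2, 3])
        assert comp.test == "rank_sum_exact"
        assert comp.p_value == 1.0

    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p = 2/C(6,3) = 0.1."""
        comp = rank_test([1, 2, 3], [4, 5, 6])
        assert comp.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # small integer-valued samples, so ties occur frequently
        a = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(2, 6)).astype(float)
        comp = rank_test(a, b)
        assert comp.test == "rank_sum_exact"
        assert comp.p_value == pytest.approx(mwu_enumeration_oracle(a, b))

    def test_matches_scipy_exact_when_tie_free(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        comp = rank_test(a, b)
        sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert comp.p_value == pytest.approx(float(sp.pvalue))

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        comp = rank_test(a, b)
        assert comp.test == "rank_sum_normal"
        assert 0.0 <= comp.p_value <= 1.0

    def test_signed_rank_paired(self, rng):
        x = rng.normal(size=12)
        comp = rank_test(x, x + 2.0, mode="signed_rank")
        assert comp.test == "signed_rank"
        assert comp.p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_test([], [1.0, 2.0])

    def test_fixture_doubling_split_frozen_value(self):
        """The cohort's doubling-split ΔADC% contrast: exact p = 0.0023."""
        from fetadc.reproduce import doubling_comparison, load_fixture

        comp = doubling_comparison(load_fixture())
        assert comp.test == "rank_sum_exact"
        assert comp.p_value == pytest.approx(0.002331002331, abs=1e-9)
        assert comp.p_value == pytest.approx(
            mwu_enumeration_oracle(comp.group_values[0], comp.group_values[1])
        )


class TestSurvival:
    def test_identical_groups_statistic_zero(self):
        t = (5.0, 8.0, 12.0, 5.0, 8.0, 12.0)
        e = (1, 1, 1, 1, 1, 1)
        g = ("a", "a", "a", "b", "b", "b")
        res = km_logrank(SurvivalStratification(t, e, g))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_life_table_oracle(self):
        t = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        e = (1, 1, 1, 1, 1, 1)
        g = ("a", "a", "a", "b", "b", "b")
        res = km_logrank(SurvivalStratification(t, e, g))
        assert res["statistic"] == pytest.approx(life_table_logrank(t, e, g))

    def test_oracle_with_censoring(self, rng):
        t = rng.exponential(10.0, size=16).round(2) + 0.01
        e = rng.integers(0, 2, size=16)
        if e.sum() == 0:
            e[0] = 1
        g = np.array(["a"] * 8 + ["b"] * 8)
        res = km_logrank(SurvivalStratification(tuple(t), tuple(e), tuple(g)))
        assert res["statistic"] == pytest.approx(life_table_logrank(t, e, g))

    def test_time_rescaling_invariance(self):
        t = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
        e = (1, 1, 0, 1, 1, 1)
        g = ("a", "a", "a", "b", "b", "b")
        r1 = km_logrank(SurvivalStratification(t, e, g))
        r2 = km_logrank(SurvivalStratification(tuple(30 * x for x in t), e, g))
        assert r1["statistic"] == pytest.approx(r2["statistic"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_power_under_hazard_ratio_three(self):
        """Exponential arms with hazard ratio 3, n=100/arm: rejection rate
        at alpha 0.05 exceeds 80% over 200 replicates."""
        rejections = 0
        n = 100
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, size=n)
            tb = rng.exponential(3.0, size=n)
            t = np.concatenate([ta, tb]) + 1e-9
            e = np.ones(2 * n, dtype=int)
            g = np.array(["a"] * n + ["b"] * n)
            res = km_logrank(SurvivalStratification(tuple(t), tuple(e), tuple(g)))
            rejections += res["p"] < 0.05
        assert rejections / 200 > 0.80

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalStratification((1.0, 2.0), (1, 1), ("a", "a"))

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalStratification((1.0, 2.0), (0, 0), ("a", "b"))

    def test_split_rules(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        assert list(split_by_rule(vals, "median")) == ["low", "low", "high", "high"]
        assert list(split_by_rule(vals, "threshold:25")) == ["low", "low", "high", "high"]
        flags = [True, False, True, False]
        assert list(split_by_rule(vals, "doubling", doubling_flags=flags)) == [
            "doubled", "not_doubled", "doubled", "not_doubled",
        ]
        with pytest.raises(ValidationError):
            split_by_rule(vals, "nope")
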