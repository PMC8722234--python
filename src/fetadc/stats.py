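"""Cohort statistics: normality screening, correlation, rank tests, survival.

The analysis plan is deliberately small-sample: Shapiro–Wilk screening at
alpha = 0.05 decides parametric vs non-parametric branches; two-group
contrasts use the exact-permutation Wilcoxon rank-sum (Mann–Whitney) with
midranked ties whenever the combined sample is small enough to enumerate,
falling back to the tie-corrected normal approximation otherwise; paired
contrasts use the signed-rank test; overall-survival stratifications are
compared with Kaplan–Meier curves and the log-rank test.

The exact rank-sum enumerates every assignment of the pooled observations
to the two groups (C(n, n_a) combinations), computes the rank-sum of the
first group under midranks, and reports the two-sided p as
``min(1, 2 * min(P(W <= w), P(W >= w)))`` — the convention that yields
p = 0.1 for {1,2,3} vs {4,5,6} and p = 1 for identical groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ALPHA = 0.05

#: largest combined sample for which the rank-sum null is enumerated exactly
EXACT_RANKSUM_MAX_N = 20


# ---------------------------------------------------------------------------
# normality screening


def shapiro_screen(samples: dict, alpha: float = ALPHA) -> pd.DataFrame:
    """Shapiro–Wilk screen per metric.

    Parameters
    ----------
    samples : dict mapping metric name -> 1D array-like (no missing values)

    Returns a DataFrame indexed by metric with columns ``W``, ``p`` and
    ``normal`` (True when p >= alpha, i.e. normality is not rejected).
    """
    rows = {}
    for name, values in samples.items():
        x = np.asarray(values, dtype=float)
        if x.ndim != 1 or x.size < 3:
            raise ValidationError(f"{name}: Shapiro–Wilk needs >= 3 one-dimensional values")
        if np.any(np.isnan(x)):
            raise ValidationError(f"{name}: missing values must be removed first")
        if np.ptp(x) == 0:
            raise ValidationError(f"{name}: constant sample, W undefined")
        w, p = sps.shapiro(x)
        rows[name] = {"W": float(w), "p": float(p), "normal": bool(p >= alpha)}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# correlation


def pearson_r(x, y) -> tuple[float, int]:
    """Pearson product-moment correlation with listwise deletion.

    Pairs with a missing member are dropped; at least 3 complete pairs and
    non-zero variance in both variables are required. Returns ``(r, n_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be paired (same length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[keep], y[keep]
    if xs.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValidationError("zero variance in one of the variables")
    r, _ = sps.pearsonr(xs, ys)
    return float(r), int(xs.size)


# ---------------------------------------------------------------------------
# two-group comparisons


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_labels: tuple[str, str]
    group_values: tuple[tuple, tuple]
    test: str  # rank_sum_exact | rank_sum_normal | signed_rank
    statistic: float
    p_value: float


def _exact_ranksum_p(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum p by full enumeration with midranked ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = pooled.size
    na = len(a)
    w_obs = ranks[:na].sum()
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for idx in combinations(range(n), na):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(w_obs), p


def rank_test(group_a, group_b, mode: str = "rank_sum", metric: str = "",
              labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-group comparison; two-sided.

    ``mode='rank_sum'`` runs the Wilcoxon rank-sum / Mann–Whitney test for
    independent groups: exact permutation null (ties midranked) when the
    combined n is <= 20, tie-corrected normal approximation otherwise.
    ``mode='signed_rank'`` runs the paired Wilcoxon signed-rank test.
    Missing values are removed per group beforehand.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if mode == "signed_rank":
        if a.size != b.size or a.size == 0:
            raise ValidationError("signed-rank test requires paired non-empty samples")
        res = sps.wilcoxon(a, b, alternative="two-sided")
        return GroupComparison(metric, labels, (tuple(a), tuple(b)),
                               "signed_rank", float(res.statistic), float(res.pvalue))
    if mode != "rank_sum":
        raise ValidationError(f"unknown mode {mode!r}")
    if a.size == 0 or b.size == 0:
        raise ValidationError("each group needs at least one value")
    if a.size + b.size <= EXACT_RANKSUM_MAX_N:
        stat, p = _exact_ranksum_p(a, b)
        return GroupComparison(metric, labels, (tuple(a), tuple(b)),
                               "rank_sum_exact", stat, p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(metric, labels, (tuple(a), tuple(b)),
                           "rank_sum_normal", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalStratification:
    """Times (days), event flags and a two-level (or more) grouping."""

    times: tuple
    events: tuple
    groups: tuple
    split_rule: str = "custom"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=float)
        g = np.asarray(self.groups)
        if not (t.size == e.size == g.size) or t.size == 0:
            raise ValidationError("times, events and groups must be equal-length, non-empty")
        if np.any(t <= 0):
            raise ValidationError("survival times must be positive")
        labels, counts = np.unique(g, return_counts=True)
        if labels.size < 2:
            raise ValidationError("need at least two non-empty groups")
        if e.sum() == 0:
            raise ValidationError("need at least one event")


def split_by_rule(values, rule: str, doubling_flags=None, rano=None):
    """Group labels for survival stratification.

    ``rule`` is ``median`` (median split of the values), ``doubling``
    (uses the precomputed flags) or ``threshold:X`` (values >= X).
    ``rano`` labels pass through unchanged with ``rule='rano'``.
    """
    if rule == "median":
        v = np.asarray(values, dtype=float)
        med = np.nanmedian(v)
        return np.where(v >= med, "high", "low")
    if rule == "doubling":
        if doubling_flags is None:
            raise ValidationError("doubling split needs precomputed flags")
        return np.where(np.asarray(doubling_flags, dtype=bool), "doubled", "not_doubled")
    if rule == "rano":
        if rano is None:
            raise ValidationError("rano split needs RANO labels")
        return np.asarray(rano)
    if rule.startswith("threshold:"):
        thr = float(rule.split(":", 1)[1])
        v = np.asarray(values, dtype=float)
        return np.where(v >= thr, "high", "low")
    raise ValidationError(f"unknown split rule {rule!r}")


def km_logrank(strat: SurvivalStratification) -> dict:
    """Log-rank test plus Kaplan–Meier summaries per group.

    Returns ``statistic`` (chi-square, k-1 df), ``p``, per-group median
    survival, and per-group KM step functions as (time, survival) arrays.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(strat.times, dtype=float)
    e = np.asarray(strat.events, dtype=int)
    g = np.asarray(strat.groups)
    res = multivariate_logrank_test(t, g, e)
    curves = {}
    medians = {}
    for label in np.unique(g):
        sel = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(label))
        sf = kmf.survival_function_
        curves[str(label)] = {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }
        medians[str(label)] = float(kmf.median_survival_time_)
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "median_survival": medians,
        "curves": curves,
        "split_rule": strat.split_rule,
    }
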