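"""Closed-form statistical tests used throughout the pipeline.

All statistics are computed from their textbook formulas; SciPy supplies
only the distribution tail functions.  Two-sided p-values are reported
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import f as _f_dist
from scipy.stats import kruskal as _scipy_kruskal
from scipy.stats import norm as _norm_dist
from scipy.stats import t as _t_dist

__all__ = [
    "TestResult",
    "welch_t",
    "chi2_gof",
    "bh_adjust",
    "anova_one_way",
    "anova_two_way",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    test_name: str
    extra: dict = field(default_factory=dict)


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Unequal-variance two-sample t-test with Welch-Satterthwaite df.

    t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny); at least one group must
    have nonzero variance and both need n >= 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("welch_t is undefined when both groups have zero variance")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    p = 2.0 * _t_dist.sf(abs(t), df)
    return TestResult(t, df, float(p), "welch_t")


def chi2_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> TestResult:
    """Chi-square goodness-of-fit against given (or equal) expected counts.

    df = k - 1.  With ``expected`` omitted, the total is split equally
    across cells.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValueError("chi2_gof needs a 1-D vector of >= 2 cells")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if expected is None:
        total = obs.sum()
        if total <= 0:
            raise ValueError("all observed counts are zero")
        exp = np.full(len(obs), total / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValueError("observed and expected lengths differ")
        if (exp <= 0).any():
            raise ValueError("expected counts must be positive")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return TestResult(stat, float(df), float(_chi2_dist.sf(stat, df)), "chi2_gof")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Adjusted values never fall below the raw ones and are invariant under
    permutation of the input (up to matching reorder).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def anova_one_way(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F-test across k independent groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("anova_one_way needs >= 2 nonempty groups")
    all_vals = np.concatenate(arrays)
    n_total = len(all_vals)
    k = len(arrays)
    if n_total - k < 1:
        raise ValueError("not enough observations for the error term")
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(_f_dist.sf(f, df_b, df_w))
    return TestResult(float(f), float(df_b), p, "anova_one_way", {"df_denom": df_w})


def anova_two_way(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> dict[str, TestResult]:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Requires every (A, B) cell to hold the same number (>= 2) of
    replicates; sums of squares then follow the classical decomposition.
    Returns results keyed by "factor_a", "factor_b" and "interaction".
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("values and factor vectors must share one length")
    levels_a = sorted(set(fa.tolist()))
    levels_b = sorted(set(fb.tolist()))
    a, b = len(levels_a), len(levels_b)
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = {}
    for la in levels_a:
        for lb in levels_b:
            cell = y[(fa == la) & (fb == lb)]
            cells[(la, lb)] = cell
    sizes = {len(c) for c in cells.values()}
    if len(sizes) != 1:
        raise ValueError("design must be balanced (equal cell sizes)")
    n = sizes.pop()
    if n < 2:
        raise ValueError("need >= 2 replicates per cell for the error term")

    grand = y.mean()
    mean_a = {la: y[fa == la].mean() for la in levels_a}
    mean_b = {lb: y[fb == lb].mean() for lb in levels_b}
    ss_a = n * b * sum((mean_a[la] - grand) ** 2 for la in levels_a)
    ss_b = n * a * sum((mean_b[lb] - grand) ** 2 for lb in levels_b)
    ss_ab = n * sum(
        (cells[(la, lb)].mean() - mean_a[la] - mean_b[lb] + grand) ** 2
        for la in levels_a
        for lb in levels_b
    )
    ss_e = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_a, df_b_, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e

    def _result(name: str, ss: float, df: int) -> TestResult:
        if ms_e == 0:
            f = math.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / df) / ms_e
            p = float(_f_dist.sf(f, df, df_e))
        return TestResult(float(f), float(df), p, name, {"df_denom": df_e})

    return {
        "factor_a": _result("anova_two_way:factor_a", ss_a, df_a),
        "factor_b": _result("anova_two_way:factor_b", ss_b, df_b_),
        "interaction": _result("anova_two_way:interaction", ss_ab, df_ab),
    }


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test (thin wrapper, df = k - 1)."""
    stat, p = _scipy_kruskal(*groups)
    return TestResult(float(stat), float(len(groups) - 1), float(p), "kruskal_wallis")


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bh"
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled ranks, with tie correction.

    ``adjust`` is "bh", "bonferroni" or "none"; returns adjusted p per
    unordered group pair.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n_total)
    sorted_vals = pooled[order]
    i = 0
    rank_pos = np.arange(1, n_total + 1, dtype=float)
    tie_sum = 0.0
    while i < n_total:
        j = i
        while j + 1 < n_total and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = rank_pos[i : j + 1].mean()
        t = j - i + 1
        if t > 1:
            tie_sum += t**3 - t
        i = j + 1
    tie_corr = tie_sum / (12.0 * (n_total - 1))
    offsets = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = [
        ranks[offsets[k] : offsets[k + 1]].mean() for k in range(len(arrays))
    ]
    raw: list[float] = []
    pairs = list(combinations(range(len(names)), 2))
    for k, l in pairs:
        nk, nl = len(arrays[k]), len(arrays[l])
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_corr) * (1.0 / nk + 1.0 / nl)
        )
        z = (mean_ranks[k] - mean_ranks[l]) / se
        raw.append(2.0 * float(_norm_dist.sf(abs(z))))
    if adjust == "bh":
        adj = bh_adjust(raw)
    elif adjust == "bonferroni":
        adj = np.minimum(np.asarray(raw) * len(raw), 1.0)
    elif adjust == "none":
        adj = np.asarray(raw)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return {
        (names[k], names[l]): float(adj[i]) for i, (k, l) in enumerate(pairs)
    }
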