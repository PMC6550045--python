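"""Shared statistical primitives.

* :func:`bh_adjust` — Benjamini–Hochberg step-up FDR adjustment.
* :func:`anova_lsd` — one-way ANOVA with Fisher's LSD post-hoc pairwise
  t-tests on the pooled within-group variance (LSD p-values are by
  definition unadjusted).
* :func:`ks_2sample` — two-sample Kolmogorov–Smirnov test; the statistic is
  the supremum ECDF difference over the pooled sample, the p-value is exact
  (hypergeometric path recursion, valid for continuous data) for
  n1*n2 <= 10_000 and asymptotic (Kolmogorov distribution at the effective
  sample size n1*n2/(n1+n2)) otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

_TINY = np.finfo(float).tiny


def bh_adjust(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of a p-value vector, order-preserving.

    ``method="bh"`` applies the step-up Benjamini–Hochberg procedure:
    p_adj(i) = min_{j >= i} (m/j) p_(j), clamped to 1, where p_(j) are the
    sorted p-values.  ``method="bonferroni"`` is exposed as an alternative.
    Note BH is monotone but not idempotent in general.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "bh":
        raise ValueError(f"unknown adjustment method: {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class AnovaResult:
    """One-way ANOVA with Fisher-LSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict
    pairwise: pd.DataFrame      # columns group1, group2, t, p
    degenerate: bool = False    # zero within-group variance with unequal means


def anova_lsd(groups, labels=None) -> AnovaResult:
    """One-way ANOVA over replicate-value lists plus Fisher's LSD post hoc.

    Each group needs >= 2 replicates.  With zero within-group variance the
    omnibus test is degenerate: F is infinite and p is reported as the
    smallest positive float (flagged via ``degenerate``); if additionally
    all group means coincide, F = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two replicates")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between = k - 1
    df_within = n_total - k
    ms_within = ss_within / df_within

    degenerate = False
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, _TINY
            degenerate = True
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if ms_within > 0:
                se = np.sqrt(ms_within * (1.0 / ns[i] + 1.0 / ns[j]))
                t = diff / se
                p_ij = float(2.0 * stats.t.sf(abs(t), df_within))
            else:
                t = 0.0 if diff == 0 else np.inf * np.sign(diff)
                p_ij = 1.0 if diff == 0 else _TINY
            rows.append((labels[i], labels[j], t, p_ij))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "t", "p"])
    return AnovaResult(
        f_statistic=float(f_stat), p_value=float(p),
        df_between=df_between, df_within=df_within, ms_within=ms_within,
        group_means=dict(zip(labels, means)), pairwise=pairwise,
        degenerate=degenerate,
    )


def ks_statistic(x, y) -> float:
    """Two-sample KS statistic: sup of |ECDF1 - ECDF2| over pooled points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_exact_sf(d: float, n1: int, n2: int) -> float:
    """P(D >= d) under H0 for continuous data, by path counting.

    A random interleaving of the two samples is a lattice path from (0, 0)
    to (n1, n2); D < d iff the path keeps |i/n1 - j/n2| < d at every
    vertex.  The recursion walks the pooled draws with hypergeometric
    transition probabilities, so no combinatorial overflow occurs.
    """
    tol = 1e-10
    if d <= tol:
        return 1.0
    total = n1 + n2
    i = np.arange(n1 + 1, dtype=float)
    dp = np.zeros(n1 + 1)
    dp[0] = 1.0
    for k in range(1, total + 1):
        rem = total - (k - 1)
        p1 = np.clip((n1 - i) / rem, 0.0, 1.0)          # draw from sample 1
        p2 = np.clip((n2 - (k - 1 - i)) / rem, 0.0, 1.0)
        new = dp * p2
        new[1:] += dp[:-1] * p1[:-1]
        j = k - i
        invalid = (j < 0) | (j > n2)
        new[invalid] = 0.0
        new[np.abs(i / n1 - j / n2) >= d - tol] = 0.0
        dp = new
    return float(min(max(1.0 - dp[n1], 0.0), 1.0))


def ks_2sample(x, y, mode: str = "auto"):
    """Two-sample KS test; returns ``(D, p)``.

    ``mode`` is ``"exact"``, ``"asymp"`` or ``"auto"`` (exact whenever
    n1*n2 <= 10_000).  The exact p-value assumes continuous data (no ties
    between the samples beyond what the ECDFs already encode).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    d = ks_statistic(x, y)
    n1, n2 = len(x), len(y)
    if mode == "auto":
        mode = "exact" if n1 * n2 <= 10_000 else "asymp"
    if mode == "exact":
        p = _ks_exact_sf(d, n1, n2)
    elif mode == "asymp":
        n_eff = n1 * n2 / (n1 + n2)
        p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return d, float(min(max(p, 0.0), 1.0))
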