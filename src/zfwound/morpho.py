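"""Circularity distribution analysis and between-group comparison.

Circularity (4*pi*A/P^2) is a proxy for the macrophage activation state:
rounded (high-circularity) cells correspond to the pro-inflammatory
phenotype, elongated/dendritic cells to resting or alternatively activated
states.  This module bins per-cell circularity values into a histogram over
(0, 1], reports the high-circularity fraction (C in (0.5, 1.0]) and
compares two groups with the two-sample Kolmogorov–Smirnov test on the
unbinned values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import ks_2sample


@dataclass
class CircularityDistribution:
    """Histogram of circularity values over (0, 1]."""

    bin_edges: np.ndarray       # length n_bins + 1, from 0 to 1
    fractions: np.ndarray       # length n_bins, sums to 1 when n > 0
    high_fraction: float        # fraction with C in (0.5, 1.0]
    n: int
    n_clamped: int              # raw values > 1 clamped to 1.0
    empty: bool


def circularity_distribution(values, bin_width: float = 0.1) -> CircularityDistribution:
    """Left-open/right-closed histogram of circularity values.

    ``bin_width`` must divide 1 evenly.  Values above 1 (discretization
    artifacts) are clamped to 1.0 and counted in ``n_clamped``; values must
    be strictly positive.
    """
    n_bins = 1.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return CircularityDistribution(
            bin_edges=edges, fractions=np.zeros(n_bins), high_fraction=np.nan,
            n=0, n_clamped=0, empty=True)
    if np.any(values <= 0):
        raise ValueError("circularity values must be > 0")
    n_clamped = int((values > 1.0).sum())
    values = np.minimum(values, 1.0)
    # (left, right] bins: bin index = ceil(v / w) - 1
    idx = np.ceil(values / bin_width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    high = float((values > 0.5).sum() / values.size)
    return CircularityDistribution(
        bin_edges=edges, fractions=counts / counts.sum(), high_fraction=high,
        n=int(values.size), n_clamped=n_clamped, empty=False)


@dataclass
class KSComparison:
    d: float
    p: float
    n1: int
    n2: int
    mode: str


def ks_compare(values1, values2, mode: str = "auto") -> KSComparison:
    """Two-sample KS comparison of circularity distributions.

    Values are compared unbinned.  Raises on an empty group.
    """
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    if values1.size == 0 or values2.size == 0:
        raise ValueError("both groups must contain at least one value")
    used = mode
    if mode == "auto":
        used = "exact" if values1.size * values2.size <= 10_000 else "asymp"
    d, p = ks_2sample(values1, values2, mode=used)
    return KSComparison(d=d, p=p, n1=int(values1.size), n2=int(values2.size),
                        mode=used)


def group_comparison_table(cells: pd.DataFrame, group_col: str,
                           value_col: str = "circularity",
                           bin_width: float = 0.1):
    """Histograms per group plus all pairwise KS comparisons.

    Returns ``(hist_table, ks_table)`` DataFrames from a segmented-cell
    table with a group column.
    """
    hists, ks_rows = [], []
    groups = {lab: g[value_col].to_numpy(float)
              for lab, g in cells.groupby(group_col)}
    for lab, vals in groups.items():
        dist = circularity_distribution(vals, bin_width)
        row = {"group": lab, "n": dist.n, "high_fraction": dist.high_fraction,
               "n_clamped": dist.n_clamped}
        for k in range(len(dist.fractions)):
            row[f"bin_{dist.bin_edges[k]:.2f}_{dist.bin_edges[k + 1]:.2f}"] = (
                dist.fractions[k])
        hists.append(row)
    labels = sorted(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            cmp = ks_compare(groups[a], groups[b])
            ks_rows.append({"group1": a, "group2": b, "d": cmp.d, "p": cmp.p,
                            "mode": cmp.mode})
    return pd.DataFrame(hists), pd.DataFrame(ks_rows)
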