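"""Transcriptome arm: filtering, paired differential test, attenuation stats.

The pipeline starts from a genes x samples integer count matrix for the
four-condition design {control, amp, beclo, amp_beclo} with paired
replicates.  Per contrast (treatment vs control) it applies the low-count
filter (sum over the six samples of the pair < 30 removed), median-of-ratios
size factors, and a deliberately simple paired negative-binomial test:
a NB GLM with log link, replicate blocking dummies and a condition
indicator, method-of-moments dispersion pooled across the two groups, and a
Wald z-test on the condition coefficient, followed by Benjamini–Hochberg
adjustment.  This is an explicitly simplified stand-in for a full
differential-expression package, not a clone of one; downstream set algebra
(regulation sets, Venn overlaps) and the attenuation-fraction statistic
operate on its per-gene results.  A DeltaDeltaCt fold-change helper covers
the qPCR arm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_adjust

CONTRASTS = ("amp", "beclo", "amp_beclo")

RESULT_COLUMNS = ["gene", "contrast", "base_mean", "log2fc", "fold_change",
                  "pvalue", "padj", "dispersion"]


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def _contrast_samples(meta: pd.DataFrame, treatment: str, control: str):
    for t in (treatment, control):
        if not (meta["treatment"] == t).any():
            raise ValueError(f"treatment {t!r} missing from sample metadata")
    trt = meta.loc[meta["treatment"] == treatment].sort_values("replicate")
    ctl = meta.loc[meta["treatment"] == control].sort_values("replicate")
    return ctl["sample"].tolist(), trt["sample"].tolist()


def filter_low_counts(counts: pd.DataFrame, meta: pd.DataFrame,
                      treatment: str, control: str = "control",
                      min_total: int = 30) -> pd.Index:
    """Genes retained for one contrast: total count over the two groups >= 30.

    The sum runs over all samples of the two treatments (replicates x 2
    groups); genes whose sum is lower than ``min_total`` are removed, so a
    sum of exactly ``min_total`` is retained.
    """
    ctl, trt = _contrast_samples(meta, treatment, control)
    totals = counts[ctl + trt].sum(axis=1)
    return counts.index[totals >= min_total]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    factor_s = median over genes (nonzero in every sample) of
    count_gs / geometric-mean_g(counts).  Raises when no gene is nonzero in
    all samples; supply a pseudo-reference upstream in that case.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "add a pseudo-reference or filter samples")
    sub = mat[all_nonzero]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Paired NB Wald test (batched IRLS across genes)
# ---------------------------------------------------------------------------

def _irls_nb_batch(y, X, offset, alpha, max_iter=50, tol=1e-10):
    """Fit NB log-link GLMs for many genes sharing one design matrix.

    y: (G, n) counts, X: (n, p) design, offset: (n,) log size factors,
    alpha: (G,) fixed NB dispersions.  Returns (beta, se) each (G, p).
    """
    G, n = y.shape
    p = X.shape[1]
    eta = np.log(np.maximum(y, 0) + 0.5) - offset   # linear predictor minus offset
    # initial beta by unweighted least squares
    beta, *_ = np.linalg.lstsq(X, eta.T, rcond=None)
    beta = beta.T
    ridge = 1e-10 * np.eye(p)
    for _ in range(max_iter):
        lin = beta @ X.T + offset                    # (G, n)
        lin = np.clip(lin, -30.0, 30.0)
        mu = np.exp(lin)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (lin - offset) + (y - mu) / mu
        xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
        xtwz = np.einsum("gn,gn,np->gp", w, z, X)
        new = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    lin = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(lin)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
    cov = np.linalg.inv(xtwx + ridge)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se


def _mom_dispersion(norm_ctl, norm_trt, floor=1e-8, share="maximum"):
    """Method-of-moments NB dispersion pooled across the two groups.

    With few replicates the per-gene moment estimate is very noisy (and
    clipped at zero for roughly half of the truly overdispersed genes),
    which makes a plug-in Wald test anticonservative.  ``share="maximum"``
    therefore raises each gene to at least the across-gene median
    dispersion, the conservative sharing rule of classic count-based DE
    testing; ``share="gene"`` keeps the raw per-gene values.
    """
    alphas = []
    for grp in (norm_ctl, norm_trt):
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / m**2, 0.0)
        alphas.append(np.clip(a, 0.0, None))
    pooled = np.mean(alphas, axis=0)
    if share == "maximum" and pooled.size:
        pooled = np.maximum(pooled, np.median(pooled))
    return np.maximum(pooled, floor)


def paired_nb_test(counts: pd.DataFrame, meta: pd.DataFrame, treatment: str,
                   control: str = "control",
                   sf: pd.Series | None = None,
                   min_total: int = 30) -> pd.DataFrame:
    """Paired differential test of one treatment against the control group.

    Applies the low-count filter, normalizes by size factors (computed on
    the full matrix unless given), reports log2 fold changes from shrunken
    group means (pseudocount 0.5 on normalized means) and Wald z p-values
    from the NB GLM with replicate blocking, BH-adjusted over the tested
    genes.
    """
    ctl_samples, trt_samples = _contrast_samples(meta, treatment, control)
    if len(ctl_samples) != len(trt_samples):
        raise ValueError("paired design requires equal replicate counts")
    if len(ctl_samples) < 2:
        raise ValueError("need at least two paired replicates")
    kept = filter_low_counts(counts, meta, treatment, control, min_total)
    if sf is None:
        sf = size_factors(counts)
    samples = ctl_samples + trt_samples
    y = counts.loc[kept, samples].to_numpy(dtype=float)
    s = sf[samples].to_numpy(dtype=float)
    norm = y / s
    n_rep = len(ctl_samples)

    norm_ctl, norm_trt = norm[:, :n_rep], norm[:, n_rep:]
    mean_ctl = norm_ctl.mean(axis=1)
    mean_trt = norm_trt.mean(axis=1)
    log2fc = np.log2((mean_trt + 0.5) / (mean_ctl + 0.5))
    alpha = _mom_dispersion(norm_ctl, norm_trt)

    # design: intercept, replicate dummies (pairing), condition indicator
    n = 2 * n_rep
    X = np.zeros((n, 1 + (n_rep - 1) + 1))
    X[:, 0] = 1.0
    for r in range(1, n_rep):
        X[r, r] = 1.0
        X[n_rep + r, r] = 1.0
    X[n_rep:, -1] = 1.0
    offset = np.log(s)

    beta, se = _irls_nb_batch(y, X, offset, alpha)
    coef = beta[:, -1]
    sigma = se[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, coef / sigma, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    return pd.DataFrame({
        "gene": kept,
        "contrast": treatment,
        "base_mean": norm.mean(axis=1),
        "log2fc": log2fc,
        "fold_change": 2.0 ** log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "dispersion": alpha,
    }).set_index("gene", drop=False)


def run_all_contrasts(counts: pd.DataFrame, meta: pd.DataFrame,
                      control: str = "control",
                      contrasts=CONTRASTS) -> dict:
    """Paired NB test of every treatment against the control group."""
    sf = size_factors(counts)
    return {c: paired_nb_test(counts, meta, c, control, sf=sf)
            for c in contrasts}


# ---------------------------------------------------------------------------
# Regulation sets, Venn overlaps, attenuation
# ---------------------------------------------------------------------------

@dataclass
class RegulationSets:
    """Significantly up-/down-regulated genes per contrast."""

    up: dict        # contrast -> set of genes
    down: dict
    padj_cutoff: float
    fc_cutoff: float


def classify_regulation(results: dict, padj_cutoff: float = 0.05,
                        fc_cutoff: float = 2.0) -> RegulationSets:
    """Apply the significance cutoffs (p.adj < 0.05, |FoldChange| > 2).

    Up-regulation means fold change > fc_cutoff, down-regulation fold
    change < 1/fc_cutoff (the cutoff applied symmetrically on the ratio
    scale), both at p.adj < padj_cutoff.
    """
    up, down = {}, {}
    for contrast, res in results.items():
        sig = res["padj"] < padj_cutoff
        up[contrast] = set(res.loc[sig & (res["fold_change"] > fc_cutoff), "gene"])
        down[contrast] = set(res.loc[sig & (res["fold_change"] < 1.0 / fc_cutoff),
                                     "gene"])
    return RegulationSets(up=up, down=down, padj_cutoff=padj_cutoff,
                          fc_cutoff=fc_cutoff)


def venn_counts(sets: dict) -> dict:
    """Sizes of all 1-, 2- and 3-way (and higher) intersections.

    Keys are "a", "a&b", "a&b&c" with member names sorted alphabetically
    inside each key.
    """
    from itertools import combinations

    names = sorted(sets)
    out = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            out["&".join(combo)] = len(inter)
    return out


ATTENUATION_CLASSES = ("attenuated", "enhanced", "unchanged", "sign_flipped")


@dataclass
class AttenuationReport:
    """Per-gene attenuation classes over the amp-significant set.

    ``fraction_attenuated`` follows the identity-line reading: sign-flipped
    genes whose combined-treatment response is smaller in magnitude count
    with the attenuated genes.  ``fraction_attenuated_same_sign`` counts
    only same-sign attenuation.  The four classes partition the set.
    """

    table: pd.DataFrame         # gene, lfc_amp, lfc_combo, klass, flagged
    n_attenuated: int
    n_enhanced: int
    n_unchanged: int
    n_sign_flipped: int
    n_flip_attenuated: int      # sign-flips with |lfc_combo| < |lfc_amp|
    fraction_attenuated: float
    fraction_attenuated_same_sign: float
    tol: float


def attenuation_fraction(amp_results: pd.DataFrame,
                         combo_results: pd.DataFrame,
                         amp_significant, tol: float = 0.0) -> AttenuationReport:
    """Classify glucocorticoid attenuation of the amputation response.

    For each gene in the amp-significant set, compare the log2 fold change
    under the combined treatment with the one under amputation alone:
    same sign and |combo| < |amp| - tol is attenuated; same sign and
    |combo| > |amp| + tol is enhanced; opposite nonzero signs is
    sign-flipped; anything else is unchanged.  Genes missing from the
    combined-contrast results are flagged and conservatively classed as
    unchanged.  ``tol`` (log2 units) widens the unchanged band around the
    identity line to absorb estimation noise.
    """
    genes = list(amp_significant)
    if len(genes) == 0:
        raise ValueError("amp-significant set is empty")
    lfc_amp = amp_results.set_index("gene")["log2fc"] if "gene" in amp_results \
        else amp_results["log2fc"]
    lfc_combo = combo_results.set_index("gene")["log2fc"] if "gene" in combo_results \
        else combo_results["log2fc"]
    missing_amp = [g for g in genes if g not in lfc_amp.index]
    if missing_amp:
        raise ValueError(f"amp results missing genes: {missing_amp[:5]}")

    rows = []
    for g in genes:
        a = float(lfc_amp.loc[g])
        flagged = g not in lfc_combo.index
        c = 0.0 if flagged else float(lfc_combo.loc[g])
        if flagged:
            klass = "unchanged"
        elif a * c < 0:
            klass = "sign_flipped"
        elif abs(c) < abs(a) - tol:
            klass = "attenuated"
        elif abs(c) > abs(a) + tol:
            klass = "enhanced"
        else:
            klass = "unchanged"
        rows.append((g, a, c, klass, flagged))
    table = pd.DataFrame(rows, columns=["gene", "lfc_amp", "lfc_combo",
                                        "klass", "flagged"])
    n = len(table)
    n_att = int((table["klass"] == "attenuated").sum())
    n_enh = int((table["klass"] == "enhanced").sum())
    n_unc = int((table["klass"] == "unchanged").sum())
    n_flip = int((table["klass"] == "sign_flipped").sum())
    flips = table[table["klass"] == "sign_flipped"]
    n_flip_att = int((flips["lfc_combo"].abs() < flips["lfc_amp"].abs()).sum())
    return AttenuationReport(
        table=table,
        n_attenuated=n_att, n_enhanced=n_enh, n_unchanged=n_unc,
        n_sign_flipped=n_flip, n_flip_attenuated=n_flip_att,
        fraction_attenuated=(n_att + n_flip_att) / n,
        fraction_attenuated_same_sign=n_att / n,
        tol=tol,
    )


def immune_gene_table(results: dict, gene_list) -> pd.DataFrame:
    """Long-format fold changes of selected genes across all contrasts.

    ``signed_fold_change`` expresses down-regulation as a negative ratio
    (-1/FC), the convention of grouped fold-change bar plots.  Genes absent
    from every contrast trigger a warning and are skipped.
    """
    rows = []
    for gene in gene_list:
        found = False
        for contrast, res in results.items():
            if gene in res.index:
                fc = float(res.loc[gene, "fold_change"])
                rows.append({
                    "gene": gene,
                    "contrast": contrast,
                    "fold_change": fc,
                    "log2fc": float(res.loc[gene, "log2fc"]),
                    "signed_fold_change": fc if fc >= 1.0 else -1.0 / fc,
                })
                found = True
        if not found:
            warnings.warn(f"gene {gene!r} not present in any contrast; skipped")
    return pd.DataFrame(rows, columns=["gene", "contrast", "fold_change",
                                       "log2fc", "signed_fold_change"])


# ---------------------------------------------------------------------------
# qPCR DeltaDeltaCt
# ---------------------------------------------------------------------------

def ddct_fold_change(ct: pd.DataFrame, control_samples,
                     reference_gene: str = "ppiab") -> pd.DataFrame:
    """Relative expression by the 2^(-DeltaDeltaCt) method.

    ``ct`` is long-format with columns sample, gene, ct and must include
    the reference gene for every sample.  DeltaCt = Ct_target - Ct_ref per
    sample; DeltaDeltaCt subtracts the mean DeltaCt of the control samples;
    fold change = 2^(-DeltaDeltaCt).
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    samples = ct["sample"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"reference gene {reference_gene!r} missing for "
                         f"samples: {missing}")
    targets = ct[ct["gene"] != reference_gene].copy()
    targets["delta_ct"] = targets["ct"] - targets["sample"].map(ref).to_numpy()
    control_samples = set(control_samples)
    ctrl_mean = (targets[targets["sample"].isin(control_samples)]
                 .groupby("gene")["delta_ct"].mean())
    genes_without_ctrl = set(targets["gene"]) - set(ctrl_mean.index)
    if genes_without_ctrl:
        raise ValueError(f"no control-sample Ct for genes: "
                         f"{sorted(genes_without_ctrl)[:5]}")
    targets["ddct"] = targets["delta_ct"] - targets["gene"].map(ctrl_mean).to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "gene", "ct", "delta_ct", "ddct",
                    "fold_change"]].reset_index(drop=True)
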