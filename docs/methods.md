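# Methods

This note documents the models, numerical choices and known limitations of
the `zfwound` pipeline, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scene simulation

Cells perform a biased random walk toward the wound. At each frame a cell
draws a speed from a normal distribution truncated at zero
(`speed_mean`, `speed_sd`, µm/min; `sd = 0` gives the constant speed) and a
direction from a von Mises distribution whose mean points at the nearest
point of the wound geometry and whose concentration is `kappa`
(`kappa = 0` is an unbiased walk, large `kappa` saturates toward the
wound). Positions reflect off the field boundary, which avoids truncating
tracks in recovery tests at the cost of slightly distorting the angular
distribution of steps taken within one step length of the border; tests of
angular uniformity therefore use a large field with an initial keep-out
margin so no cell reaches the boundary.

No motion model is claimed to describe real leukocytes; the walk was chosen
because it exposes exactly the read-outs the pipeline measures (ROI
occupancy, per-step speed, wound-relative directionality) with analytically
known expectations. Real macrophages show persistence, shape-coupled
motility, and mutual avoidance, none of which are simulated.

Cells are rendered as anisotropic Gaussian blobs (scale `blob_sigma` px)
whose long axis follows the current step direction and whose axis ratio is
drawn once per cell from `axis_ratio_range`. Every level set of such a blob
is an ellipse with that axis ratio, so the cell's true circularity is the
ellipse value 4πA/P² computed with the exact elliptic-integral perimeter.
Defaults (512×512 px at 0.65 µm/px, 1 min frame interval, 30 cells at
3.5 ± 1 µm/min, `kappa = 2`, peak amplitude 120 over background 10 with
noise sd 2) emulate a confocal field of a wounded tail fin at a ~1 min
acquisition interval; they are plausible study conditions, not fits to any
dataset. Touching blobs merge at detection and segmentation — resolving
them is out of scope and simulated scenes used for recovery statistics
enforce an initial 15 px separation instead.

Note on the high-circularity cut: an ideal 4:1 ellipse has C ≈ 0.555,
which is *above* the 0.5 threshold of the "high circularity" band, so the
high fraction only discriminates populations once elongation exceeds about
4.4:1 (C(ratio 6) ≈ 0.40). Comparisons of mildly elongated populations
should use the full distribution (KS test) or the mean, not the high
fraction alone.

## Detection, segmentation, tracking

Detection smooths with a Gaussian (`sigma`, px) and extracts local maxima
at least `min_distance` px apart and above `abs_threshold`, with ties
resolved toward higher intensity then lower (y, x); an optional local
center-of-mass step refines peaks to subpixel precision. Segmentation
thresholds (Otsu per frame by default, absolute for synthetic fixtures),
labels 8-connected components, drops components under `min_area` px², and
measures the Crofton (4-direction) perimeter. The naive boundary-pixel
perimeter biases circularity above 1 for small disks; Crofton keeps the
rasterized disk of radius 20 px within 0.05 of the analytic value. Raw
circularity can still slightly exceed 1 on small regions; reported values
are clamped to 1.0 with the raw value retained.

Linking solves the gated rectangular assignment problem per frame pair with
the Hungarian algorithm (cost = Euclidean displacement, pairs beyond
`max_disp` forbidden); this is deterministic, globally optimal and directly
checkable against a brute-force permutation oracle. A greedy
nearest-neighbour mode exists for very dense scenes. Tracks missing for up
to `max_gap` frames (default 2) re-join within `max_disp × (gap + 1)`;
re-joined steps carry a gap flag and their velocity divides by the elapsed
time.

## Migration statistics

Hour h covers [60(h−1), 60h) minutes. Step angles are measured against the
unit vector from the step's *start* point to the nearest wound point
(a fixed axis would be wrong for curved wound geometry); bin k of the 8-bin
directionality histogram covers (45k − 22.5°, 45k + 22.5°], so +22.5° falls
in bin 0 and −22.5° in bin 7. Zero-displacement steps have no angle; they
are excluded from the bins and reported as an immobile count. Histograms
are computed over steps by default; aggregating per track first is possible
by pre-filtering the step table. Group comparisons use one-way ANOVA on
per-replicate hourly means with Fisher's LSD post hoc (pairwise t-tests on
the pooled within-group variance, unadjusted, as the procedure is defined).
When the within-group variance is exactly zero the omnibus test is
degenerate; F is reported as 0 (equal means, p = 1) or infinity (unequal
means, p bounded by the smallest positive float and flagged).

## Statistical primitives

Benjamini–Hochberg is the step-up rule p_adj(i) = min_{j≥i} (m/j) p_(j)
clamped to 1; it is monotone but not idempotent. The two-sample KS
statistic is the supremum ECDF difference over the pooled sample. Its
p-value is exact for n₁n₂ ≤ 10⁴ via the lattice-path recursion with
hypergeometric transition probabilities (valid for continuous data —
numerically stable, no binomial overflow), and asymptotic otherwise, using
the Kolmogorov distribution at the effective size n₁n₂/(n₁+n₂). Under the
null with n = 100 per group the exact test rejects at close to the nominal
5% (measured by the acceptance script).

## Count simulation and the paired NB test

`simulate_counts` draws NB counts (Poisson when `dispersion = 0`) with
gene baselines log-normal(5, 1) (median ≈ 150 counts), dispersion α = 0.05,
and a log-normal replicate offset (sd 0.15) shared by the four conditions
of a replicate — the pairing structure. Each gene belongs to exactly one
class: null (60% by default), amputation-responsive with attenuation
(the amp log2FC, magnitude U(1.5, 3) with 66% up, is multiplied by
U(0.1, 0.5) in the combined condition), amputation-responsive and
glucocorticoid-insensitive (25% of the responsive genes; combined log2FC
equals the amp log2FC), or drug-responsive (5%; the drug effect appears in
both drug-containing conditions). These defaults emulate a strong, broadly
attenuated wounding response with a planted 75% attenuated fraction.

The differential test is a deliberately simple paired NB Wald test, not a
re-implementation of any published tool: counts are modeled by an NB GLM
with log link, design = intercept + replicate dummies + condition
indicator, offset = log size factor (median-of-ratios over genes nonzero in
every sample). The dispersion is a method-of-moments estimate on normalized
counts pooled across the two groups, floored at 1e-8 — and, because a
3-replicate moment estimate is extremely noisy (roughly half of the
estimates clip at zero even for overdispersed genes, which makes a plug-in
Wald test anticonservative), each gene's dispersion is raised to at least
the across-gene median ("maximum" sharing, the conservative rule familiar
from classic count-based DE testing). The fit is an IRLS loop vectorized
across genes (all genes share one design matrix); p-values come from the
normal distribution of the Wald z on the condition coefficient and are
BH-adjusted over the tested genes. Reported log2 fold changes use shrunken
group means (pseudocount 0.5 on normalized means) rather than the GLM
coefficient. Under all-null simulation the measured type-I error at
p < 0.05 falls in the 0.03–0.08 band (see the acceptance script).

Median-of-ratios normalization assumes most genes are unchanged; planting
effects in a large fraction of the transcriptome (≳ 30–50%) biases the
factors and shrinks every fold change (the usual composition effect). The
simulation defaults keep the responsive fraction at 20%.

## Attenuation classification

For each amp-significant gene the combined-treatment log2FC is compared
with the amputation log2FC: same sign and |combo| < |amp| − tol is
attenuated, same sign and |combo| > |amp| + tol is enhanced, opposite
nonzero signs is sign-flipped, anything else unchanged; the four classes
partition the set exactly. The headline `fraction_attenuated` counts
sign-flipped genes whose combined response is smaller in magnitude together
with the attenuated class (the "below the identity line" reading of the
scatter plot); `fraction_attenuated_same_sign` excludes them. Genes missing
from the combined contrast (filtered there but not in the amp contrast) are
flagged and conservatively classed unchanged.

`tol` (log2 units, default 0) deserves care. With tol = 0, a gene whose
true responses are *equal* in the two contrasts falls on either side of the
identity line with probability ½ under estimation noise, so the raw
identity-line fraction systematically overshoots the true attenuated
fraction by half the insensitive fraction. At the default study conditions
the per-contrast log2FC noise is ≈ 0.2–0.3 sd (difference ≈ 0.3), so the
acceptance evaluation uses tol = 0.5 — chosen from this noise scale, not
fitted — which sends truly insensitive genes to "unchanged" while truly
attenuated genes (margin |lfc|·(1 − factor) − tol mostly well above zero)
remain detected. The script reports both the tol = 0.5 fraction (which
recovers the planted value) and the raw tol = 0 identity-line fraction.

## qPCR

ΔCt = Ct_target − Ct_reference per sample (reference gene *ppiab* by
default), ΔΔCt subtracts the mean control ΔCt per gene, and the relative
expression is 2^(−ΔΔCt). Missing reference measurements are an error, not
imputed.

## Problem sizes and determinism

All stochastic operations take explicit seeds; identical seeds give
bit-identical stacks, tracks and count matrices. The standard verification
sizes are: 30 cells × 60 frames for detection/tracking/speed recovery,
200 cells × 52 frames on a 2000 px field (≥ 10⁴ steps) for directionality,
1000 replicates of n = 100 per group for KS calibration, and 2000 genes
for the transcriptome calibrations — sizes at which the binomial/CLT error
bounds quoted in the tests are meaningful while the whole suite stays
fast.

## Known limitations

- Touching cells merge in both detection and segmentation; no watershed or
  learned splitting.
- One-way ANOVA on hourly means only; no two-way designs or mixed models.
- The NB test is a transparent stand-in: no trended dispersion fit, no
  fold-change shrinkage estimator, no outlier handling.
- The simulators do not model photobleaching, z-projection artifacts, cell
  division/death, track merging, or library-size outliers.
- KS p-values assume continuous data; heavy ties make the exact recursion
  conservative.
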