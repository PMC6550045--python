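# zfwound

Quantification pipeline for the zebrafish tail-wounding inflammation
assay: leukocyte migration and morphology from fluorescence time-lapse
stacks, and glucocorticoid attenuation of the wounding-induced macrophage
transcriptome from a four-condition count matrix. It is aimed at groups
using larval-zebrafish wounding models to dissect how anti-inflammatory
drugs act on innate immune cells.

## What it computes

**Imaging arm.** From a single-channel time-lapse (one 2D maximum-projection
frame per ~1 min):

- *Detection* — Gaussian smoothing + local maxima with distance suppression
  gives per-frame cell centroids; threshold/label segmentation measures each
  cell's area *A* (px²), Crofton perimeter *P* (px) and circularity
  C = 4πA / P² (1 for a disk, → 0 for dendritic shapes; a proxy for the
  pro-inflammatory, rounded macrophage phenotype).
- *Tracking* — per frame pair, the one-to-one assignment minimizing total
  displacement (Hungarian algorithm) under a gate `max_disp`, with gap
  closing up to `max_gap` frames.
- *Migration read-outs* — boundary-inclusive cell counts in a wound ROI,
  step velocities v = d/Δt (µm/min) averaged per hour, and an 8-bin
  directionality histogram of the angle θ between each step and the unit
  vector toward the nearest wound point; bin 0 covers (−22.5°, 22.5°]
  (movement toward the wound). Groups are compared per hour by one-way
  ANOVA with Fisher's LSD post hoc, and circularity distributions by the
  two-sample Kolmogorov–Smirnov test.

**Transcriptome arm.** From a genes × samples count matrix over
{control, amp, beclo, amp_beclo} × paired replicates: per-contrast
low-count filtering (two-group sum < 30 removed), median-of-ratios size
factors, a simplified paired negative-binomial Wald test (replicate as a
blocking covariate, method-of-moments dispersion), Benjamini–Hochberg
adjustment, regulation sets at p.adj < 0.05 and |FoldChange| > 2 with Venn
overlap counts, the **attenuated fraction** (how many amputation-regulated
genes respond more weakly when the glucocorticoid is present), and qPCR
ΔΔCt fold changes (2^(−ΔΔCt), ppiab reference).

**Synthetic ground truth.** `zfwound.simgen` renders wound-biased random
walks (von Mises-directed steps, truncated-normal speeds, anisotropic
Gaussian blobs with known true circularity) and draws paired NB count
matrices with planted regulation and attenuation structure, so every stage
of the pipeline is verifiable without external data.

## Worked example

```python
from zfwound import simgen, atten

counts, meta, truth = simgen.simulate_counts(simgen.CountSimConfig(seed=1))
results = atten.run_all_contrasts(counts, meta)
sets = atten.classify_regulation(results)
amp_sig = sorted(sets.up["amp"] | sets.down["amp"])
report = atten.attenuation_fraction(results["amp"], results["amp_beclo"],
                                    amp_sig, tol=0.5)
print(f"amp-significant genes: {len(amp_sig)} "
      f"({len(sets.up['amp'])} up, {len(sets.down['amp'])} down)")
print(f"attenuated fraction: {100 * report.fraction_attenuated:.2f}%")
print(f"classes: {report.n_attenuated} attenuated, {report.n_enhanced} "
      f"enhanced, {report.n_unchanged} unchanged, "
      f"{report.n_sign_flipped} sign-flipped")
```

prints

```
amp-significant genes: 401 (257 up, 144 down)
attenuated fraction: 76.56%
classes: 297 attenuated, 4 enhanced, 90 unchanged, 10 sign-flipped
```

The simulation plants 400 amputation-responsive genes, 75% of which have
their response attenuated under the drug; the pipeline recovers 401
significant genes and an attenuated fraction of 76.6%, within sampling
error of the planted value. `tol` is the log2 margin around the identity
line that separates genuine attenuation from fold-change estimation noise.

The same flow is available from the shell:

```bash
zfwound simulate counts --out sim/
zfwound atten --counts sim/counts.tsv --meta sim/meta.tsv --out results/
zfwound simulate scene --out scene/
zfwound detect --stack scene/movie.tif --sigma 2 --min-distance 8 \
    --threshold 30 --out det.csv
zfwound track --dets det.csv --max-disp 15 --out tracks.csv
```

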