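"""Synthetic ground-truth data: chemotaxis movies and paired count matrices.

Two generators with fully known truth back every stage of the pipeline:

* :func:`simulate_scene` renders single-channel time-lapse stacks of cells
  performing a wound-biased random walk (von Mises-directed steps toward
  the nearest wound point, truncated-normal speeds, reflecting boundaries),
  drawn as anisotropic Gaussian blobs whose elongation controls the true
  circularity of the equivalent ellipse.
* :func:`simulate_counts` draws negative-binomial RNA-seq-like counts for
  the four-condition design {control, amp, beclo, amp_beclo} x paired
  replicates, with a planted fraction of amputation-responsive genes whose
  response is attenuated by a known factor under the glucocorticoid.

Every operation takes an explicit seed; there is no global RNG state.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ellipe
from scipy.stats import truncnorm

from .geometry import WoundROI

TREATMENTS = ("control", "amp", "beclo", "amp_beclo")

GENE_CLASSES = ("null", "amp_attenuated", "amp_insensitive", "beclo")


def _default_wound(width_px: int = 512, height_px: int = 512) -> WoundROI:
    # amputation edge along the right image border, counting box = right quarter
    return WoundROI(
        region=(0.75 * width_px, 0.0, width_px - 1.0, height_px - 1.0),
        wound=((width_px - 1.0, 0.0), (width_px - 1.0, height_px - 1.0)),
    )


@dataclass
class SceneConfig:
    """Parameters of a simulated wounding time-lapse.

    Defaults emulate the acquisition conditions of the wounding assay this
    package quantifies: a ~330 um field imaged at 0.65 um/px with a ~1 min
    frame interval, a few tens of leukocytes moving at a few um/min with a
    directional bias toward the wound edge.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size: float = 0.65           # um / px
    n_frames: int = 60
    frame_interval: float = 1.0        # min
    n_cells: int = 30
    speed_mean: float = 3.5            # um / min
    speed_sd: float = 1.0              # um / min
    kappa: float = 2.0                 # von Mises concentration; 0 = unbiased
    wound: WoundROI | None = None
    axis_ratio_range: tuple = (1.0, 3.0)
    blob_sigma: float = 3.0            # px
    amplitude: float = 120.0           # peak intensity above background
    background_level: float = 10.0
    noise_sd: float = 2.0
    min_separation_px: float = 0.0     # minimum pairwise distance at t=0
    init_margin_px: float = 0.0        # keep-out border for initial positions
    seed: int = 0

    def __post_init__(self):
        if self.wound is None:
            self.wound = _default_wound(self.width_px, self.height_px)
        if self.pixel_size <= 0:
            raise ValueError("configuration error: pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("configuration error: frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("configuration error: n_frames must be >= 2")
        if self.n_cells < 0:
            raise ValueError("configuration error: n_cells must be >= 0")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("configuration error: speeds must be >= 0")
        if self.kappa < 0:
            raise ValueError("configuration error: kappa must be >= 0")
        lo, hi = self.axis_ratio_range
        if lo < 1.0 or hi < lo:
            raise ValueError("configuration error: axis_ratio_range must be [1, rmax]")


@dataclass
class GroundTruthTrack:
    """True trajectory and shape of one simulated cell."""

    cell_id: int
    xy_um: np.ndarray          # (n_frames, 2)
    orientation: np.ndarray    # (n_frames,) radians, blob long-axis direction
    axis_ratio: np.ndarray     # (n_frames,)
    circularity: np.ndarray    # (n_frames,) true ellipse circularity, in (0, 1]


def ellipse_circularity(axis_ratio) -> np.ndarray:
    """Circularity 4*pi*A/P^2 of an ellipse with the given long/short axis ratio.

    The perimeter uses the exact complete elliptic integral, so the value
    is 1 for ratio 1 and decreases monotonically with elongation.
    """
    r = np.asarray(axis_ratio, dtype=float)
    a = np.sqrt(r)
    b = 1.0 / a
    m = 1.0 - (b / a) ** 2          # squared eccentricity
    perimeter = 4.0 * a * ellipe(m)
    area = np.pi * a * b
    return 4.0 * np.pi * area / perimeter**2


def _reflect(x: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates into [0, hi] by mirror reflection."""
    period = 2.0 * hi
    y = np.mod(x, period)
    return np.where(y > hi, period - y, y)


def _sample_speeds(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd           # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _init_positions(rng, config: SceneConfig) -> np.ndarray:
    w_um = config.width_px * config.pixel_size
    h_um = config.height_px * config.pixel_size
    margin = config.init_margin_px * config.pixel_size
    min_sep = config.min_separation_px * config.pixel_size
    pos = np.empty((config.n_cells, 2))
    placed = 0
    attempts = 0
    while placed < config.n_cells:
        attempts += 1
        if attempts > 20000:
            raise ValueError("configuration error: cannot place cells with the "
                             "requested separation inside the frame")
        cand = np.array([
            rng.uniform(margin, w_um - margin),
            rng.uniform(margin, h_um - margin),
        ])
        if min_sep > 0 and placed:
            if np.min(np.hypot(*(pos[:placed] - cand).T)) < min_sep:
                continue
        pos[placed] = cand
        placed += 1
    return pos


def simulate_tracks(config: SceneConfig, rng: np.random.Generator | None = None):
    """Draw ground-truth trajectories (positions in um) without rendering."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, t = config.n_cells, config.n_frames
    w_um = config.width_px * config.pixel_size
    h_um = config.height_px * config.pixel_size
    wound_um = config.wound.scaled(config.pixel_size)

    xy = np.zeros((t, n, 2))
    theta = np.zeros((t, n))
    if n == 0:
        return []
    xy[0] = _init_positions(rng, config)
    theta[0] = rng.uniform(-np.pi, np.pi, n)

    lo, hi = config.axis_ratio_range
    ratios = rng.uniform(lo, hi, n)

    for f in range(1, t):
        to_wound = wound_um.direction_to_wound(xy[f - 1])
        mu = np.arctan2(to_wound[:, 1], to_wound[:, 0])
        if config.kappa == 0:
            ang = rng.uniform(-np.pi, np.pi, n)
        else:
            ang = rng.vonmises(mu, config.kappa, n)
        speed = _sample_speeds(rng, config.speed_mean, config.speed_sd, n)
        step = speed[:, None] * config.frame_interval * np.column_stack(
            [np.cos(ang), np.sin(ang)])
        nxt = xy[f - 1] + step
        nxt[:, 0] = _reflect(nxt[:, 0], w_um)
        nxt[:, 1] = _reflect(nxt[:, 1], h_um)
        xy[f] = nxt
        theta[f] = ang
    theta[0] = theta[1] if t > 1 else theta[0]

    circ = ellipse_circularity(ratios)
    tracks = []
    for i in range(n):
        tracks.append(GroundTruthTrack(
            cell_id=i,
            xy_um=xy[:, i].copy(),
            orientation=theta[:, i].copy(),
            axis_ratio=np.full(t, ratios[i]),
            circularity=np.full(t, circ[i]),
        ))
    return tracks


def _render_blob(img, cx, cy, amplitude, sigma_major, sigma_minor, theta):
    """Add one anisotropic Gaussian blob in place (local-patch evaluation)."""
    h, w = img.shape
    half = int(np.ceil(4.0 * sigma_major))
    x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
    y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy      # along the long axis
    v = -s * dx + c * dy
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / sigma_major) ** 2 + (v / sigma_minor) ** 2))


def simulate_scene(config: SceneConfig):
    """Render a time-lapse stack plus its ground-truth tracks.

    Returns
    -------
    stack : float32 array, shape (n_frames, height_px, width_px)
    tracks : list of GroundTruthTrack
    """
    rng = np.random.default_rng(config.seed)
    tracks = simulate_tracks(config, rng)
    t = config.n_frames
    stack = np.empty((t, config.height_px, config.width_px), dtype=np.float32)
    for f in range(t):
        img = np.full((config.height_px, config.width_px),
                      config.background_level, dtype=float)
        for tr in tracks:
            r = tr.axis_ratio[f]
            sig_major = config.blob_sigma * np.sqrt(r)
            sig_minor = config.blob_sigma / np.sqrt(r)
            cx = tr.xy_um[f, 0] / config.pixel_size
            cy = tr.xy_um[f, 1] / config.pixel_size
            _render_blob(img, cx, cy, config.amplitude,
                         sig_major, sig_minor, tr.orientation[f])
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, img.shape)
        stack[f] = np.clip(img, 0.0, None)
    return stack, tracks


def tracks_to_dataframe(tracks, pixel_size: float) -> pd.DataFrame:
    """Long-format ground truth: one row per cell per frame."""
    rows = []
    for tr in tracks:
        n = len(tr.xy_um)
        rows.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "frame": np.arange(n),
            "x_um": tr.xy_um[:, 0],
            "y_um": tr.xy_um[:, 1],
            "x_px": tr.xy_um[:, 0] / pixel_size,
            "y_px": tr.xy_um[:, 1] / pixel_size,
            "axis_ratio": tr.axis_ratio,
            "circularity": tr.circularity,
        }))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "frame", "x_um", "y_um",
                                     "x_px", "y_px", "axis_ratio", "circularity"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Count-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Planted-truth negative-binomial counts for the 4-condition design.

    Each gene belongs to exactly one class: ``null`` (no effect),
    ``amp_attenuated`` (responds to amputation; the response is multiplied
    by a factor in [0, 1] under the combined treatment), ``amp_insensitive``
    (responds to amputation; unchanged by the glucocorticoid) or ``beclo``
    (responds to the drug alone, in both drug-containing conditions).
    Pairing is a replicate-specific log-normal offset on the baseline mean,
    shared by the four conditions of that replicate.
    """

    n_genes: int = 2000
    n_reps: int = 3
    baseline_log_mean: float = 5.0    # natural-log mean of the baseline
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05          # NB alpha; 0 -> Poisson limit
    frac_amp_responsive: float = 0.20
    lfc_amp_magnitude: tuple = (1.5, 3.0)   # |log2FC| range for amp genes
    prob_up: float = 0.66
    attenuation_factor_range: tuple = (0.1, 0.5)
    frac_gc_insensitive: float = 0.25       # of the amp-responsive genes
    frac_beclo_responsive: float = 0.05
    lfc_beclo_magnitude: tuple = (1.0, 2.5)
    rep_offset_sd: float = 0.15       # log-normal sigma of replicate offsets
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_amp_responsive", "frac_gc_insensitive",
                     "frac_beclo_responsive", "prob_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"configuration error: {name} must be in [0, 1]")
        if self.frac_amp_responsive + self.frac_beclo_responsive > 1.0:
            raise ValueError("configuration error: gene-class fractions exceed 1")
        lo, hi = self.attenuation_factor_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("configuration error: attenuation_factor_range must "
                             "lie within [0, 1]")
        if self.n_genes < 1 or self.n_reps < 2:
            raise ValueError("configuration error: need n_genes >= 1, n_reps >= 2")
        if self.dispersion < 0:
            raise ValueError("configuration error: dispersion must be >= 0")


def _nb_sample(rng, mean, alpha):
    if alpha <= 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: CountSimConfig):
    """Draw the count matrix, sample metadata and per-gene truth table.

    Returns
    -------
    counts : DataFrame, genes x samples (integer)
    meta : DataFrame with columns sample, treatment, replicate
    truth : DataFrame with columns gene, klass, lfc_amp, lfc_beclo,
        lfc_amp_beclo, attenuation_factor
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = np.array([f"gene{i:05d}" for i in range(g)])

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, g)

    klass = np.full(g, "null", dtype=object)
    order = rng.permutation(g)
    n_amp = int(round(config.frac_amp_responsive * g))
    n_ins = int(round(config.frac_gc_insensitive * n_amp))
    n_bec = int(round(config.frac_beclo_responsive * g))
    amp_idx = order[:n_amp]
    klass[amp_idx] = "amp_attenuated"
    klass[amp_idx[:n_ins]] = "amp_insensitive"
    klass[order[n_amp:n_amp + n_bec]] = "beclo"

    signs = np.where(rng.uniform(size=g) < config.prob_up, 1.0, -1.0)
    lfc_amp = np.zeros(g)
    lfc_beclo = np.zeros(g)
    lfc_combo = np.zeros(g)
    atten = np.full(g, np.nan)

    is_amp = (klass == "amp_attenuated") | (klass == "amp_insensitive")
    lfc_amp[is_amp] = signs[is_amp] * rng.uniform(*config.lfc_amp_magnitude,
                                                  is_amp.sum())
    att_mask = klass == "amp_attenuated"
    atten[att_mask] = rng.uniform(*config.attenuation_factor_range, att_mask.sum())
    lfc_combo[att_mask] = lfc_amp[att_mask] * atten[att_mask]
    ins_mask = klass == "amp_insensitive"
    lfc_combo[ins_mask] = lfc_amp[ins_mask]

    bec_mask = klass == "beclo"
    lfc_beclo[bec_mask] = signs[bec_mask] * rng.uniform(*config.lfc_beclo_magnitude,
                                                        bec_mask.sum())
    lfc_combo[bec_mask] = lfc_beclo[bec_mask]   # the drug is present in the combo

    offsets = rng.lognormal(0.0, config.rep_offset_sd, config.n_reps)
    lfc_by_treatment = {
        "control": np.zeros(g),
        "amp": lfc_amp,
        "beclo": lfc_beclo,
        "amp_beclo": lfc_combo,
    }

    samples, columns, meta_rows = [], [], []
    for treatment in TREATMENTS:
        for rep in range(1, config.n_reps + 1):
            mu = baseline * offsets[rep - 1] * 2.0 ** lfc_by_treatment[treatment]
            columns.append(_nb_sample(rng, mu, config.dispersion))
            name = f"{treatment}_r{rep}"
            samples.append(name)
            meta_rows.append({"sample": name, "treatment": treatment,
                              "replicate": rep})

    counts = pd.DataFrame(np.column_stack(columns), index=genes, columns=samples)
    counts.index.name = "gene"
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame({
        "gene": genes,
        "klass": klass,
        "lfc_amp": lfc_amp,
        "lfc_beclo": lfc_beclo,
        "lfc_amp_beclo": lfc_combo,
        "attenuation_factor": atten,
    })
    return counts, meta, truth
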