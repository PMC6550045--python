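"""Migration read-outs: ROI counts, step velocities and 8-bin directionality.

Angles are measured per track step, relative to the unit vector from the
step's start point toward the nearest point of the wound geometry; bin 0
covers (-22.5 deg, 22.5 deg] (movement toward the wound), bin k covers
(45k - 22.5, 45k + 22.5].  Hour h spans [60(h-1), 60h) minutes of the
recording.  Zero-displacement steps carry no angle: they are excluded from
the angular bins and reported separately as an immobile fraction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import WoundROI, relative_angle_deg
from .stats_core import anova_lsd

STEP_COLUMNS = ["track_id", "t_min", "dt_min", "dx_um", "dy_um",
                "d_um", "v_um_min", "theta_deg", "gap"]


def hour_of(t_min) -> np.ndarray:
    """1-based hour label of a time in minutes: hour h = [60(h-1), 60h)."""
    return np.floor(np.asarray(t_min, dtype=float) / 60.0).astype(int) + 1


def angle_bin(theta_deg) -> np.ndarray:
    """8-bin directionality category of an angle in (-180, 180] degrees.

    Bin k covers the half-open arc (45k - 22.5, 45k + 22.5]; bin 0 points
    toward the wound, so +22.5 falls in bin 0 and -22.5 in bin 7.
    """
    theta = np.asarray(theta_deg, dtype=float)
    theta = np.where(theta <= -180.0, theta + 360.0, theta)
    return (np.ceil((theta - 22.5) / 45.0).astype(int)) % 8


def count_in_roi(detections: pd.DataFrame, roi: WoundROI, frame_interval: float,
                 frame_shape: tuple | None = None):
    """Boundary-inclusive per-frame centroid counts in the counting region.

    Returns ``(per_frame, per_hour)``: a Series of counts indexed by frame
    and a DataFrame with the mean count over the frames of each hour.
    ``frame_shape=(height, width)`` enables a configuration check that the
    region lies inside the frame.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if frame_shape is not None:
        roi.validate_in_frame(frame_shape[1], frame_shape[0])
    if detections.empty:
        per_frame = pd.Series(dtype=int, name="count")
        return per_frame, pd.DataFrame(columns=["hour", "mean_count", "n_frames"])
    inside = roi.contains(detections[["x", "y"]].to_numpy(float))
    per_frame = (
        detections.assign(inside=inside)
        .groupby("frame")["inside"].sum().astype(int).rename("count")
    )
    hours = hour_of(per_frame.index.to_numpy() * frame_interval)
    per_hour = (
        pd.DataFrame({"hour": hours, "count": per_frame.to_numpy()})
        .groupby("hour")
        .agg(mean_count=("count", "mean"), n_frames=("count", "size"))
        .reset_index()
    )
    return per_frame, per_hour


def step_vectors(tracks: pd.DataFrame, pixel_size: float, frame_interval: float,
                 wound: WoundROI | None = None) -> pd.DataFrame:
    """Per-step displacement, velocity and wound-relative angle.

    Track coordinates are in pixels; displacements are converted with
    ``pixel_size`` (um/px) and times with ``frame_interval`` (min).  Steps
    spanning a detection gap are divided by the elapsed time.  ``theta_deg``
    is NaN for zero-displacement steps or when no wound is supplied.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("pixel_size and frame_interval must be > 0")
    if tracks.empty:
        return pd.DataFrame(columns=STEP_COLUMNS)
    rows = []
    for tid, g in tracks.sort_values(["track_id", "frame"]).groupby("track_id"):
        if len(g) < 2:
            continue
        xy = g[["x", "y"]].to_numpy(float) * pixel_size
        frames = g["frame"].to_numpy()
        d_xy = np.diff(xy, axis=0)
        dt = np.diff(frames) * frame_interval
        d = np.hypot(d_xy[:, 0], d_xy[:, 1])
        theta = np.full(len(d), np.nan)
        if wound is not None:
            wound_um = wound.scaled(pixel_size)
            ref = wound_um.direction_to_wound(xy[:-1])
            moving = d > 0
            theta[moving] = relative_angle_deg(d_xy[moving], ref[moving])
        rows.append(pd.DataFrame({
            "track_id": tid,
            "t_min": frames[:-1] * frame_interval,
            "dt_min": dt,
            "dx_um": d_xy[:, 0],
            "dy_um": d_xy[:, 1],
            "d_um": d,
            "v_um_min": d / dt,
            "theta_deg": theta,
            "gap": np.diff(frames) > 1,
        }))
    if not rows:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def step_velocities(tracks: pd.DataFrame, pixel_size: float,
                    frame_interval: float, wound: WoundROI | None = None):
    """Step vectors plus the per-hour mean velocity.

    The hourly mean averages over all steps whose start time falls in that
    hour.  Returns ``(steps, per_hour)``.
    """
    steps = step_vectors(tracks, pixel_size, frame_interval, wound)
    if steps.empty:
        return steps, pd.DataFrame(columns=["hour", "mean_velocity", "n_steps"])
    hours = hour_of(steps["t_min"])
    per_hour = (
        pd.DataFrame({"hour": hours, "v": steps["v_um_min"]})
        .groupby("hour")
        .agg(mean_velocity=("v", "mean"), n_steps=("v", "size"))
        .reset_index()
    )
    return steps, per_hour


@dataclass
class DirectionalityHistogram:
    """8-bin angular distribution of steps within a time window."""

    fractions: np.ndarray       # length 8, sums to 1 when n_steps > 0
    n_steps: int                # steps with nonzero displacement in window
    n_zero: int                 # immobile (zero-displacement) steps
    window: tuple               # (t0_min, t1_min), half-open
    empty: bool


def directionality(steps: pd.DataFrame, window: tuple) -> DirectionalityHistogram:
    """Bin wound-relative step angles into the 8 directionality categories.

    ``window = (t0, t1)`` selects steps with start time in [t0, t1)
    minutes.  Fractions are normalized over the binned (moving) steps;
    zero-displacement steps are counted separately.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must be a non-empty time interval")
    sel = steps[(steps["t_min"] >= t0) & (steps["t_min"] < t1)]
    moving = sel[sel["d_um"] > 0]
    n_zero = int((sel["d_um"] == 0).sum())
    if moving.empty or moving["theta_deg"].isna().all():
        return DirectionalityHistogram(
            fractions=np.zeros(8), n_steps=0, n_zero=n_zero,
            window=(t0, t1), empty=True)
    theta = moving["theta_deg"].dropna().to_numpy()
    bins = angle_bin(theta)
    counts = np.bincount(bins, minlength=8).astype(float)
    return DirectionalityHistogram(
        fractions=counts / counts.sum(), n_steps=int(counts.sum()),
        n_zero=n_zero, window=(t0, t1), empty=False)


def directionality_table(steps: pd.DataFrame, frame_interval: float,
                         n_frames: int) -> pd.DataFrame:
    """Directionality histogram per recording hour (long output table)."""
    total_min = n_frames * frame_interval
    rows = []
    h = 1
    while (h - 1) * 60.0 < total_min:
        hist = directionality(steps, ((h - 1) * 60.0, h * 60.0))
        row = {"hour": h, "n_steps": hist.n_steps, "n_zero": hist.n_zero,
               "empty": hist.empty}
        row.update({f"bin{k}": hist.fractions[k] for k in range(8)})
        rows.append(row)
        h += 1
    return pd.DataFrame(rows)


def compare_hourly(data: pd.DataFrame, value: str = "value"):
    """Per-hour one-way ANOVA with Fisher-LSD pairwise tests across groups.

    ``data`` is long-format with columns group, replicate, hour and the
    value column (one replicate-level hourly mean per row).  Every group
    needs >= 2 replicates per hour.  Returns ``(summary, pairwise)``
    DataFrames; the omnibus F, its p and the unadjusted LSD p-values follow
    the named procedure.
    """
    required = {"group", "replicate", "hour", value}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    summaries, pairwise_rows = [], []
    for hour, g in data.groupby("hour"):
        labels = sorted(g["group"].unique())
        groups = [g.loc[g["group"] == lab, value].to_numpy() for lab in labels]
        res = anova_lsd(groups, labels=labels)
        row = {"hour": hour, "F": res.f_statistic, "p": res.p_value,
               "degenerate": res.degenerate}
        row.update({f"mean_{lab}": res.group_means[lab] for lab in labels})
        summaries.append(row)
        pw = res.pairwise.copy()
        pw.insert(0, "hour", hour)
        pairwise_rows.append(pw)
    return pd.DataFrame(summaries), pd.concat(pairwise_rows, ignore_index=True)
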