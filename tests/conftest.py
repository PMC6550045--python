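import numpy as np
import pandas as pd
import pytest

from zfwound import simgen


@pytest.fixture(scope="session")
def recovery_scene():
    """High-SNR 30-cell/60-frame scene used by the recovery checks.

    Unbiased walk (kappa 0) with initial 15 px separation; speed 5 +/- 1
    um/min at 0.65 um/px and 1 min interval.
    """
    config = simgen.SceneConfig(
        n_cells=30, n_frames=60, speed_mean=5.0, speed_sd=1.0,
        kappa=0.0, min_separation_px=15, seed=3,
    )
    stack, tracks = simgen.simulate_scene(config)
    truth = simgen.tracks_to_dataframe(tracks, config.pixel_size)
    return config, stack, truth


@pytest.fixture(scope="session")
def null_counts():
    """Simulated count matrix with every effect switched off (null genes only)."""
    config = simgen.CountSimConfig(
        n_genes=2000, frac_amp_responsive=0.0, frac_beclo_responsive=0.0,
        seed=11,
    )
    counts, meta, truth = simgen.simulate_counts(config)
    return counts, meta, truth


def match_detections(dets: pd.DataFrame, truth: pd.DataFrame, n_frames: int,
                     radius: float = 3.0):
    """Greedy-optimal per-frame matching of detections to ground truth.

    Returns (true positives, false positives, false negatives) at the
    given matching radius in px.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    tp = fp = fn = 0
    for f in range(n_frames):
        d = dets.loc[dets["frame"] == f, ["x", "y"]].to_numpy(float)
        t = truth.loc[truth["frame"] == f, ["x_px", "y_px"]].to_numpy(float)
        if len(d) == 0:
            fn += len(t)
            continue
        if len(t) == 0:
            fp += len(d)
            continue
        dist = cdist(t, d)
        rows, cols = linear_sum_assignment(dist)
        m = int((dist[rows, cols] <= radius).sum())
        tp += m
        fn += len(t) - m
        fp += len(d) - m
    return tp, fp, fn


def link_recovery(tracks: pd.DataFrame, truth: pd.DataFrame, n_frames: int,
                  radius: float = 3.0) -> float:
    """Fraction of true frame-to-frame links present in the built tracks."""
    recovered = total = 0
    for f in range(n_frames - 1):
        t0 = truth[truth["frame"] == f]
        t1 = truth[truth["frame"] == f + 1]
        a = tracks[tracks["frame"] == f]
        b = tracks[tracks["frame"] == f + 1]
        merged = a.merge(b, on="track_id", suffixes=("0", "1"))
        for cid in t0["cell_id"]:
            p0 = t0.loc[t0["cell_id"] == cid, ["x_px", "y_px"]].to_numpy(float)[0]
            p1 = t1.loc[t1["cell_id"] == cid, ["x_px", "y_px"]].to_numpy(float)[0]
            total += 1
            if merged.empty:
                continue
            d0 = np.hypot(merged["x0"] - p0[0], merged["y0"] - p0[1])
            d1 = np.hypot(merged["x1"] - p1[0], merged["y1"] - p1[1])
            if bool(((d0 <= radius) & (d1 <= radius)).any()):
                recovered += 1
    return recovered / total
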