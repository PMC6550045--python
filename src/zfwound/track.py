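"""Frame-to-frame linking of detections into trajectories.

Linking solves a gated rectangular assignment problem per frame pair:
the one-to-one assignment minimizing total displacement among pairs
within ``max_disp`` (Hungarian algorithm; a greedy nearest-neighbour
option exists for speed).  Tracks tolerate short detection drop-outs:
a track unmatched for up to ``max_gap`` frames may be re-joined within a
displacement gate that scales with the gap length.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

TRACK_COLUMNS = ["track_id", "frame", "x", "y", "gap"]

_BIG = 1e12


def link_frames(xy_a, xy_b, max_disp: float, method: str = "hungarian"):
    """Match points of frame A to points of frame B.

    Returns an integer array of (index_a, index_b) pairs whose distance is
    <= max_disp, minimizing the total displacement of the matched pairs
    (global optimum for ``method="hungarian"``).  Unmatched points are
    simply absent from the result.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    xy_a = np.asarray(xy_a, dtype=float).reshape(-1, 2)
    xy_b = np.asarray(xy_b, dtype=float).reshape(-1, 2)
    if len(xy_a) == 0 or len(xy_b) == 0:
        return np.empty((0, 2), dtype=int)
    dist = cdist(xy_a, xy_b)
    gate = np.full_like(dist, max_disp)
    return _gated_assignment(dist, gate, method)


def _gated_assignment(dist, gate, method="hungarian"):
    """Assignment on a distance matrix with per-pair gates."""
    allowed = dist <= gate
    if not allowed.any():
        return np.empty((0, 2), dtype=int)
    if method == "hungarian":
        cost = np.where(allowed, dist, _BIG)
        rows, cols = linear_sum_assignment(cost)
        keep = allowed[rows, cols]
        return np.column_stack([rows[keep], cols[keep]])
    if method == "greedy":
        pairs = []
        cost = np.where(allowed, dist, np.inf)
        cost = cost.copy()
        while np.isfinite(cost).any():
            i, j = np.unravel_index(np.argmin(cost), cost.shape)
            pairs.append((i, j))
            cost[i, :] = np.inf
            cost[:, j] = np.inf
        return np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    raise ValueError(f"unknown linking method: {method!r}")


def build_tracks(detections: pd.DataFrame, max_disp: float, max_gap: int = 2,
                 method: str = "hungarian") -> pd.DataFrame:
    """Link a detection table (columns frame, x, y) into tracks.

    Track ids are assigned in order of first appearance.  A track missing
    from up to ``max_gap`` consecutive frames may be continued if a
    detection lies within ``max_disp * (gap + 1)`` of its last position;
    the re-joining row carries ``gap=True``.

    Returns a DataFrame with columns track_id, frame, x, y, gap sorted by
    (track_id, frame).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if detections.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    detections = detections.sort_values("frame", kind="stable")
    frames = detections["frame"].to_numpy()
    first, last = int(frames.min()), int(frames.max())

    rows = []                      # (track_id, frame, x, y, gap)
    active = {}                    # track_id -> (last_frame, x, y)
    next_id = 0
    by_frame = {int(f): g[["x", "y"]].to_numpy(float)
                for f, g in detections.groupby("frame")}

    for f in range(first, last + 1):
        # retire tracks that can no longer be continued
        active = {tid: s for tid, s in active.items()
                  if f - s[0] - 1 <= max_gap}
        dets = by_frame.get(f)
        if dets is None or len(dets) == 0:
            continue
        matched_det = np.zeros(len(dets), dtype=bool)
        if active:
            tids = sorted(active)
            last_xy = np.array([[active[t][1], active[t][2]] for t in tids])
            gaps = np.array([f - active[t][0] - 1 for t in tids])
            dist = cdist(last_xy, dets)
            gate = (max_disp * (gaps + 1))[:, None] * np.ones((1, len(dets)))
            pairs = _gated_assignment(dist, gate, method)
            for ti, dj in pairs:
                tid = tids[ti]
                x, y = dets[dj]
                rows.append((tid, f, x, y, gaps[ti] > 0))
                active[tid] = (f, x, y)
                matched_det[dj] = True
        for dj in np.nonzero(~matched_det)[0]:
            x, y = dets[dj]
            rows.append((next_id, f, x, y, False))
            active[next_id] = (f, x, y)
            next_id += 1

    out = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return out.sort_values(["track_id", "frame"], ignore_index=True)
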