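"""Wound geometry: counting regions and the wound reference used for directionality.

The counting region (the dashed box of the recruitment assay) is an
axis-aligned rectangle or an arbitrary polygon in pixel coordinates.  The
wound itself is represented by a point or a line segment (the amputation
edge); directional read-outs are measured relative to the unit vector from
a cell's position toward the *nearest* point of the wound geometry.

Coordinates are 0-based, pixel-center, x to the right and y down (image
convention).  All geometry here is in pixels; callers convert to microns.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely


@dataclass
class WoundROI:
    """Counting region plus wound reference geometry.

    Parameters
    ----------
    region:
        Either ``(x0, y0, x1, y1)`` for an axis-aligned rectangle or an
        ``(N, 2)`` array of polygon vertices, in pixels.
    wound:
        Either ``(x, y)`` for a point or ``((x1, y1), (x2, y2))`` for a
        line segment, in pixels.
    """

    region: tuple | np.ndarray
    wound: tuple | np.ndarray

    _polygon: object = field(init=False, repr=False, default=None)

    def __post_init__(self):
        region = np.asarray(self.region, dtype=float)
        if region.ndim == 1:
            if region.shape != (4,):
                raise ValueError("rectangle region must be (x0, y0, x1, y1)")
            x0, y0, x1, y1 = region
            if x0 == x1 or y0 == y1:
                raise ValueError("degenerate rectangle region")
            self.region = (min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
        else:
            if region.ndim != 2 or region.shape[0] < 3 or region.shape[1] != 2:
                raise ValueError("polygon region must be an (N>=3, 2) array")
            self.region = region
            self._polygon = shapely.Polygon(region)
            if self._polygon.area == 0:
                raise ValueError("degenerate polygon region")

        wound = np.asarray(self.wound, dtype=float)
        if wound.shape == (2,):
            self.wound = wound
        elif wound.shape == (2, 2):
            self.wound = wound
        else:
            raise ValueError("wound must be a point (x, y) or a segment ((x1, y1), (x2, y2))")

    # -- region ---------------------------------------------------------

    @property
    def is_rectangle(self) -> bool:
        return self._polygon is None

    def contains(self, xy) -> np.ndarray:
        """Boundary-inclusive membership test for an (n, 2) array of points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.is_rectangle:
            x0, y0, x1, y1 = self.region
            return (
                (xy[:, 0] >= x0) & (xy[:, 0] <= x1)
                & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
            )
        pts = shapely.points(xy)
        return shapely.covers(self._polygon, pts)

    def validate_in_frame(self, width_px: float, height_px: float) -> None:
        """Raise if the counting region extends outside the image frame."""
        if self.is_rectangle:
            x0, y0, x1, y1 = self.region
            xs = np.array([x0, x1])
            ys = np.array([y0, y1])
        else:
            xs = self.region[:, 0]
            ys = self.region[:, 1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > width_px - 1 or ys.max() > height_px - 1:
            raise ValueError("counting region lies (partly) outside the image frame")

    # -- wound reference -------------------------------------------------

    def nearest_wound_point(self, xy) -> np.ndarray:
        """Nearest point of the wound geometry for each query point."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        wound = np.asarray(self.wound, dtype=float)
        if wound.shape == (2,):
            return np.broadcast_to(wound, xy.shape).copy()
        a, b = wound
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            return np.broadcast_to(a, xy.shape).copy()
        t = np.clip((xy - a) @ ab / denom, 0.0, 1.0)
        return a + t[:, None] * ab

    def direction_to_wound(self, xy) -> np.ndarray:
        """Unit vectors from each point toward the nearest wound point.

        Points lying exactly on the wound get a zero vector.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = self.nearest_wound_point(xy) - xy
        norm = np.hypot(d[:, 0], d[:, 1])
        out = np.zeros_like(d)
        ok = norm > 0
        out[ok] = d[ok] / norm[ok, None]
        return out

    def scaled(self, factor: float) -> "WoundROI":
        """Same geometry with all coordinates multiplied by ``factor``."""
        if self.is_rectangle:
            region = tuple(np.asarray(self.region) * factor)
        else:
            region = np.asarray(self.region) * factor
        return WoundROI(region=region, wound=np.asarray(self.wound) * factor)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        region = self.region if self.is_rectangle else self.region.tolist()
        return {"region": list(np.asarray(region).reshape(-1)) if self.is_rectangle else region,
                "wound": np.asarray(self.wound).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "WoundROI":
        region = np.asarray(d["region"], dtype=float)
        if region.size == 4 and region.ndim == 1:
            region = tuple(region)
        return cls(region=region, wound=np.asarray(d["wound"], dtype=float))


def relative_angle_deg(vec, ref) -> np.ndarray:
    """Signed angle in degrees, in (-180, 180], from ``ref`` to ``vec``.

    Both arguments are (n, 2) arrays; the angle is measured in the image
    plane (a positive angle is a rotation from ref toward +y).
    """
    vec = np.atleast_2d(np.asarray(vec, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    cross = ref[:, 0] * vec[:, 1] - ref[:, 1] * vec[:, 0]
    dot = ref[:, 0] * vec[:, 0] + ref[:, 1] * vec[:, 1]
    ang = np.degrees(np.arctan2(cross, dot))
    # atan2 yields [-180, 180]; fold -180 onto +180 for the (-180, 180] convention
    ang[ang <= -180.0] = 180.0
    return ang
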