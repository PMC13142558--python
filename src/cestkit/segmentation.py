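"""Manual polygon ROIs and semi-automated six-segment LV segmentation.

The left-ventricle workflow takes user-drawn epicardial/endocardial
contours plus the two RV insertion points and produces the six standard
mid-ventricular segments (anteroseptal, inferoseptal, anterior,
anterolateral, inferolateral, inferior) by angular sectoring around the LV
centroid.  Images are assumed to follow radiological convention for
cardiac short-axis slices (row index increasing downward).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

LV_LABELS = (
    "anteroseptal",
    "inferoseptal",
    "anterior",
    "anterolateral",
    "inferolateral",
    "inferior",
)


@dataclass
class SegmentSet:
    """Ordered label -> boolean-mask map; masks are pairwise disjoint."""

    masks: Dict[str, np.ndarray]
    kind: str = "manual"  # or "lv_auto"

    def __post_init__(self):
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        labels = list(self.masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"segments {a!r} and {b!r} overlap")

    def union(self) -> np.ndarray:
        out = None
        for m in self.masks.values():
            out = m.copy() if out is None else (out | m)
        return out

    def __iter__(self):
        return iter(self.masks.items())

    def __len__(self):
        return len(self.masks)


def polygon_mask(vertices: Sequence[Tuple[float, float]],
                 shape: Tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon: pixel centers strictly inside are True.

    Vertices are (x, y) = (col, row) pixel coordinates; pixel (r, c) has
    its center at (c, r).  The even-odd (crossing-number) fill rule is
    used, so self-intersecting outlines behave predictably.  A degenerate
    zero-area polygon yields an empty mask with a warning.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    # shoelace area; zero means degenerate
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0:
        warnings.warn("degenerate zero-area polygon; empty mask returned")
        return np.zeros(shape, dtype=bool)

    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols, dtype=float),
                         np.arange(rows, dtype=float))
    px, py = cc.ravel(), rr.ravel()
    inside = np.zeros(px.size, dtype=bool)
    n = v.shape[0]
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        if y0 == y1:
            continue
        # half-open edge rule avoids double counting at shared vertices
        crosses = ((y0 <= py) != (y1 <= py))
        with np.errstate(divide="ignore", invalid="ignore"):
            xi = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < xi)
    return inside.reshape(shape)


@dataclass
class LVGeometry:
    """User-drawn LV contours and RV insertion points, (x, y) pixel coords."""

    epicardium: np.ndarray
    endocardium: np.ndarray
    anterior_insertion: Tuple[float, float]
    inferior_insertion: Tuple[float, float]

    def __post_init__(self):
        self.epicardium = np.asarray(self.epicardium, dtype=float)
        self.endocardium = np.asarray(self.endocardium, dtype=float)
        if tuple(self.anterior_insertion) == tuple(self.inferior_insertion):
            raise ValueError("insertion points must be distinct")

    def to_json(self) -> str:
        return json.dumps({
            "epicardium": self.epicardium.tolist(),
            "endocardium": self.endocardium.tolist(),
            "anterior_insertion": list(self.anterior_insertion),
            "inferior_insertion": list(self.inferior_insertion),
        })

    @classmethod
    def from_json(cls, s: str) -> "LVGeometry":
        d = json.loads(s)
        return cls(
            epicardium=np.asarray(d["epicardium"]),
            endocardium=np.asarray(d["endocardium"]),
            anterior_insertion=tuple(d["anterior_insertion"]),
            inferior_insertion=tuple(d["inferior_insertion"]),
        )


def _angles_deg(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """CCW angle in [0, 360) in the display frame (y up = toward row 0)."""
    return np.degrees(np.arctan2(y, x)) % 360.0


def lv_segments(geom: LVGeometry, shape: Tuple[int, int],
                insertion_tol_px: float = 3.0) -> SegmentSet:
    """Partition the LV myocardium into the six standard segments.

    The LV mask is the epicardial minus the endocardial polygon area.  All
    coordinates are re-centered on the LV-mask centroid; per-pixel angles
    come from the two-argument arctangent and the frame is rotated so the
    inferior insertion point sits at 0°, with angles increasing toward the
    anterior insertion point.  The inferior-to-anterior arc with span
    < 180° is the septum (two equal-angle halves: inferoseptal adjacent to
    the inferior point, anteroseptal adjacent to the anterior point); the
    remaining arc is the free wall in four equal-angle quarters ordered
    anterior, anterolateral, inferolateral, inferior from the anterior
    point.  Sectors are half-open [start, end) so boundary pixels are
    assigned deterministically.
    """
    epi = polygon_mask(geom.epicardium, shape)
    endo = polygon_mask(geom.endocardium, shape)
    if not np.all(epi | ~endo == np.ones(shape, bool)) or not endo.any():
        # endocardium must sit inside epicardium
        if np.any(endo & ~epi):
            raise ValueError("endocardium must lie inside epicardium")
    lv = epi & ~endo
    if not lv.any():
        raise ValueError("empty LV mask")

    rr, cc = np.nonzero(lv)
    cy, cx = rr.mean(), cc.mean()

    # insertion points must sit near the annulus
    for label, (ix, iy) in (("anterior", geom.anterior_insertion),
                            ("inferior", geom.inferior_insertion)):
        d = np.sqrt((rr - iy) ** 2 + (cc - ix) ** 2).min()
        if d > insertion_tol_px:
            raise ValueError(
                f"{label} insertion point is {d:.1f} px from the LV annulus"
            )

    # centered display-frame coordinates (y up)
    x = cc - cx
    y = cy - rr
    ang = _angles_deg(x, y)
    a_inf = _angles_deg(
        np.array([geom.inferior_insertion[0] - cx]),
        np.array([cy - geom.inferior_insertion[1]]),
    )[0]
    a_ant = _angles_deg(
        np.array([geom.anterior_insertion[0] - cx]),
        np.array([cy - geom.anterior_insertion[1]]),
    )[0]

    phi = (ang - a_inf) % 360.0
    phi_a = (a_ant - a_inf) % 360.0
    if phi_a == 0:
        raise ValueError("insertion points are angularly coincident")
    if phi_a > 180.0:
        # traverse the short (septal) arc: mirror the angular direction
        phi = (-phi) % 360.0
        phi_a = 360.0 - phi_a

    half = phi_a / 2.0
    q = (360.0 - phi_a) / 4.0
    edges = {
        "inferoseptal": (0.0, half),
        "anteroseptal": (half, phi_a),
        "anterior": (phi_a, phi_a + q),
        "anterolateral": (phi_a + q, phi_a + 2 * q),
        "inferolateral": (phi_a + 2 * q, phi_a + 3 * q),
        "inferior": (phi_a + 3 * q, 360.0),
    }
    masks = {}
    for label in LV_LABELS:
        lo, hi = edges[label]
        sel = (phi >= lo) & (phi < hi)
        if hi == 360.0:
            sel |= phi >= hi  # fold numerical 360.0 back into the last sector
        m = np.zeros(shape, dtype=bool)
        m[rr[sel], cc[sel]] = True
        masks[label] = m
    return SegmentSet(masks=masks, kind="lv_auto")
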