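"""LV-centric polar frame, 6-segment model, and strain summarization.

The mid-ventricular myocardium is split into six 60-degree arcs named, in
order around the ring: anterior, antero-septal, infero-septal, inferior,
infero-lateral, antero-lateral.  The angular anchor is a configuration
input (clinically set from the RV insertion point); the synthetic phantom
uses offset 0, which centers the anterior arc on the image-up direction.
Note that segmental values (unlike the global mean) depend on this offset.

Coordinates are (row, col) in physical mm; "image up" is the direction of
decreasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .strain import StrainTensorField

__all__ = [
    "SEGMENT_NAMES",
    "SegmentModel",
    "StrainCurves",
    "estimate_center",
    "polar_basis",
    "assign_segments",
    "summarize_strain",
    "peak_strain",
]

SEGMENT_NAMES = (
    "anterior",
    "antero-septal",
    "infero-septal",
    "inferior",
    "infero-lateral",
    "antero-lateral",
)

# pixels closer than this to the LV center have no defined polar basis
_CENTER_TOL_MM = 1e-9


@dataclass
class SegmentModel:
    """Angular partition of the short-axis ring into the 6 named segments.

    Segment k spans [offset + 60k - 30, offset + 60k + 30) degrees, i.e.
    each arc is centered on offset + 60k, closed on its lower bound.  A
    full-turn change of offset leaves every assignment unchanged.
    """

    angular_offset_deg: float = 0.0
    names: tuple = field(default=SEGMENT_NAMES)

    def __post_init__(self):
        if tuple(self.names) != SEGMENT_NAMES:
            raise ValueError("segment names and order are fixed")


def estimate_center(mask, pixel_spacing=None) -> np.ndarray:
    """Centroid of the myocardial mask in physical (row, col) mm coordinates."""
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not arr.any():
        raise ValueError("empty mask")
    if pixel_spacing is None:
        pixel_spacing = getattr(mask, "pixel_spacing", (1.0, 1.0))
    px = np.atleast_1d(np.asarray(pixel_spacing, dtype=float))
    if px.size == 1:
        px = np.repeat(px, 2)
    rows, cols = np.nonzero(arr)
    return np.array([rows.mean() * px[0], cols.mean() * px[1]])


def polar_basis(center, point) -> tuple[np.ndarray, np.ndarray]:
    """Local radial and circumferential unit vectors at ``point``.

    e_r points away from the center; e_c is e_r rotated a quarter turn
    ((x, y) -> (-y, x)).  Since strain projections are quadratic in the
    direction, the sense of the quarter turn does not affect Ecc.
    """
    center = np.asarray(center, dtype=float)
    point = np.asarray(point, dtype=float)
    d = point - center
    norm = np.linalg.norm(d)
    if norm <= _CENTER_TOL_MM:
        raise ValueError("point coincides with the center")
    e_r = d / norm
    e_c = np.array([-e_r[1], e_r[0]])
    return e_r, e_c


def _angles_deg(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Polar angle measured from image-up (decreasing row), one turn = 360."""
    d = np.atleast_2d(points) - center
    return np.degrees(np.arctan2(-d[:, 1], -d[:, 0]))


def assign_segments(points, center, model: Optional[SegmentModel] = None) -> np.ndarray:
    """Segment index (0..5, order of SEGMENT_NAMES) for each point."""
    if model is None:
        model = SegmentModel()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.asarray(center, dtype=float)
    r = np.linalg.norm(points - center, axis=1)
    if np.any(r <= _CENTER_TOL_MM):
        raise ValueError("point coincides with the center")
    theta = _angles_deg(points, center)
    rel = np.mod(theta - model.angular_offset_deg + 30.0, 360.0)
    return np.minimum((rel // 60.0).astype(int), 5)


@dataclass
class StrainCurves:
    """Global and per-segment circumferential strain over the cine cycle (percent)."""

    frames: np.ndarray  # (T,) frame indices
    global_pct: np.ndarray  # (T,)
    segment_pct: np.ndarray  # (T, 6); NaN where a segment has no pixels
    pixel_counts: np.ndarray  # (6,)
    time_ms: Optional[np.ndarray] = None
    segment_names: tuple = SEGMENT_NAMES

    @property
    def peak_global_pct(self) -> float:
        return peak_strain(self.global_pct)

    @property
    def peak_segment_pct(self) -> dict:
        out = {}
        for k, name in enumerate(self.segment_names):
            col = self.segment_pct[:, k]
            out[name] = peak_strain(col) if self.pixel_counts[k] > 0 else None
        return out

    @property
    def present_segments(self) -> list:
        return [n for k, n in enumerate(self.segment_names) if self.pixel_counts[k] > 0]


def _pixel_ecc(tensor_field: StrainTensorField, center: np.ndarray) -> np.ndarray:
    d = tensor_field.points_mm - center
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm <= _CENTER_TOL_MM):
        raise ValueError("mask pixel coincides with the LV center")
    e_r = d / norm[:, None]
    e_c = np.stack([-e_r[:, 1], e_r[:, 0]], axis=1)
    return np.einsum("ni,nij,nj->n", e_c, tensor_field.E, e_c)


def summarize_strain(
    tensor_fields: Sequence[StrainTensorField],
    center,
    model: Optional[SegmentModel] = None,
) -> StrainCurves:
    """Per-frame global and segmental mean Ecc (percent) and pixel bookkeeping.

    All frames must share the same reference-mask pixel set.  Segments with
    no pixels are reported as absent (NaN columns, zero count), never as
    zero strain.  The global mean is always the pixel-count-weighted mean
    of the segment means.
    """
    if len(tensor_fields) == 0:
        raise ValueError("need at least one frame of strain tensors")
    if model is None:
        model = SegmentModel()
    center = np.asarray(center, dtype=float)
    pts = tensor_fields[0].points_mm
    for tf in tensor_fields[1:]:
        if tf.points_mm.shape != pts.shape or not np.allclose(tf.points_mm, pts):
            raise ValueError("all frames must share the reference mask pixels")
    labels = assign_segments(pts, center, model)
    counts = np.bincount(labels, minlength=6)

    n_frames = len(tensor_fields)
    global_pct = np.empty(n_frames)
    segment_pct = np.full((n_frames, 6), np.nan)
    frames = np.empty(n_frames, dtype=int)
    for i, tf in enumerate(tensor_fields):
        ecc = _pixel_ecc(tf, center) * 100.0
        frames[i] = tf.frame_index
        global_pct[i] = ecc.mean()
        for k in range(6):
            if counts[k] > 0:
                segment_pct[i, k] = ecc[labels == k].mean()
    return StrainCurves(
        frames=frames,
        global_pct=global_pct,
        segment_pct=segment_pct,
        pixel_counts=counts,
    )


def peak_strain(curve) -> float:
    """Most negative value over the cycle (shortening is negative)."""
    curve = np.asarray(curve, dtype=float)
    curve = curve[~np.isnan(curve)]
    if curve.size == 0:
        raise ValueError("empty strain curve")
    return float(curve.min())
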