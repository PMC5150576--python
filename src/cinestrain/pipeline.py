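"""End-to-end deformation-tracking pipeline: track -> strain -> summarize."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ffd import ControlPointGrid, RegistrationConfig, track_sequence
from .geometry import SegmentModel, StrainCurves, estimate_center, summarize_strain
from .io import CineSeries, MyocardialMask
from .strain import StrainTensorField, strain_tensor_field

__all__ = ["StrainResult", "compute_strain"]


@dataclass
class StrainResult:
    """Everything one tracking run produces."""

    curves: StrainCurves
    tensor_fields: list  # per-frame StrainTensorField on the mask
    grids: list  # per-frame ControlPointGrid
    center_mm: np.ndarray
    registration_info: list  # per-frame optimizer diagnostics
    config: RegistrationConfig

    def jacobian_health(self) -> dict:
        """Fraction of mask pixels with det F > 0, worst over frames."""
        fractions = [float(np.mean(tf.det_F > 0)) for tf in self.tensor_fields]
        return {
            "min_positive_detF_fraction": min(fractions),
            "per_frame_positive_detF_fraction": fractions,
        }


def compute_strain(
    series: CineSeries,
    mask: MyocardialMask,
    config: Optional[RegistrationConfig] = None,
    model: Optional[SegmentModel] = None,
    center_mm=None,
) -> StrainResult:
    """Track the cine sequence and summarize circumferential strain.

    The mask must be congruent with the frames.  The LV center defaults to
    the mask centroid; the segment anchor comes from ``model``.
    """
    if config is None:
        config = RegistrationConfig()
    if model is None:
        model = SegmentModel()
    if mask.mask.shape != series.frame_shape:
        raise ValueError("mask shape does not match the cine frames")
    mask = MyocardialMask(mask=mask.mask, pixel_spacing=series.pixel_spacing)
    grids, infos = track_sequence(series, mask, config, return_info=True)
    points = mask.points_mm()
    fields = [
        strain_tensor_field(g, points, frame_index=k) for k, g in enumerate(grids)
    ]
    center = (
        np.asarray(center_mm, dtype=float)
        if center_mm is not None
        else estimate_center(mask)
    )
    curves = summarize_strain(fields, center, model)
    times = series.times_ms()
    if times is not None:
        curves.time_ms = times
    return StrainResult(
        curves=curves,
        tensor_fields=fields,
        grids=grids,
        center_mm=center,
        registration_info=infos,
        config=config,
    )
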