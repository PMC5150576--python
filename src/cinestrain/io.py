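"""Readers and writers for cine series, masks, strain tables and field exports.

Conventions: arrays are indexed (row, col); physical position of pixel
(i, j) is (i * spacing_row, j * spacing_col) mm with the origin at the
center of pixel (0, 0).  The reference (end-diastolic) frame defaults to
index 0 and is configurable.  Loading never rescales intensities beyond
the format-mandated slope/intercept and never reorders pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import SEGMENT_NAMES, StrainCurves

__all__ = [
    "CineSeries",
    "MyocardialMask",
    "load_cine",
    "load_mask",
    "write_strain_table",
    "read_strain_table",
    "write_deformation_fields",
    "write_strain_tensors",
]


@dataclass
class CineSeries:
    """A time-ordered stack of 2D short-axis frames with geometry metadata."""

    frames: np.ndarray  # (T, H, W)
    pixel_spacing: np.ndarray  # (row, col) mm
    reference_index: int = 0
    frame_interval_ms: Optional[float] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack of 2D rasters")
        if self.frames.shape[0] < 2:
            raise ValueError("a cine series needs at least 2 frames")
        self.pixel_spacing = np.atleast_1d(np.asarray(self.pixel_spacing, dtype=float))
        if self.pixel_spacing.size == 1:
            self.pixel_spacing = np.repeat(self.pixel_spacing, 2)
        if np.any(self.pixel_spacing <= 0):
            raise ValueError("pixel spacing components must be positive")
        if not (0 <= self.reference_index < self.frames.shape[0]):
            raise ValueError("reference_index out of range")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def reference_frame(self) -> np.ndarray:
        return self.frames[self.reference_index]

    def times_ms(self) -> Optional[np.ndarray]:
        if self.frame_interval_ms is None:
            return None
        return np.arange(self.n_frames) * float(self.frame_interval_ms)


@dataclass
class MyocardialMask:
    """Binary myocardium on the reference frame; the domain of u, F and E."""

    mask: np.ndarray
    pixel_spacing: np.ndarray = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.pixel_spacing is None:
            self.pixel_spacing = np.array([1.0, 1.0])
        self.pixel_spacing = np.atleast_1d(np.asarray(self.pixel_spacing, dtype=float))
        if self.pixel_spacing.size == 1:
            self.pixel_spacing = np.repeat(self.pixel_spacing, 2)

    def points_mm(self) -> np.ndarray:
        """(N, 2) physical coordinates of mask pixel centers."""
        rows, cols = np.nonzero(self.mask)
        return np.stack(
            [rows * self.pixel_spacing[0], cols * self.pixel_spacing[1]], axis=1
        )


def _time_zoom_to_ms(zoom: float, unit: str) -> Optional[float]:
    if zoom <= 0:
        return None
    return {"sec": zoom * 1000.0, "msec": zoom, "usec": zoom / 1000.0}.get(unit)


def _check_raw_nifti_spacing(path: Path) -> None:
    # nibabel silently repairs non-positive pixdims, so validate the raw header
    import nibabel as nib
    from nibabel.openers import ImageOpener

    try:
        with ImageOpener(str(path), "rb") as f:
            hdr = nib.Nifti1Header.from_fileobj(f, check=False)
    except Exception:
        return  # not a plain .nii/.nii.gz stream; trust the repaired header
    if np.any(np.asarray(hdr["pixdim"][1:3]) <= 0):
        raise ValueError("non-positive pixel spacing in NIfTI header field 'pixdim'")


def _load_nifti_cine(path: Path, reference_index: int) -> CineSeries:
    import nibabel as nib

    _check_raw_nifti_spacing(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise ValueError("multi-slice NIfTI not supported; expected 2D+t")
        data = data[:, :, 0, :]
        t_zoom = zooms[3] if len(zooms) > 3 else 0.0
    elif data.ndim == 3:
        t_zoom = zooms[2] if len(zooms) > 2 else 0.0
    else:
        raise ValueError("expected a 2D+t NIfTI (3D or 4D with singleton z)")
    spacing = np.asarray(zooms[:2], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(
            "non-positive pixel spacing in NIfTI header field 'pixdim'"
        )
    frames = np.moveaxis(data, -1, 0)
    interval = _time_zoom_to_ms(float(t_zoom), img.header.get_xyzt_units()[1])
    return CineSeries(
        frames=frames,
        pixel_spacing=spacing,
        reference_index=reference_index,
        frame_interval_ms=interval,
    )


def _load_dicom_cine(path: Path, reference_index: int) -> CineSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM files in the directory
        if hasattr(ds, "pixel_array"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"found {len(datasets)} DICOM frames in {path}; need >= 2")

    first = datasets[0]
    if not getattr(first, "PixelSpacing", None):
        raise ValueError("missing DICOM header field 'PixelSpacing' (0028,0030)")
    ref_geom = (
        tuple(float(v) for v in first.PixelSpacing),
        (int(first.Rows), int(first.Columns)),
        tuple(float(v) for v in getattr(first, "ImagePositionPatient", ())),
    )
    for ds in datasets[1:]:
        geom = (
            tuple(float(v) for v in getattr(ds, "PixelSpacing", ())),
            (int(ds.Rows), int(ds.Columns)),
            tuple(float(v) for v in getattr(ds, "ImagePositionPatient", ())),
        )
        if geom != ref_geom:
            raise ValueError("mixed geometry across DICOM frames")

    have_trigger = all(getattr(ds, "TriggerTime", None) is not None for ds in datasets)
    if have_trigger:
        datasets.sort(key=lambda ds: float(ds.TriggerTime))
    else:
        datasets.sort(key=lambda ds: int(ds.InstanceNumber))

    frames = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
    interval = None
    if have_trigger and len(datasets) > 1:
        tt = np.array([float(ds.TriggerTime) for ds in datasets])
        diffs = np.diff(tt)
        if diffs.size and np.all(diffs > 0):
            interval = float(diffs.mean())
    spacing = np.asarray(ref_geom[0], dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("non-positive DICOM 'PixelSpacing' (0028,0030)")
    return CineSeries(
        frames=np.stack(frames),
        pixel_spacing=spacing,
        reference_index=reference_index,
        frame_interval_ms=interval,
    )


def load_cine(path, reference_index: int = 0) -> CineSeries:
    """Load a 2D+t NIfTI file or a directory of single-frame DICOMs.

    DICOM frames are ordered by TriggerTime when every frame carries one,
    otherwise by InstanceNumber; any geometry mismatch across frames is a
    hard error.
    """
    path = Path(path)
    if path.is_dir():
        return _load_dicom_cine(path, reference_index)
    return _load_nifti_cine(path, reference_index)


def load_mask(path, pixel_spacing=None) -> MyocardialMask:
    """Load a binary myocardial mask from NIfTI (nonzero) or PNG (nonzero)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return MyocardialMask(mask=arr > 0, pixel_spacing=pixel_spacing)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError("mask must be a single 2D raster")
    if pixel_spacing is None:
        pixel_spacing = np.asarray(img.header.get_zooms()[:2], dtype=float)
    return MyocardialMask(mask=data != 0, pixel_spacing=pixel_spacing)


_TABLE_COLUMNS = ["frame", "time_ms", "global_Ecc", *SEGMENT_NAMES]


def write_strain_table(curves: StrainCurves, path) -> None:
    """CSV with one row per frame: frame, time_ms, global Ecc then the 6 segments (%)."""
    if len(curves.frames) < 1:
        raise ValueError("strain curves are empty")
    times = curves.time_ms
    if times is None:
        times = np.full(len(curves.frames), np.nan)
    df = pd.DataFrame({"frame": curves.frames, "time_ms": times})
    df["global_Ecc"] = curves.global_pct
    for k, name in enumerate(SEGMENT_NAMES):
        df[name] = curves.segment_pct[:, k]
    df.to_csv(path, index=False, float_format="%.6f")


def read_strain_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"strain table missing columns: {missing}")
    return df


def _spacing_affine(pixel_spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = pixel_spacing[0]
    aff[1, 1] = pixel_spacing[1]
    return aff


def write_nifti(data: np.ndarray, pixel_spacing, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), _spacing_affine(pixel_spacing))
    nib.save(img, str(path))


def write_deformation_fields(grids: Sequence, path) -> None:
    """Export dense per-frame displacement as a (H, W, T, 2) NIfTI, mm units."""
    dense = [np.moveaxis(g.dense_displacement(), 0, -1) for g in grids]
    data = np.stack(dense, axis=2)  # (H, W, T, 2)
    write_nifti(data, grids[0].pixel_spacing, path)


def write_strain_tensors(tensor_fields, mask: MyocardialMask, path) -> None:
    """Export (H, W, T, 3) NIfTI of (Exx, Exy, Eyy); NaN outside the mask."""
    shape = mask.mask.shape
    rows, cols = np.nonzero(mask.mask)
    data = np.full((shape[0], shape[1], len(tensor_fields), 3), np.nan)
    for t, tf in enumerate(tensor_fields):
        data[rows, cols, t, 0] = tf.E[:, 0, 0]
        data[rows, cols, t, 1] = tf.E[:, 0, 1]
        data[rows, cols, t, 2] = tf.E[:, 1, 1]
    write_nifti(data, mask.pixel_spacing, path)
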