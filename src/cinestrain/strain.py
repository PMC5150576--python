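"""Deformation gradient and Green-Lagrange strain from tracked displacement fields.

With u(X) the displacement tracked on reference (end-diastolic) coordinates
X, the deformation gradient is F = I + du/dX and the Green-Lagrange strain
E = (FᵀF - I)/2.  E vanishes for rigid motions and is frame-indifferent,
which is what makes it the appropriate measure for a rotating, contracting
ventricle.  Strain is evaluated pixel-wise on the reference myocardial mask
using the analytic b-spline derivatives of the displacement parameterization
(no finite differencing of the dense field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ffd import ControlPointGrid

__all__ = [
    "StrainTensorField",
    "displacement_gradient",
    "deformation_gradient",
    "green_lagrange",
    "project_strain",
    "strain_tensor_field",
]


def displacement_gradient(grid: ControlPointGrid, points) -> np.ndarray:
    """du/dX (N, 2, 2) at reference positions (mm), from analytic basis derivatives."""
    return grid.displacement_jacobian(points)


def deformation_gradient(du_dX) -> np.ndarray:
    """F = I + du/dX, batched over leading dimensions."""
    du = np.asarray(du_dX, dtype=float)
    if du.shape[-2:] != (2, 2):
        raise ValueError("expected trailing 2x2 matrices")
    if not np.all(np.isfinite(du)):
        raise ValueError("displacement gradient must be finite")
    return du + np.eye(2)


def green_lagrange(F) -> np.ndarray:
    """E = (FᵀF - I)/2, symmetric by construction; batched."""
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (2, 2):
        raise ValueError("expected trailing 2x2 matrices")
    FtF = np.einsum("...ki,...kj->...ij", F, F)
    return 0.5 * (FtF - np.eye(2))


def project_strain(E, e_r, e_c) -> tuple:
    """Radial and circumferential normal strains (Err, Ecc) = (e_rᵀEe_r, e_cᵀEe_c).

    Dimensionless; callers multiply by 100 at output boundaries to report
    percent.  e_r and e_c must be orthonormal.
    """
    E = np.asarray(E, dtype=float)
    e_r = np.asarray(e_r, dtype=float)
    e_c = np.asarray(e_c, dtype=float)
    tol = 1e-8
    if abs(np.dot(e_r, e_r) - 1.0) > tol or abs(np.dot(e_c, e_c) - 1.0) > tol:
        raise ValueError("direction vectors must be unit length")
    if abs(np.dot(e_r, e_c)) > tol:
        raise ValueError("direction vectors must be orthogonal")
    err = float(e_r @ E @ e_r) if E.ndim == 2 else np.einsum("i,nij,j->n", e_r, E, e_r)
    ecc = float(e_c @ E @ e_c) if E.ndim == 2 else np.einsum("i,nij,j->n", e_c, E, e_c)
    return err, ecc


@dataclass
class StrainTensorField:
    """Per-pixel F and E on the reference myocardial mask for one frame."""

    frame_index: int
    points_mm: np.ndarray  # (N, 2) reference positions
    F: np.ndarray  # (N, 2, 2)
    E: np.ndarray  # (N, 2, 2)

    def __post_init__(self):
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        n = self.points_mm.shape[0]
        if self.F.shape != (n, 2, 2) or self.E.shape != (n, 2, 2):
            raise ValueError("F and E must be (N, 2, 2) matching points")

    @property
    def det_F(self) -> np.ndarray:
        return np.linalg.det(self.F)


def strain_tensor_field(
    grid: ControlPointGrid, points_mm, frame_index: int = 0
) -> StrainTensorField:
    """Evaluate F and E at the given reference positions from one tracked grid."""
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    du = displacement_gradient(grid, points_mm)
    F = deformation_gradient(du)
    E = green_lagrange(F)
    return StrainTensorField(frame_index=frame_index, points_mm=points_mm, F=F, E=E)
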