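"""Uniform cubic b-spline free-form deformation (FFD) and intensity registration.

The displacement field of one cine frame relative to the reference frame is
parameterized by a lattice of control-point coefficients blended with cubic
b-spline basis functions:

    u(X) = sum_ij c_ij B3((x - ox)/sx - i) B3((y - oy)/sy - j)

with all coordinates in physical millimetres.  Registration minimizes the
mean sum-of-squared-differences (SSD) between the reference frame and the
warped target frame plus a bending-energy smoothness penalty, by limited
memory quasi-Newton descent over a 3-level image pyramid.  Everything is
deterministic: no randomized initialization anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

__all__ = [
    "ControlPointGrid",
    "RegistrationConfig",
    "RegistrationError",
    "cubic_bspline",
    "evaluate_displacement",
    "warp_image",
    "ssd_cost",
    "bending_energy",
    "register_pair",
    "track_sequence",
]


class RegistrationError(RuntimeError):
    """Raised when the registration objective becomes non-finite or inputs are invalid."""


def cubic_bspline(u, deriv: int = 0):
    """Centered cubic b-spline basis B3(u), or its first/second derivative.

    B3 has support (-2, 2), is C2, and the integer translates form a
    partition of unity.
    """
    u = np.asarray(u, dtype=float)
    a = np.abs(u)
    if deriv == 0:
        inner = (4.0 - 6.0 * a * a + 3.0 * a * a * a) / 6.0
        outer = (2.0 - a) ** 3 / 6.0
    elif deriv == 1:
        s = np.sign(u)
        inner = u * (1.5 * a - 2.0)
        outer = -s * (2.0 - a) ** 2 / 2.0
    elif deriv == 2:
        inner = 3.0 * a - 2.0
        outer = 2.0 - a
    else:
        raise ValueError("deriv must be 0, 1 or 2")
    return np.where(a < 1.0, inner, np.where(a < 2.0, outer, 0.0))


def _grid_axis(extent_mm: float, spacing_mm: float) -> tuple[float, int]:
    """Origin and control-point count covering [0, extent] with >= 2 CPs beyond each border."""
    origin = -2.0 * spacing_mm
    n_ctrl = int(np.floor(extent_mm / spacing_mm + 2.0)) + 4
    return origin, n_ctrl


@dataclass
class ControlPointGrid:
    """Cubic b-spline coefficient lattice for one frame's displacement field.

    coefficients has shape (2, n_row_ctrl, n_col_ctrl): component 0 is the
    row-direction displacement in mm, component 1 the column direction.
    The grid remembers the image geometry it was built for so that
    domain-integral quantities (bending energy) are well defined.
    """

    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    coefficients: np.ndarray
    image_shape: tuple[int, int]
    pixel_spacing: np.ndarray

    def __post_init__(self):
        self.spacing_mm = np.atleast_1d(np.asarray(self.spacing_mm, dtype=float))
        if self.spacing_mm.size == 1:
            self.spacing_mm = np.repeat(self.spacing_mm, 2)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.pixel_spacing = np.asarray(self.pixel_spacing, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("control-point spacing must be positive")
        if self.coefficients.ndim != 3 or self.coefficients.shape[0] != 2:
            raise ValueError("coefficients must have shape (2, n_row_ctrl, n_col_ctrl)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @classmethod
    def for_image(
        cls,
        image_shape: Sequence[int],
        pixel_spacing,
        control_spacing_mm,
    ) -> "ControlPointGrid":
        """Zero-displacement grid whose support covers the whole image domain."""
        pixel_spacing = np.atleast_1d(np.asarray(pixel_spacing, dtype=float))
        if pixel_spacing.size == 1:
            pixel_spacing = np.repeat(pixel_spacing, 2)
        cp = np.atleast_1d(np.asarray(control_spacing_mm, dtype=float))
        if cp.size == 1:
            cp = np.repeat(cp, 2)
        origin = np.empty(2)
        n_ctrl = np.empty(2, dtype=int)
        for ax in range(2):
            extent = (image_shape[ax] - 1) * pixel_spacing[ax]
            origin[ax], n_ctrl[ax] = _grid_axis(extent, cp[ax])
        coef = np.zeros((2, n_ctrl[0], n_ctrl[1]))
        return cls(cp, origin, coef, tuple(image_shape), pixel_spacing)

    @property
    def n_ctrl(self) -> tuple[int, int]:
        return self.coefficients.shape[1], self.coefficients.shape[2]

    def copy(self) -> "ControlPointGrid":
        return ControlPointGrid(
            self.spacing_mm.copy(),
            self.origin_mm.copy(),
            self.coefficients.copy(),
            self.image_shape,
            self.pixel_spacing.copy(),
        )

    # -- evaluation at scattered points ------------------------------------

    def _axis_terms(self, points: np.ndarray, axis: int, deriv: int):
        t = (points[:, axis] - self.origin_mm[axis]) / self.spacing_mm[axis]
        base = np.floor(t).astype(np.int64) - 1
        n = self.coefficients.shape[1 + axis]
        if np.any(base < 0) or np.any(base + 3 > n - 1):
            raise ValueError("point outside control grid support")
        u = t[:, None] - (base[:, None] + np.arange(4)[None, :])
        w = cubic_bspline(u, deriv) / self.spacing_mm[axis] ** deriv
        return base, w

    def _gather(self, base_r, base_c):
        offs = np.arange(4)
        i = base_r[:, None] + offs[None, :]
        j = base_c[:, None] + offs[None, :]
        # (2, N, 4, 4) patches of in-support coefficients
        return self.coefficients[:, i[:, :, None], j[:, None, :]]

    def displacement(self, points) -> np.ndarray:
        """u(X) in mm at reference positions ``points`` (N, 2) in mm."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        br, wr = self._axis_terms(points, 0, 0)
        bc, wc = self._axis_terms(points, 1, 0)
        patch = self._gather(br, bc)
        return np.einsum("cnab,na,nb->nc", patch, wr, wc)

    def displacement_jacobian(self, points) -> np.ndarray:
        """du/dX (N, 2, 2), dimensionless, J[n, i, j] = d u_i / d X_j."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        br, wr0 = self._axis_terms(points, 0, 0)
        bc, wc0 = self._axis_terms(points, 1, 0)
        _, wr1 = self._axis_terms(points, 0, 1)
        _, wc1 = self._axis_terms(points, 1, 1)
        patch = self._gather(br, bc)
        d_dr = np.einsum("cnab,na,nb->nc", patch, wr1, wc0)
        d_dc = np.einsum("cnab,na,nb->nc", patch, wr0, wc1)
        return np.stack([d_dr, d_dc], axis=-1)

    def basis_matrix(self, coords_mm: np.ndarray, axis: int, deriv: int = 0) -> np.ndarray:
        """Dense 1D collocation matrix mapping coefficients to values at coords_mm."""
        coords_mm = np.asarray(coords_mm, dtype=float)
        pts = np.zeros((coords_mm.size, 2))
        pts[:, axis] = coords_mm
        pts[:, 1 - axis] = self.origin_mm[1 - axis] + 2.0 * self.spacing_mm[1 - axis]
        base, w = self._axis_terms(pts, axis, deriv)
        n = self.coefficients.shape[1 + axis]
        mat = np.zeros((coords_mm.size, n))
        rows = np.arange(coords_mm.size)
        for a in range(4):
            mat[rows, base + a] += w[:, a]
        return mat

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        rows = np.arange(self.image_shape[0]) * self.pixel_spacing[0]
        cols = np.arange(self.image_shape[1]) * self.pixel_spacing[1]
        return rows, cols

    def dense_displacement(self) -> np.ndarray:
        """(2, H, W) displacement in mm at every pixel center."""
        rows, cols = self.pixel_coords_mm()
        br = self.basis_matrix(rows, 0)
        bc = self.basis_matrix(cols, 1)
        return np.stack([br @ self.coefficients[c] @ bc.T for c in range(2)])


def evaluate_displacement(grid: ControlPointGrid, points) -> np.ndarray:
    """Exact tensor-product b-spline evaluation of u at reference positions (mm)."""
    return grid.displacement(points)


# -- image interpolation ----------------------------------------------------


def _mirror_index(idx: np.ndarray, n: int) -> np.ndarray:
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


class SplineImage:
    """Cubic b-spline interpolant of a 2D raster with analytic gradient.

    Mirror boundary handling; interpolation is exact at the sample points.
    """

    def __init__(self, image: np.ndarray):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("expected a 2D image")
        self.shape = image.shape
        self.coef = ndimage.spline_filter(image, order=3, mode="mirror")
        self._flat = self.coef.ravel()

    def _terms(self, x: np.ndarray, n: int, deriv: int):
        base = np.floor(x).astype(np.int64) - 1
        u = x[:, None] - (base[:, None] + np.arange(4)[None, :])
        w = cubic_bspline(u, deriv)
        idx = _mirror_index(base[:, None] + np.arange(4)[None, :], n)
        return idx, w

    def sample(
        self,
        rows,
        cols,
        fill: float = 0.0,
        with_gradient: bool = False,
        mode: str = "fill",
    ):
        """Interpolate at float pixel coordinates.

        mode='fill': constant fill outside the frame (export semantics).
        mode='clamp': edge-value extension, which keeps the registration
        objective continuous when a pixel drifts across the frame border.
        """
        rows = np.asarray(rows, dtype=float).ravel()
        cols = np.asarray(cols, dtype=float).ravel()
        nr, nc = self.shape
        in_r = (rows >= 0) & (rows <= nr - 1)
        in_c = (cols >= 0) & (cols <= nc - 1)
        r = np.clip(rows, 0.0, nr - 1.0)
        c = np.clip(cols, 0.0, nc - 1.0)
        ir, wr0 = self._terms(r, nr, 0)
        ic, wc0 = self._terms(c, nc, 0)
        flat_idx = ir[:, :, None] * nc + ic[:, None, :]
        patch = self._flat[flat_idx]
        val = np.einsum("nab,na,nb->n", patch, wr0, wc0)
        if mode == "fill":
            val = np.where(in_r & in_c, val, fill)
        elif mode != "clamp":
            raise ValueError("mode must be 'fill' or 'clamp'")
        if not with_gradient:
            return val
        _, wr1 = self._terms(r, nr, 1)
        _, wc1 = self._terms(c, nc, 1)
        gr = np.einsum("nab,na,nb->n", patch, wr1, wc0)
        gc = np.einsum("nab,na,nb->n", patch, wr0, wc1)
        if mode == "fill":
            inside = in_r & in_c
            gr = np.where(inside, gr, 0.0)
            gc = np.where(inside, gc, 0.0)
        else:  # clamped coordinate has zero sensitivity beyond the edge
            gr = np.where(in_r, gr, 0.0)
            gc = np.where(in_c, gc, 0.0)
        return val, gr, gc


def warp_image(
    image: np.ndarray,
    grid: ControlPointGrid,
    order: str = "cubic",
    fill: float = 0.0,
) -> np.ndarray:
    """Backward-warp: output(X) = image(X + u(X)) sampled at every reference pixel."""
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(grid.image_shape):
        raise ValueError("image shape does not match grid geometry")
    u = grid.dense_displacement()
    rows, cols = grid.pixel_coords_mm()
    pr = (rows[:, None] + u[0]) / grid.pixel_spacing[0]
    pc = (cols[None, :] + u[1]) / grid.pixel_spacing[1]
    if order == "cubic":
        out = SplineImage(image).sample(pr.ravel(), pc.ravel(), fill=fill)
        return out.reshape(image.shape)
    if order == "linear":
        return ndimage.map_coordinates(
            image, [pr, pc], order=1, mode="constant", cval=fill
        )
    raise ValueError("order must be 'cubic' or 'linear'")


def ssd_cost(
    reference: np.ndarray,
    target: np.ndarray,
    grid: ControlPointGrid,
    support: Optional[np.ndarray] = None,
    order: str = "cubic",
    fill: float = 0.0,
) -> float:
    """Mean squared intensity difference between reference and warped target."""
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError("reference and target must be congruent")
    warped = warp_image(target, grid, order=order, fill=fill)
    diff = reference - warped
    if support is None:
        return float(np.mean(diff**2))
    support = np.asarray(support, dtype=bool)
    if support.shape != reference.shape:
        raise ValueError("support mask must be congruent with the images")
    if not support.any():
        raise ValueError("empty support")
    return float(np.mean(diff[support] ** 2))


def bending_energy(grid: ControlPointGrid) -> float:
    """Mean squared second derivatives of u over the image domain (thin-plate bending).

    Zero for any globally affine displacement; units mm^-2 scaled by mm^2
    displacement, i.e. dimensionless per mm^2 of curvature.
    """
    rows, cols = grid.pixel_coords_mm()
    br = [grid.basis_matrix(rows, 0, d) for d in range(3)]
    bc = [grid.basis_matrix(cols, 1, d) for d in range(3)]
    total = 0.0
    for c in range(2):
        coef = grid.coefficients[c]
        urr = br[2] @ coef @ bc[0].T
        urc = br[1] @ coef @ bc[1].T
        ucc = br[0] @ coef @ bc[2].T
        total += np.mean(urr**2 + 2.0 * urc**2 + ucc**2)
    return float(total)


# -- registration -----------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Tuning knobs for the FFD registration.

    control_spacing_mm is the spacing at the finest pyramid level; coarser
    levels double it.  regularization_weight multiplies the bending energy
    (intensities are normalized to [0, 1] first so the weight transfers
    across scanners).  convergence_tol is the relative objective decrease
    below which a level stops.
    """

    control_spacing_mm: float = 8.0
    regularization_weight: float = 0.01
    pyramid_levels: int = 3
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    interpolation: str = "cubic"
    fill_value: float = 0.0
    normalize: bool = True
    mask_support: bool = False

    def __post_init__(self):
        if self.control_spacing_mm <= 0:
            raise ValueError("control_spacing_mm must be positive")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.interpolation not in ("cubic", "linear"):
            raise ValueError("interpolation must be 'cubic' or 'linear'")

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown registration options: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _downsample(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return image
    smoothed = ndimage.gaussian_filter(image, sigma=factor / 2.0, mode="nearest")
    return smoothed[::factor, ::factor]


def resample_grid(src: ControlPointGrid, dst: ControlPointGrid) -> None:
    """Initialize dst coefficients so its field interpolates src at dst control points."""
    nr, nc = dst.n_ctrl
    pr = dst.origin_mm[0] + np.arange(nr) * dst.spacing_mm[0]
    pc = dst.origin_mm[1] + np.arange(nc) * dst.spacing_mm[1]
    lo = src.origin_mm + src.spacing_mm  # inclusive support bounds
    hi = src.origin_mm + src.spacing_mm * (np.array(src.n_ctrl) - 2) - 1e-9
    pts = np.stack(
        [
            np.clip(np.repeat(pr, nc), lo[0], hi[0]),
            np.clip(np.tile(pc, nr), lo[1], hi[1]),
        ],
        axis=1,
    )
    vals = src.displacement(pts).reshape(nr, nc, 2)
    for c in range(2):
        dst.coefficients[c] = ndimage.spline_filter(vals[:, :, c], order=3, mode="mirror")


class _LevelProblem:
    """Objective + analytic gradient for one pyramid level (all dense matmuls)."""

    def __init__(self, reference, target, grid: ControlPointGrid, config, support):
        self.ref = reference
        self.tgt = SplineImage(target)
        self.grid = grid
        self.lam = config.regularization_weight
        self.fill = config.fill_value
        rows, cols = grid.pixel_coords_mm()
        self.rows_mm = rows[:, None]
        self.cols_mm = cols[None, :]
        self.px = grid.pixel_spacing
        self.br = [grid.basis_matrix(rows, 0, d) for d in range(3)]
        self.bc = [grid.basis_matrix(cols, 1, d) for d in range(3)]
        self.shape = reference.shape
        self.n_pix = reference.size
        if support is not None:
            support = np.asarray(support, dtype=bool)
            if not support.any():
                raise RegistrationError("empty registration support mask")
        self.support = support
        self.n_support = int(support.sum()) if support is not None else self.n_pix
        self.coef_shape = grid.coefficients.shape

    def __call__(self, x: np.ndarray):
        C = x.reshape(self.coef_shape)
        u0 = self.br[0] @ C[0] @ self.bc[0].T
        u1 = self.br[0] @ C[1] @ self.bc[0].T
        pr = (self.rows_mm + u0) / self.px[0]
        pc = (self.cols_mm + u1) / self.px[1]
        val, gr, gc = self.tgt.sample(
            pr.ravel(), pc.ravel(), with_gradient=True, mode="clamp"
        )
        resid = val.reshape(self.shape) - self.ref
        gr = gr.reshape(self.shape) / self.px[0]  # intensity per mm
        gc = gc.reshape(self.shape) / self.px[1]
        if self.support is not None:
            resid = np.where(self.support, resid, 0.0)
        ssd = float(np.sum(resid**2)) / self.n_support
        w = (2.0 / self.n_support) * resid
        grad = np.empty(self.coef_shape)
        grad[0] = self.br[0].T @ (w * gr) @ self.bc[0]
        grad[1] = self.br[0].T @ (w * gc) @ self.bc[0]
        be = 0.0
        if self.lam > 0:
            for c in range(2):
                f_rr = self.br[2] @ C[c] @ self.bc[0].T
                f_rc = self.br[1] @ C[c] @ self.bc[1].T
                f_cc = self.br[0] @ C[c] @ self.bc[2].T
                be += (
                    np.sum(f_rr**2) + 2.0 * np.sum(f_rc**2) + np.sum(f_cc**2)
                ) / self.n_pix
                grad[c] += (
                    self.lam
                    * (2.0 / self.n_pix)
                    * (
                        self.br[2].T @ f_rr @ self.bc[0]
                        + 2.0 * self.br[1].T @ f_rc @ self.bc[1]
                        + self.br[0].T @ f_cc @ self.bc[2]
                    )
                )
        f = ssd + self.lam * be
        if not np.isfinite(f):
            raise RegistrationError(
                "non-finite registration objective; check regularization weight "
                "and control-point spacing"
            )
        return f, grad.ravel()


def _joint_normalize(reference, target):
    lo = min(reference.min(), target.min())
    hi = max(reference.max(), target.max())
    if hi - lo <= 0:
        return reference - lo, target - lo
    return (reference - lo) / (hi - lo), (target - lo) / (hi - lo)


def register_pair(
    reference: np.ndarray,
    target: np.ndarray,
    pixel_spacing,
    config: Optional[RegistrationConfig] = None,
    init: Optional[ControlPointGrid] = None,
    support: Optional[np.ndarray] = None,
    return_info: bool = False,
):
    """Estimate the b-spline displacement field warping target onto reference.

    Returns the finest-level ControlPointGrid; with ``return_info`` also a
    dict of per-level objectives and iteration counts.  Deterministic.
    """
    if config is None:
        config = RegistrationConfig()
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError("reference and target must be congruent")
    pixel_spacing = np.atleast_1d(np.asarray(pixel_spacing, dtype=float))
    if pixel_spacing.size == 1:
        pixel_spacing = np.repeat(pixel_spacing, 2)
    if config.normalize:
        reference, target = _joint_normalize(reference, target)

    info = {"levels": []}
    prev_grid = init
    grid = None
    for level in range(config.pyramid_levels - 1, -1, -1):
        factor = 2**level
        if min(reference.shape) // factor < 8:
            continue  # image too small for this level
        ref_l = _downsample(reference, factor)
        tgt_l = _downsample(target, factor)
        sup_l = None
        if support is not None and config.mask_support:
            sup_l = np.asarray(support, dtype=bool)[::factor, ::factor]
        px_l = pixel_spacing * factor
        grid = ControlPointGrid.for_image(
            ref_l.shape, px_l, config.control_spacing_mm * factor
        )
        if prev_grid is not None:
            resample_grid(prev_grid, grid)
        problem = _LevelProblem(ref_l, tgt_l, grid, config, sup_l)
        x0 = grid.coefficients.ravel().copy()
        f0, _ = problem(x0)
        ftol = config.convergence_tol * max(abs(f0), 1e-12)
        res = minimize(
            problem,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "maxfun": 20 * config.max_iterations,
                "ftol": ftol,
                "gtol": 1e-12,
            },
        )
        x_best = res.x if res.fun <= f0 else x0
        f_best = min(float(res.fun), f0)
        grid.coefficients = x_best.reshape(grid.coefficients.shape).copy()
        info["levels"].append(
            {
                "level": level,
                "shape": list(ref_l.shape),
                "initial_objective": f0,
                "final_objective": f_best,
                "iterations": int(res.nit),
            }
        )
        prev_grid = grid
    if grid is None:
        raise RegistrationError("image too small for the requested pyramid")
    info["final_objective"] = info["levels"][-1]["final_objective"]
    if return_info:
        return grid, info
    return grid


def track_sequence(
    series,
    mask=None,
    config: Optional[RegistrationConfig] = None,
    return_info: bool = False,
):
    """Register every frame of a cine series to its reference frame (Lagrangian).

    Returns one ControlPointGrid per frame; the grid at the reference index
    is the zero field.  Registrations are warm-started from the temporally
    adjacent solution, marching outward from the reference frame, and all
    fields live on reference-frame coordinates.
    """
    if config is None:
        config = RegistrationConfig()
    frames = np.asarray(series.frames, dtype=float)
    n = frames.shape[0]
    ridx = series.reference_index
    lo, hi = float(frames.min()), float(frames.max())
    if config.normalize and hi > lo:
        frames = (frames - lo) / (hi - lo)
    cfg = dataclasses.replace(config, normalize=False)
    support = None
    if mask is not None and config.mask_support:
        support = np.asarray(mask.mask, dtype=bool)

    grids: list = [None] * n
    infos: list = [None] * n
    grids[ridx] = ControlPointGrid.for_image(
        frames[ridx].shape, series.pixel_spacing, config.control_spacing_mm
    )
    infos[ridx] = {"levels": [], "final_objective": 0.0}
    order = list(range(ridx + 1, n)) + list(range(ridx - 1, -1, -1))
    for k in order:
        prev = k - 1 if k > ridx else k + 1
        try:
            grids[k], infos[k] = register_pair(
                frames[ridx],
                frames[k],
                series.pixel_spacing,
                cfg,
                init=grids[prev],
                support=support,
                return_info=True,
            )
        except RegistrationError as exc:
            raise RegistrationError(f"frame {k}: {exc}") from exc
    if return_info:
        return grids, infos
    return grids
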