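"""Cubic b-spline FFD evaluation, similarity/regularizer terms, and registration."""

import numpy as np
import pytest
from scipy import ndimage

from cinestrain.ffd import (
    ControlPointGrid,
    RegistrationConfig,
    SplineImage,
    bending_energy,
    cubic_bspline,
    evaluate_displacement,
    register_pair,
    ssd_cost,
    track_sequence,
    warp_image,
)
from cinestrain.io import CineSeries


def smooth_texture(shape, seed, sigma=3.0):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    return (img - img.min()) / (img.max() - img.min())


def affine_grid(shape, spacing, ctrl, A, b):
    g = ControlPointGrid.for_image(shape, spacing, ctrl)
    nr, nc = g.n_ctrl
    pr = g.origin_mm[0] + np.arange(nr) * g.spacing_mm[0]
    pc = g.origin_mm[1] + np.arange(nc) * g.spacing_mm[1]
    P0, P1 = np.meshgrid(pr, pc, indexing="ij")
    for c in range(2):
        g.coefficients[c] = A[c, 0] * P0 + A[c, 1] * P1 + b[c]
    return g


class TestBasis:
    def test_partition_of_unity(self):
        x = np.linspace(-0.49, 0.49, 23)
        total = sum(cubic_bspline(x + k) for k in range(-2, 3))
        assert np.allclose(total, 1.0, atol=1e-14)

    def test_derivative_matches_finite_difference(self):
        # stay away from the knots (0, ±1, ±2) where the second derivative
        # has kinks and central differences pick up O(h) error
        x = np.concatenate(
            [np.linspace(a + 0.05, b - 0.05, 25) for a, b in
             [(-2, -1), (-1, 0), (0, 1), (1, 2)]]
        )
        h = 1e-6
        fd1 = (cubic_bspline(x + h) - cubic_bspline(x - h)) / (2 * h)
        assert np.abs(cubic_bspline(x, 1) - fd1).max() < 1e-8
        fd2 = (cubic_bspline(x + h, 1) - cubic_bspline(x - h, 1)) / (2 * h)
        assert np.abs(cubic_bspline(x, 2) - fd2).max() < 1e-8

    def test_compact_support(self):
        assert cubic_bspline(2.0) == 0 and cubic_bspline(-2.5) == 0


class TestEvaluate:
    def test_zero_coefficients_zero_field(self):
        g = ControlPointGrid.for_image((32, 32), 1.0, 5.0)
        u = evaluate_displacement(g, [[10.0, 20.0]])
        assert np.allclose(u, 0)

    def test_constant_coefficients_constant_field(self):
        g = ControlPointGrid.for_image((32, 32), 1.0, 5.0)
        g.coefficients[0] = 3.0
        g.coefficients[1] = -1.0
        pts = np.random.default_rng(0).uniform(0, 31, (100, 2))
        u = evaluate_displacement(g, pts)
        assert np.abs(u - [3.0, -1.0]).max() < 1e-13

    def test_single_coefficient_matches_brute_force_sum(self):
        g = ControlPointGrid.for_image((32, 32), 1.0, 5.0)
        g.coefficients[0, 5, 6] = 1.0
        pts = np.random.default_rng(1).uniform(5, 25, (20, 2))
        u = evaluate_displacement(g, pts)
        # direct summation over every control point
        expected = np.zeros(len(pts))
        for i in range(g.n_ctrl[0]):
            for j in range(g.n_ctrl[1]):
                ti = (pts[:, 0] - g.origin_mm[0]) / g.spacing_mm[0] - i
                tj = (pts[:, 1] - g.origin_mm[1]) / g.spacing_mm[1] - j
                expected += g.coefficients[0, i, j] * cubic_bspline(ti) * cubic_bspline(tj)
        assert np.abs(u[:, 0] - expected).max() < 1e-12
        assert np.allclose(u[:, 1], 0)

    def test_point_outside_support_rejected(self):
        g = ControlPointGrid.for_image((32, 32), 1.0, 5.0)
        with pytest.raises(ValueError):
            evaluate_displacement(g, [[200.0, 0.0]])


class TestWarp:
    def test_zero_field_identity(self):
        img = smooth_texture((24, 24), 0)
        g = ControlPointGrid.for_image(img.shape, 1.0, 6.0)
        assert np.abs(warp_image(img, g) - img).max() < 1e-9

    def test_constant_shift_moves_bright_pixel(self):
        img = np.zeros((32, 32))
        img[20, 16] = 1.0
        g = ControlPointGrid.for_image(img.shape, 1.0, 6.0)
        g.coefficients[0] = 4.0  # u = (+4, 0): sample from 4 rows below
        warped = warp_image(img, g, order="linear")
        assert warped[16, 16] == pytest.approx(1.0)
        assert warped[20, 16] == pytest.approx(0.0)

    def test_linear_ramp_under_constant_shift(self):
        rows = np.arange(40, dtype=float)
        img = np.tile(rows[:, None], (1, 40))  # ramp in the row direction
        g = ControlPointGrid.for_image(img.shape, 1.0, 8.0)
        g.coefficients[0] = 2.5
        warped = warp_image(img, g)
        # the spline prefilter's mirror boundary influence decays like
        # 0.268^d, so compare well inside the frame
        interior = warped[12:-15, 12:-12]
        expected = img[12:-15, 12:-12] + 2.5
        assert np.abs(interior - expected).max() < 1e-5


class TestSSD:
    def test_identical_images_zero_cost(self):
        img = smooth_texture((16, 16), 2)
        g = ControlPointGrid.for_image(img.shape, 1.0, 5.0)
        assert ssd_cost(img, img, g) < 1e-18

    def test_constant_offset_mean_ssd(self):
        ref = np.ones((4, 4))
        tgt = np.full((4, 4), 3.0)
        g = ControlPointGrid.for_image((4, 4), 1.0, 2.0)
        assert ssd_cost(ref, tgt, g) == pytest.approx(4.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 1, (8, 8))
        tgt = rng.uniform(0, 1, (8, 8))
        g = ControlPointGrid.for_image((8, 8), 1.0, 3.0)
        expected = 0.0
        for i in range(8):
            for j in range(8):
                expected += (ref[i, j] - tgt[i, j]) ** 2
        expected /= 64.0
        assert ssd_cost(ref, tgt, g) == pytest.approx(expected, abs=1e-9)

    def test_empty_support_rejected(self):
        img = np.ones((8, 8))
        g = ControlPointGrid.for_image((8, 8), 1.0, 3.0)
        with pytest.raises(ValueError):
            ssd_cost(img, img, g, support=np.zeros((8, 8), bool))


class TestBendingEnergy:
    def test_zero_for_zero_field(self):
        g = ControlPointGrid.for_image((24, 24), 1.0, 6.0)
        assert bending_energy(g) == 0.0

    def test_zero_for_affine_fields(self):
        A = np.array([[0.2, -0.1], [0.05, 0.15]])
        g = affine_grid((24, 24), 1.0, 6.0, A, np.array([1.0, -2.0]))
        assert bending_energy(g) < 1e-10

    def test_single_bump_matches_finite_difference_quadrature(self):
        # incommensurate knot spacing so pixel centers avoid the knots,
        # where the third derivative jumps and central FD degrades
        g = ControlPointGrid.for_image((24, 24), 1.0, 5.3)
        g.coefficients[0, 4, 4] = 1.0
        g.coefficients[1, 5, 3] = -0.7
        rows, cols = g.pixel_coords_mm()
        pts = np.stack(
            [np.repeat(rows, cols.size), np.tile(cols, rows.size)], axis=1
        )
        h = 1e-3
        total = 0.0
        for c_ax in range(2):
            step = np.zeros(2)
            step[c_ax] = h
            upp = g.displacement(pts + step)
            umm = g.displacement(pts - step)
            u00 = g.displacement(pts)
            second = (upp - 2 * u00 + umm) / h**2  # d2u/dax2 for both comps
            if c_ax == 0:
                d2_rr = second
            else:
                d2_cc = second
        upp = g.displacement(pts + [h, h])
        upm = g.displacement(pts + [h, -h])
        ump = g.displacement(pts + [-h, h])
        umm = g.displacement(pts + [-h, -h])
        d2_rc = (upp - upm - ump + umm) / (4 * h**2)
        total = np.mean(
            np.sum(d2_rr**2, 1) + 2 * np.sum(d2_rc**2, 1) + np.sum(d2_cc**2, 1)
        )
        assert bending_energy(g) == pytest.approx(total, rel=1e-4)


class TestObjectiveGradient:
    def test_analytic_gradient_matches_central_differences(self):
        from cinestrain.ffd import _LevelProblem

        rng = np.random.default_rng(7)
        ref = smooth_texture((24, 24), 8)
        tgt = smooth_texture((24, 24), 9)
        cfg = RegistrationConfig(pyramid_levels=1, regularization_weight=0.05)
        grid = ControlPointGrid.for_image(ref.shape, 1.0, 6.0)
        prob = _LevelProblem(ref, tgt, grid, cfg, None)
        x0 = rng.normal(0, 0.4, grid.coefficients.size)
        _, g0 = prob(x0)
        h = 1e-5
        for i in rng.choice(x0.size, 25, replace=False):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            fd = (prob(xp)[0] - prob(xm)[0]) / (2 * h)
            denom = max(abs(fd), abs(g0[i]), 1e-10)
            assert abs(fd - g0[i]) / denom < 1e-4


class TestRegisterPair:
    def test_identity_input_returns_near_zero_field(self):
        img = smooth_texture((48, 48), 10)
        grid = register_pair(img, img.copy(), 1.0, RegistrationConfig(pyramid_levels=2))
        pts = np.stack(
            np.meshgrid(np.arange(8, 40, 2.0), np.arange(8, 40, 2.0), indexing="ij"),
            -1,
        ).reshape(-1, 2)
        u = evaluate_displacement(grid, pts)
        assert np.mean(np.abs(u)) < 0.1  # px (spacing 1 mm)

    def test_two_pixel_translation_recovered(self):
        img = smooth_texture((80, 80), 11)
        tgt = np.roll(img, -2, axis=0)  # tgt(X) = img(X + 2 rows)
        grid, info = register_pair(img, tgt, 1.0, RegistrationConfig(), return_info=True)
        pts = np.stack(
            np.meshgrid(np.arange(20, 60, 1.0), np.arange(20, 60, 1.0), indexing="ij"),
            -1,
        ).reshape(-1, 2)
        u = evaluate_displacement(grid, pts)
        assert np.abs(u.mean(axis=0) - [-2.0, 0.0]).max() < 0.2
        assert info["final_objective"] <= info["levels"][0]["initial_objective"]

    def test_objective_not_increased_from_init(self):
        img = smooth_texture((48, 48), 12)
        tgt = np.roll(img, 1, axis=1)
        cfg = RegistrationConfig(pyramid_levels=2, max_iterations=5)
        grid, info = register_pair(img, tgt, 1.0, cfg, return_info=True)
        for lvl in info["levels"]:
            assert lvl["final_objective"] <= lvl["initial_objective"] + 1e-15

    def test_deterministic_bit_identical(self):
        img = smooth_texture((48, 48), 13)
        tgt = np.roll(img, -1, axis=0)
        cfg = RegistrationConfig(pyramid_levels=2)
        g1 = register_pair(img, tgt, 1.0, cfg)
        g2 = register_pair(img, tgt, 1.0, cfg)
        assert np.array_equal(g1.coefficients, g2.coefficients)


class TestPhantomPair:
    def test_contraction_pair_ssd_reduction_and_warm_start(self):
        from cinestrain.phantom import PhantomSpec, render_phantom

        spec = PhantomSpec(image_size=48, endo_radius_mm=14.0, epi_radius_mm=20.0,
                           n_frames=6, noise_sd=0.0)
        series, mask, _ = render_phantom(spec)
        ref = series.frames[0]
        cfg = RegistrationConfig(pyramid_levels=2, max_iterations=300,
                                 convergence_tol=1e-9)
        zero = ControlPointGrid.for_image(ref.shape, series.pixel_spacing,
                                          cfg.control_spacing_mm)
        grid = register_pair(ref, series.frames[2], series.pixel_spacing, cfg)
        assert ssd_cost(ref, series.frames[2], grid) <= 0.1 * ssd_cost(
            ref, series.frames[2], zero
        )
        # warm start from the neighbouring solution reaches (essentially)
        # the same objective as a cold start
        _, cold = register_pair(ref, series.frames[3], series.pixel_spacing,
                                cfg, return_info=True)
        _, warm = register_pair(ref, series.frames[3], series.pixel_spacing,
                                cfg, init=grid, return_info=True)
        a, b = cold["final_objective"], warm["final_objective"]
        assert abs(a - b) <= 0.01 * max(a, b)


class TestTrackSequence:
    def test_static_series_gives_near_zero_fields(self):
        img = smooth_texture((48, 48), 14)
        series = CineSeries(
            frames=np.stack([img] * 4), pixel_spacing=1.0, reference_index=0
        )
        grids = track_sequence(series, config=RegistrationConfig(pyramid_levels=2))
        pts = np.stack(
            np.meshgrid(np.arange(8, 40, 2.0), np.arange(8, 40, 2.0), indexing="ij"),
            -1,
        ).reshape(-1, 2)
        for g in grids:
            assert np.mean(np.abs(evaluate_displacement(g, pts))) < 0.1

    def test_reference_frame_field_is_exactly_zero(self):
        img = smooth_texture((48, 48), 15)
        series = CineSeries(
            frames=np.stack([img, np.roll(img, 1, 0), img]),
            pixel_spacing=1.0,
            reference_index=1,
        )
        grids = track_sequence(series, config=RegistrationConfig(pyramid_levels=2))
        assert np.all(grids[1].coefficients == 0)
        assert len(grids) == 3


class TestGridGeometry:
    def test_grid_margin_covers_borders(self):
        g = ControlPointGrid.for_image((64, 64), 1.4, 8.0)
        # corners of the image must be strictly inside the support
        corners = [[0.0, 0.0], [0.0, 63 * 1.4], [63 * 1.4, 0.0], [63 * 1.4, 63 * 1.4]]
        u = evaluate_displacement(g, corners)
        assert np.allclose(u, 0)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            ControlPointGrid.for_image((32, 32), 1.0, -2.0)

    def test_nonfinite_coefficients_rejected(self):
        g = ControlPointGrid.for_image((16, 16), 1.0, 4.0)
        coef = g.coefficients.copy()
        coef[0, 2, 2] = np.nan
        with pytest.raises(ValueError):
            ControlPointGrid(g.spacing_mm, g.origin_mm, coef, g.image_shape, g.pixel_spacing)


class TestSplineImage:
    def test_reproduces_samples_at_integer_coordinates(self):
        img = smooth_texture((20, 20), 16)
        sp = SplineImage(img)
        ii, jj = np.meshgrid(np.arange(20.0), np.arange(20.0), indexing="ij")
        vals = sp.sample(ii.ravel(), jj.ravel())
        assert np.abs(vals - img.ravel()).max() < 1e-9

    def test_fill_outside_frame(self):
        img = np.ones((10, 10))
        sp = SplineImage(img)
        assert sp.sample([-3.0], [5.0], fill=7.0)[0] == 7.0
        assert sp.sample([5.0], [12.0], fill=7.0)[0] == 7.0
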