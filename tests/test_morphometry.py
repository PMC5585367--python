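import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroshape as sp
from tests.conftest import analytic_contour


def pratt_residual(pts, cx, cy, r):
    """Pratt's normalized algebraic circle residual, mean((d^2-r^2)^2)/(4r^2)
    — the quantity the fit minimizes; used as an independent optimality
    oracle evaluated directly from the circle parameters."""
    d = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 - r**2
    return float(np.mean(d**2) / (4 * r**2))


class TestFitCircle:
    def test_exact_four_point_circle(self):
        pts = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)], float)
        c = sp.fit_circle(pts)
        assert c.cx == pytest.approx(0, abs=1e-9)
        assert c.cy == pytest.approx(0, abs=1e-9)
        assert c.r == pytest.approx(1, abs=1e-9)

    def test_unit_square_corners(self):
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
        c = sp.fit_circle(pts)
        assert (c.cx, c.cy) == pytest.approx((0.5, 0.5), abs=1e-9)
        assert c.r == pytest.approx(math.sqrt(2) / 2, abs=1e-9)

    def test_wavy_boundary_near_unit_circle(self):
        pts = analytic_contour(lambda t: 1 + 0.05 * np.cos(16 * t), n=1000)
        c = sp.fit_circle(pts)
        assert math.hypot(c.cx, c.cy) < 1e-3
        assert abs(c.r - 1) < 1e-2
        # optimality: no better than the fit at the generating parameters
        assert pratt_residual(pts, c.cx, c.cy, c.r) <= pratt_residual(
            pts, 0.0, 0.0, 1.0
        ) * (1 + 1e-9)

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(sp.DegenerateCircleFitError):
            sp.fit_circle(pts)

    def test_pixel_scale_conditioning(self):
        # same circle at raster scale: the fit must not degrade
        pts = analytic_contour(lambda t: 140 + 2 * np.sin(5 * t), n=800, center=(255.5, 255.5))
        c = sp.fit_circle(pts)
        assert (c.cx, c.cy) == pytest.approx((255.5, 255.5), abs=0.05)
        assert c.r == pytest.approx(140, abs=0.1)

    @given(
        cx=st.floats(-50, 50),
        cy=st.floats(-50, 50),
        r=st.floats(0.5, 200),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None)
    def test_recovers_noiseless_circles(self, cx, cy, r, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 2 * math.pi, 50)
        pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
        if np.linalg.matrix_rank(pts - pts.mean(0), tol=1e-6 * r) < 2:
            return  # nearly collinear draw
        c = sp.fit_circle(pts)
        assert math.hypot(c.cx - cx, c.cy - cy) < 1e-6 * max(1, r)
        assert abs(c.r - r) < 1e-6 * max(1, r)


class TestDiscrepancySigma:
    def test_equal_radii_zero(self):
        prof = sp.RadialProfile(rho=np.ones(4), s=1.0)
        assert sp.discrepancy_sigma(prof) == 0.0

    def test_two_point_hand_value(self):
        prof = sp.radial_profile(
            np.array([(0.9, 0.0), (-1.1, 0.0)]), sp.FittedCircle(0, 0, 1)
        )
        assert prof.s == pytest.approx(1.0)
        assert sp.discrepancy_sigma(prof) == pytest.approx(0.1, abs=1e-12)

    def test_three_point_hand_value(self):
        prof = sp.RadialProfile(rho=np.array([0.8, 1.0, 1.2]), s=1.0)
        assert sp.discrepancy_sigma(prof) == pytest.approx(
            math.sqrt(0.08 / 3), abs=1e-12
        )

    def test_single_point_insufficient(self):
        with pytest.raises(sp.InsufficientPointsError):
            sp.discrepancy_sigma(sp.RadialProfile(rho=np.array([1.0]), s=1.0))

    def test_circle_reference_mode(self):
        pts = analytic_contour(lambda t: 1.1 * np.ones_like(t), n=100)
        prof = sp.radial_profile(pts, sp.FittedCircle(0, 0, 1), sigma_mode="circle_reference")
        # all rho = 1.1, s fixed at 1: sigma is the offset, not zero
        assert sp.discrepancy_sigma(prof) == pytest.approx(0.1, abs=1e-9)

    @given(
        rho=st.lists(st.floats(0.5, 1.5), min_size=2, max_size=50),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_nonnegative(self, rho, seed):
        rho = np.array(rho)
        rng = np.random.default_rng(seed)
        a = sp.discrepancy_sigma(sp.RadialProfile(rho=rho, s=float(rho.mean())))
        shuffled = rng.permutation(rho)
        b = sp.discrepancy_sigma(
            sp.RadialProfile(rho=shuffled, s=float(shuffled.mean()))
        )
        assert a >= 0
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)


QUAD_N = 100_000


def quadrature_sigma(r_of_theta, lo=0.0, hi=2 * math.pi):
    """Population std of a continuous normalized radial profile by dense
    midpoint quadrature — the independent oracle for R and per-sector sigma."""
    t = lo + (np.arange(QUAD_N) + 0.5) * (hi - lo) / QUAD_N
    rho = r_of_theta(t)
    return float(np.sqrt(np.mean((rho - rho.mean()) ** 2)))


class TestRoundness:
    def test_exact_circle_zero(self):
        pts = analytic_contour(lambda t: np.ones_like(t), n=3000)
        circle = sp.fit_circle(pts)
        assert sp.roundness(pts, circle) < 1e-6

    @pytest.mark.parametrize("mode", [2, 16])
    def test_cosine_mode_matches_quadrature(self, mode):
        # R measures amplitude only: same value for the global mode-2
        # ellipse and a high-frequency ripple of equal amplitude
        f = lambda t: 1 + 0.05 * np.cos(mode * t)
        pts = analytic_contour(f, n=4000)
        circle = sp.fit_circle(pts)
        expected = quadrature_sigma(f)
        assert expected == pytest.approx(0.05 / math.sqrt(2), rel=1e-4)
        assert sp.roundness(pts, circle) == pytest.approx(expected, rel=0.03)


class TestSmoothness:
    def test_exact_circle_zero(self):
        pts = analytic_contour(lambda t: np.ones_like(t), n=3000)
        circle = sp.fit_circle(pts)
        chi, n_valid = sp.smoothness(pts, circle, 32)
        assert chi < 1e-6
        assert n_valid == 32

    def test_ellipse_local_far_below_global(self):
        f = lambda t: 1 + 0.05 * np.cos(2 * t)
        pts = analytic_contour(f, n=6400)
        circle = sp.fit_circle(pts)
        chi, _ = sp.smoothness(pts, circle, 32)
        assert chi <= 0.25 * sp.roundness(pts, circle)

    def test_sin16_matches_half_wave_closed_form(self):
        f = lambda t: 1 + 0.05 * np.sin(16 * t)
        pts = analytic_contour(f, n=6400)
        chi, _ = sp.smoothness(pts, sp.fit_circle(pts), 32)
        closed_form = 0.05 * math.sqrt(0.5 - 4 / math.pi**2)
        # cross-check the closed form by per-sector quadrature
        quad = np.mean(
            [
                quadrature_sigma(f, k * math.pi / 16, (k + 1) * math.pi / 16)
                for k in range(32)
            ]
        )
        assert quad == pytest.approx(closed_form, rel=1e-4)
        assert chi == pytest.approx(closed_form, rel=0.05)

    def test_high_mode_chi_approaches_R(self):
        # wavelengths shorter than every sector: local spread == global spread
        modes = tuple(range(64, 81))
        a = 0.04 / math.sqrt(len(modes))
        rng = np.random.default_rng(5)
        phases = rng.uniform(0, 2 * math.pi, len(modes))
        f = lambda t: 1 + sum(
            a * np.cos(k * t + p) for k, p in zip(modes, phases)
        )
        pts = analytic_contour(f, n=20000)
        circle = sp.fit_circle(pts)
        chi, _ = sp.smoothness(pts, circle, 32)
        ratio = chi / sp.roundness(pts, circle)
        assert 0.8 < ratio < 1.05

    def test_sparse_sectors_excluded(self):
        # half-moon of points: only half the sectors can be valid
        t = np.linspace(0.01, math.pi - 0.01, 400)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        chi, n_valid = sp.smoothness(pts, sp.FittedCircle(0, 0, 1), 32)
        assert n_valid == 16
        assert chi >= 0

    def test_no_valid_sector_is_error(self):
        pts = np.array([(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0)])
        with pytest.raises(sp.InsufficientPointsError):
            sp.smoothness(pts, sp.FittedCircle(0, 0, 1), 32)


class TestSectorPartition:
    def test_half_open_cover(self):
        part = sp.SectorPartition(32)
        circle = sp.FittedCircle(0, 0, 1)
        t = np.array(
            [0.0, math.pi / 16 - 1e-9, math.pi / 16 + 1e-9, 2 * math.pi - 1e-9]
        )
        pts = np.column_stack([np.cos(t), np.sin(t)])
        idx = part.assign(pts, circle)
        assert list(idx) == [0, 0, 1, 31]

    def test_every_point_assigned_once(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, (500, 2))
        idx = sp.SectorPartition(32).assign(pts, sp.FittedCircle(0, 0, 1))
        assert idx.min() >= 0 and idx.max() <= 31
        assert len(idx) == 500


class TestAnalyze:
    def test_smooth_scene_near_zero_metrics(self, smooth_scene):
        _, truth, img = smooth_scene
        m = sp.analyze(img)
        assert truth.true_R == 0.0 and truth.true_chi == 0.0
        assert m.R < 0.01 and m.chi < 0.01
        assert m.satellite_count == 0
        assert m.n_valid_sectors == 32

    def test_rough_scene_rougher_than_smooth(self, smooth_scene):
        m_smooth = sp.analyze(smooth_scene[2])
        spec = sp.rough_spec(0.08, seed=1)
        m_rough = sp.analyze(sp.render(spec))
        assert m_rough.chi > m_smooth.chi

    def test_blank_image_error_tagged_with_stage(self):
        with pytest.raises(sp.NoSpheroidFoundError) as exc:
            sp.analyze(sp.GrayImage(np.full((128, 128), 7.0)))
        assert exc.value.stage == "segment"

    def test_deterministic(self, smooth_scene):
        m1 = sp.analyze(smooth_scene[2])
        m2 = sp.analyze(smooth_scene[2])
        assert m1.R == m2.R and m1.chi == m2.chi

    def test_area_um2_propagates(self, smooth_scene):
        img = sp.GrayImage(smooth_scene[2].pixels, pixel_size_um=2.0)
        m = sp.analyze(img)
        assert m.area_um2 == m.area_px * 4.0
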