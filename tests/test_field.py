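"""Gaussian chemokine field: values, gradients, invariances, raster."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elnsim.field import (GaussianFieldRaster, GaussianSource, GradientField,
                          tumor_direction)


def random_field(rng, n_sources, sigma_range=(50.0, 400.0)):
    sources = [GaussianSource(*(rng.uniform(-1000, 1000, 2)),
                              amplitude=rng.uniform(0.2, 2.0),
                              sigma=rng.uniform(*sigma_range))
               for _ in range(n_sources)]
    return GradientField(sources)


class TestConcentration:
    def test_empty_field_is_zero(self):
        f = GradientField([])
        assert f.concentration(np.array([12.3, -4.0])) == 0.0

    def test_peak_height_at_center(self):
        f = GradientField([GaussianSource(10.0, -5.0, amplitude=1.0)])
        assert f.concentration(np.array([10.0, -5.0])) == pytest.approx(1.0)

    def test_one_sigma_value(self):
        # frozen scalar oracle: exp(-1/2) at one sigma from a unit source
        f = GradientField([GaussianSource(0.0, 0.0, 1.0, sigma=200.0)])
        val = f.concentration(np.array([200.0, 0.0]))
        assert val == pytest.approx(np.exp(-0.5), rel=1e-12)
        assert val == pytest.approx(0.6065306597126334, rel=1e-12)

    def test_additivity(self):
        rng = np.random.default_rng(3)
        fa, fb = random_field(rng, 3), random_field(rng, 4)
        union = GradientField(fa.sources + fb.sources)
        pts = rng.uniform(-1500, 1500, (20, 2))
        np.testing.assert_allclose(
            union.concentration(pts),
            fa.concentration(pts) + fb.concentration(pts), rtol=1e-12)

    def test_monotone_in_source_count(self):
        rng = np.random.default_rng(4)
        f = random_field(rng, 6)
        pts = rng.uniform(-2000, 2000, (50, 2))
        prev = np.zeros(50)
        for k in range(1, 7):
            cur = GradientField(f.sources[:k]).concentration(pts)
            assert np.all(cur >= prev)
            prev = cur

    def test_rotational_invariance(self):
        rng = np.random.default_rng(5)
        f = random_field(rng, 4)
        theta = 1.234
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        rotated = GradientField([
            GaussianSource(*(rot @ [src.x, src.y]), src.amplitude, src.sigma)
            for src in f.sources])
        pts = rng.uniform(-1000, 1000, (20, 2))
        np.testing.assert_allclose(rotated.concentration(pts @ rot.T),
                                   f.concentration(pts), rtol=1e-10)
        np.testing.assert_allclose(rotated.gradient(pts @ rot.T),
                                   f.gradient(pts) @ rot.T, atol=1e-12)


class TestGradient:
    def test_zero_at_single_source_center(self):
        f = GradientField([GaussianSource(3.0, 4.0)])
        np.testing.assert_allclose(f.gradient(np.array([3.0, 4.0])), 0.0)

    def test_cancels_at_midpoint_of_equal_pair(self):
        f = GradientField([GaussianSource(-100.0, 0.0),
                           GaussianSource(100.0, 0.0)])
        np.testing.assert_allclose(f.gradient(np.array([0.0, 0.0])), 0.0,
                                   atol=1e-15)

    def test_matches_finite_differences(self):
        # the acceptance-level oracle at reduced size
        rng = np.random.default_rng(6)
        for _ in range(50):
            f = random_field(rng, rng.integers(1, 6))
            p = rng.uniform(-1200, 1200, 2)
            _assert_gradient_matches_fd(f, p)

    def test_points_uphill(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            f = random_field(rng, 3)
            p = rng.uniform(-800, 800, 2)
            g = f.gradient(p)
            if np.linalg.norm(g) < 1e-12:
                continue
            step = 1e-3 * g / np.linalg.norm(g)
            assert f.concentration(p + step) >= f.concentration(p)


def _assert_gradient_matches_fd(f, p, h=1e-3, rtol=1e-6):
    g = f.gradient(p)
    fd = np.array([
        (f.concentration(p + [h, 0]) - f.concentration(p - [h, 0])) / (2 * h),
        (f.concentration(p + [0, h]) - f.concentration(p - [0, h])) / (2 * h)])
    scale = max(np.linalg.norm(fd), 1e-9)
    np.testing.assert_allclose(g, fd, atol=rtol * scale)


class TestTumorDirection:
    def test_axis_aligned(self):
        np.testing.assert_allclose(
            tumor_direction(np.array([100.0, 0.0])), [-1.0, 0.0])

    @given(st.floats(0.01, 1e4), st.integers(0, 628))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unit_norm(self, k, centi_angle):
        theta = centi_angle / 100.0
        p = k * np.array([np.cos(theta), np.sin(theta)]) * 5.0
        d = tumor_direction(p)
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)
        # points back at the center
        np.testing.assert_allclose(p + np.linalg.norm(p) * d, 0.0, atol=1e-8)

    def test_zero_at_singular_point(self):
        np.testing.assert_allclose(tumor_direction(np.array([0.0, 0.0])), 0.0)


class TestValidation:
    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            GaussianSource(0, 0, sigma=0.0)

    def test_bad_amplitude(self):
        with pytest.raises(ValueError):
            GaussianSource(0, 0, amplitude=-1.0)

    def test_nonfinite_center(self):
        with pytest.raises(ValueError):
            GaussianSource(np.inf, 0)


class TestRaster:
    def test_matches_analytic_field(self):
        rng = np.random.default_rng(8)
        sigma = 200.0
        raster = GaussianFieldRaster(center=(2000.0, 0.0), half_extent=750.0,
                                     spacing=20.0, sigma=sigma)
        sources = []
        for _ in range(12):
            x, y = 2000 + rng.uniform(-700, 700), rng.uniform(-700, 700)
            raster.add_source(x, y)
            sources.append(GaussianSource(x, y, 1.0, sigma))
        f = GradientField(sources)
        pts = np.column_stack([2000 + rng.uniform(-900, 900, 300),
                               rng.uniform(-900, 900, 300)])
        exact = f.gradient(pts)
        approx = raster.sample_gradient(pts)
        scale = np.abs(exact).max()
        # bilinear error ~ (spacing/sigma)^2 / 8 of the local curvature scale
        np.testing.assert_allclose(approx, exact, atol=4e-3 * scale)

    def test_zero_outside_and_without_sources(self):
        raster = GaussianFieldRaster(center=(0.0, 0.0), half_extent=100.0,
                                     spacing=10.0, sigma=50.0)
        pts = np.array([[0.0, 0.0], [1e5, 1e5]])
        np.testing.assert_allclose(raster.sample_gradient(pts), 0.0)
        raster.add_source(0.0, 0.0)
        assert np.all(raster.sample_gradient(np.array([[1e5, 1e5]])) == 0.0)
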