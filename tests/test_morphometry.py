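"""Geometry primitives and the derived fiber-metric formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cottonsect import (
    COTTON_DENSITY_G_CM3,
    CalibrationScale,
    Contour,
    MorphometryError,
    ShapeMeasures,
    bounding_dims,
    circularity,
    derive_fiber_metrics,
    fineness_of,
    maturity_ratio_of,
    polygon_area,
    polygon_perimeter,
    standard_fineness_of,
    theta_of,
)
from cottonsect.morphometry import DegenerateContourError

from conftest import regular_polygon, star_polygon


class TestContour:
    def test_orientation_normalized_ccw(self):
        cw = Contour([(0, 0), (0, 1), (1, 1), (1, 0)])  # negative shoelace as given
        assert cw.area_px() > 0

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0), (1, 1)],  # too few
            [(0, 0), (1, 1), (2, 2)],  # collinear: zero area
            [(0, 0), (1, 1), (1, 0), (0, 1)],  # bowtie self-intersection
        ],
    )
    def test_invalid_contours_rejected(self, points):
        with pytest.raises(DegenerateContourError):
            Contour(points)

    def test_closing_vertex_dropped(self):
        c = Contour([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert len(c) == 4


class TestCalibrationScale:
    def test_um_per_px_is_quotient(self):
        s = CalibrationScale(reference_length_um=50.0, reference_length_px=400.0)
        assert s.um_per_px == pytest.approx(0.125)

    @pytest.mark.parametrize("um,px", [(0, 1), (1, 0), (-2, 5)])
    def test_nonpositive_reference_rejected(self, um, px):
        with pytest.raises(MorphometryError):
            CalibrationScale(reference_length_um=um, reference_length_px=px)


class TestAreaPerimeter:
    def test_unit_square(self, unit_square, unit_scale):
        assert polygon_area(unit_square, unit_scale) == pytest.approx(1.0)
        assert polygon_perimeter(unit_square, unit_scale) == pytest.approx(4.0)

    def test_area_scales_quadratically_perimeter_linearly(self, unit_square):
        s2 = CalibrationScale.from_um_per_px(2.0)
        assert polygon_area(unit_square, s2) == pytest.approx(4.0)
        assert polygon_perimeter(unit_square, s2) == pytest.approx(8.0)

    def test_regular_360gon_approaches_circle(self, unit_scale):
        r = 10.0
        c = regular_polygon(360, r)
        assert polygon_perimeter(c, unit_scale) == pytest.approx(2 * math.pi * r, rel=1e-4)
        assert polygon_area(c, unit_scale) == pytest.approx(math.pi * r * r, rel=1e-3)

    def test_area_matches_rasterization_oracle(self, unit_scale):
        """Shoelace area of a random convex 12-gon ≈ pixel-count area (1%)."""
        rng = np.random.default_rng(42)
        from skimage.draw import polygon as raster_polygon

        for _ in range(5):
            phi = np.sort(rng.uniform(0, 2 * np.pi, 12))
            r = 250.0  # ~500 px across
            pts = np.c_[300 + r * np.cos(phi), 300 + r * np.sin(phi)]
            c = Contour(pts)
            rr, cc = raster_polygon(pts[:, 1], pts[:, 0], (600, 600))
            assert polygon_area(c, unit_scale) == pytest.approx(len(rr), rel=0.01)

    def test_perimeter_matches_brute_force_resummation(self, unit_scale):
        rng = np.random.default_rng(3)
        c = star_polygon(rng, n=17, radius=40.0)
        pts = c.points
        brute = sum(
            math.dist(pts[i], pts[(i + 1) % len(pts)]) for i in range(len(pts))
        )
        assert polygon_perimeter(c, unit_scale) == pytest.approx(brute, rel=1e-12)


class TestCircularityAndDims:
    def test_circle_is_one_square_is_pi_over_4(self):
        r = 3.0
        assert circularity(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)
        assert circularity(1.0, 4.0) == pytest.approx(math.pi / 4)

    def test_printed_line_mean_outer_shell(self):
        # a line's printed means: outer area = wall 115.49 + lumen 13.59,
        # outer perimeter 55.45 → outer circularity 0.53
        assert circularity(115.49 + 13.59, 55.45) == pytest.approx(0.53, abs=0.005)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(MorphometryError):
            circularity(0.0, 1.0)
        with pytest.raises(MorphometryError):
            circularity(1.0, -1.0)

    def test_bounding_dims_rectangle(self, unit_scale):
        rect = Contour([(0, 0), (2, 0), (2, 1), (0, 1)])  # long in x
        assert bounding_dims(rect, unit_scale) == pytest.approx((1.0, 2.0))

    def test_bounding_dims_rotated_matches_coordinate_scan(self, unit_scale):
        rng = np.random.default_rng(11)
        c = star_polygon(rng, n=15, radius=20.0)
        ang = 0.7
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        rc = c.transformed(lambda p: p @ R.T)
        h, w = bounding_dims(rc, unit_scale)
        assert h == pytest.approx(np.ptp(rc.points[:, 1]))
        assert w == pytest.approx(np.ptp(rc.points[:, 0]))


def _measures(area, perimeter):
    return ShapeMeasures(
        area=area,
        perimeter=perimeter,
        circularity=circularity(area, perimeter),
        height=1.0,
        width=1.0,
    )


class TestDerivedMetrics:
    def test_reference_line_2888_printed_means(self):
        """θ, fineness, maturity from the printed light-microscope means."""
        assert theta_of(102.58, 48.07) == pytest.approx(0.56, abs=0.005)
        assert fineness_of(102.58) == pytest.approx(155.92, abs=0.005)
        assert maturity_ratio_of(0.56) == pytest.approx(0.97, abs=0.005)
        assert maturity_ratio_of(0.93) == pytest.approx(1.61, abs=0.005)

    def test_full_record_consistency(self):
        lumen = _measures(14.0, 15.0)
        outer = _measures(150.0, 50.0)
        fm = derive_fiber_metrics(lumen, outer, name="f", line="L")
        assert fm.outer_true_area == pytest.approx(outer.area - lumen.area)
        # conservation is exact
        assert fm.outer.area == fm.outer_true_area + fm.lumen.area
        assert fm.outer_lumen_ratio == pytest.approx(fm.outer_true_area / lumen.area)
        assert fm.fineness == pytest.approx(COTTON_DENSITY_G_CM3 * fm.outer_true_area)
        assert fm.maturity_ratio * 0.577 == pytest.approx(fm.theta, rel=1e-14)
        assert fm.standard_fineness * fm.theta == pytest.approx(0.577 * fm.fineness, rel=1e-14)

    def test_solid_disc_theta_limit(self):
        """A lumen-less circular fiber sits at the isoperimetric limit θ → 1."""
        r = 5.0
        assert theta_of(math.pi * r * r, 2 * math.pi * r) == pytest.approx(1.0)

    def test_lumen_exceeding_fiber_rejected(self):
        with pytest.raises(MorphometryError, match="lumen exceeds fiber"):
            derive_fiber_metrics(_measures(150.0, 50.0), _measures(150.0, 50.0))

    def test_fineness_linear_in_wall_area(self):
        a = np.linspace(10, 300, 7)
        f = np.array([fineness_of(x) for x in a])
        slope = np.diff(f) / np.diff(a)
        assert np.allclose(slope, 1.52)

    @given(st.floats(0.05, 0.99))
    @settings(deadline=None, max_examples=25)
    def test_maturity_standard_fineness_identities(self, theta):
        f = 200.0
        assert maturity_ratio_of(theta) * 0.577 == pytest.approx(theta, rel=1e-12)
        assert standard_fineness_of(f, theta) * theta == pytest.approx(0.577 * f, rel=1e-12)

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=25)
    def test_theta_and_circularity_scale_invariant(self, k):
        """Dimensionless descriptors are unchanged by uniform scaling."""
        a, p = 120.0, 47.0
        assert theta_of(a * k * k, p * k) == pytest.approx(theta_of(a, p), rel=1e-12)
        assert circularity(a * k * k, p * k) == pytest.approx(circularity(a, p), rel=1e-12)
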