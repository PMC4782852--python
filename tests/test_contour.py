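"""Cross-section metrology: perimeter, diameter fan, circularity ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shagginess.contour import (
    Contour,
    circularity_ratio,
    diameter_fan,
    perimeter,
    resample_contour,
    slice_irregularity,
)
from shagginess.errors import CenterOutsideContourError, InvalidContourError

from conftest import circle_contour_points, ellipse_contour_points
from oracles import brute_diameters, brute_perimeter, polar_section_C

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestContourConstruction:
    def test_cw_input_reoriented_ccw(self):
        c = Contour(UNIT_SQUARE[::-1])
        assert c.area > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidContourError):
            Contour(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(InvalidContourError):
            Contour(bowtie)

    def test_zero_area_rejected(self):
        with pytest.raises(InvalidContourError):
            Contour(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))


class TestPerimeter:
    def test_unit_square(self):
        assert perimeter(Contour(UNIT_SQUARE)) == pytest.approx(4.0)

    def test_regular_720gon_closed_form(self):
        # inscribed n-gon perimeter is 2 n R sin(pi/n)
        c = Contour(circle_contour_points(R=10.0, n=720))
        assert perimeter(c) == pytest.approx(2 * 720 * 10 * math.sin(math.pi / 720), rel=1e-12)
        assert perimeter(c) == pytest.approx(62.83165370035062, rel=1e-9)

    def test_ellipse_matches_arc_length_quadrature(self):
        c = Contour(ellipse_contour_points(15.0, 10.0, 720))
        assert perimeter(c) == pytest.approx(79.327, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_summation(self, seed):
        from oracles import random_star_polygon

        pts = random_star_polygon(np.random.default_rng(seed))
        assert perimeter(Contour(pts)) == pytest.approx(brute_perimeter(pts), rel=1e-12)


class TestResample:
    def test_square_to_eight_vertices_preserves_perimeter(self):
        r = resample_contour(Contour(UNIT_SQUARE), 8)
        assert len(r) == 8
        assert perimeter(r) == pytest.approx(4.0)

    def test_coarse_circle_upsampled(self):
        # 32-gon upsampled to 720 vertices: new vertices stay on the 32-gon
        # chords, so the perimeter equals the n-gon closed form 2 n R sin(pi/n)
        # (720/32 is not integer, so polygon corners are slightly cut)
        c = resample_contour(Contour(circle_contour_points(10.0, 32)), 720)
        assert len(c) == 720
        ngon = 2 * 32 * 10 * math.sin(math.pi / 32)
        assert perimeter(c) <= ngon + 1e-12
        assert perimeter(c) == pytest.approx(ngon, rel=2e-4)
        assert perimeter(c) == pytest.approx(2 * np.pi * 10, rel=2e-3)

    def test_equal_spacing(self):
        # equal arc-length steps along the source polyline; chord lengths can
        # only dip where a step straddles an original vertex
        r = resample_contour(Contour(circle_contour_points(10.0, 77)), 360)
        closed = np.vstack([r.points, r.points[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        total = perimeter(Contour(circle_contour_points(10.0, 77)))
        assert np.allclose(gaps, total / 360, rtol=1e-3)
        assert perimeter(r) <= total + 1e-12
        assert perimeter(r) == pytest.approx(total, rel=2e-4)

    def test_degenerate_input_rejected(self):
        with pytest.raises(InvalidContourError):
            Contour(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestDiameterFan:
    def test_circle_centered(self):
        fan = diameter_fan(Contour(circle_contour_points(10.0, 720)), (0.0, 0.0))
        assert fan.n_angles == 180
        assert np.allclose(fan.diameters, 20.0, atol=2e-3)
        assert fan.mean_diameter == pytest.approx(20.0, rel=1e-4)

    def test_offset_center_closed_form(self):
        # chord through a point offset by d from a circle center:
        # 2 sqrt(R^2 - d^2 sin^2 phi)
        fan = diameter_fan(Contour(circle_contour_points(10.0, 2880)), (2.0, 0.0))
        phis = np.arange(180) * np.pi / 180
        expected = 2 * np.sqrt(100 - 4 * np.sin(phis) ** 2)
        assert np.max(np.abs(fan.diameters - expected) / expected) < 1e-5

    def test_offset_center_matches_bruteforce(self):
        pts = circle_contour_points(10.0, 720)
        fan = diameter_fan(Contour(pts), (2.0, 0.0))
        assert np.allclose(fan.diameters, brute_diameters(pts, (2.0, 0.0)), rtol=1e-9)

    def test_ellipse_mean_diameter(self):
        # 2ab / sqrt(a^2 sin^2 + b^2 cos^2) averaged over the fan angles
        fan = diameter_fan(Contour(ellipse_contour_points(15.0, 10.0, 1440)), (0.0, 0.0))
        assert fan.mean_diameter == pytest.approx(24.2456, rel=5e-3)

    def test_center_outside_raises_with_center(self):
        with pytest.raises(CenterOutsideContourError) as ei:
            diameter_fan(Contour(circle_contour_points(10.0, 720)), (15.0, 0.0))
        assert ei.value.center == (15.0, 0.0)

    def test_farthest_policy_on_nonconvex(self):
        # deep dent: first crossing sees the dent, farthest sees the outer wall
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        r = 10 - 6 * np.exp(-0.5 * ((np.angle(np.exp(1j * th))) / 0.12) ** 2)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        c = Contour(pts)
        first = diameter_fan(c, (0.0, 0.0), policy="first")
        far = diameter_fan(c, (0.0, 0.0), policy="farthest")
        assert far.mean_diameter >= first.mean_diameter
        assert first.diameters[0] < far.diameters[0]


class TestCircularityRatio:
    def test_circle_is_one(self):
        assert circularity_ratio(62.8319, 20.0) == pytest.approx(1.0, abs=1e-4)

    def test_ellipse_from_measured_quantities(self):
        c = Contour(ellipse_contour_points(15.0, 10.0, 1440))
        A = perimeter(c)
        B = diameter_fan(c, (0.0, 0.0)).mean_diameter
        assert circularity_ratio(A, B) == pytest.approx(1.041454, rel=1e-3)

    def test_lobed_against_quadrature(self):
        # r = 10 (1 + 0.05 sin 8 theta); small-amplitude expansion gives
        # C ~ 1 + k^2 eps^2 / 4 = 1.04; quadrature gives 1.038896
        th = np.linspace(0, 2 * np.pi, 200_001)
        r = 10 * (1 + 0.05 * np.sin(8 * th))
        x, y = r * np.cos(th), r * np.sin(th)
        s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
        si = np.linspace(0, s[-1], 1440, endpoint=False)
        c = Contour(np.column_stack([np.interp(si, s, x), np.interp(si, s, y)]))
        C = circularity_ratio(perimeter(c), diameter_fan(c, (0.0, 0.0)).mean_diameter)
        assert C == pytest.approx(1.0388959924505683, rel=1e-2)
        assert C == pytest.approx(1.04, abs=5e-3)

    def test_printed_pi_option(self):
        assert circularity_ratio(62.8319, 20.0, pi_value=3.14) == pytest.approx(
            62.8319 / (3.14 * 20.0)
        )

    @pytest.mark.parametrize("A,B", [(0.0, 20.0), (60.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, A, B):
        with pytest.raises(ValueError):
            circularity_ratio(A, B)


class TestSliceIrregularity:
    @pytest.mark.parametrize("C,expected", [(1.0, 0.0), (1.0825, 8.25), (1.12441, 12.441)])
    def test_values(self, C, expected):
        assert slice_irregularity(C) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            slice_irregularity(0.0)


class TestInvariances:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        angle=st.floats(0, 2 * math.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_perimeter_rigid_invariance(self, angle, tx, ty):
        pts = ellipse_contour_points(15.0, 10.0, 360)
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pts @ R.T + [tx, ty]
        assert perimeter(Contour(moved)) == pytest.approx(perimeter(Contour(pts)), rel=1e-12)

    @pytest.mark.parametrize("scale", [0.1, 2.0, 37.5])
    def test_circularity_scale_invariance(self, scale):
        pts = ellipse_contour_points(15.0, 10.0, 720)
        def C_of(p):
            c = Contour(p)
            return circularity_ratio(perimeter(c), diameter_fan(c, (0.0, 0.0)).mean_diameter)
        assert C_of(pts * scale) == pytest.approx(C_of(pts), rel=1e-9)

    def test_convex_shapes_score_at_least_one(self):
        # exact convex polygons, and smooth shapes sampled densely enough
        # that the inscribed-polygon perimeter deficit (pi^2/6n^2, ~2e-7 at
        # n=2880) stays below the 1e-6 bound
        shapes = [
            circle_contour_points(10.0, 5),    # regular pentagon, exact
            circle_contour_points(10.0, 12),   # regular 12-gon, exact
            circle_contour_points(10.0, 2880),
            ellipse_contour_points(15.0, 10.0, 2880),
        ]
        for pts in shapes:
            c = Contour(pts)
            C = circularity_ratio(perimeter(c), diameter_fan(c, (0.0, 0.0)).mean_diameter)
            assert C >= 1 - 1e-6

    def test_monotone_in_lobe_amplitude(self):
        th = np.linspace(0, 2 * np.pi, 200_001)
        values = []
        for eps in (0.0, 0.02, 0.05, 0.10):
            r = 10 * (1 + eps * np.sin(8 * th))
            x, y = r * np.cos(th), r * np.sin(th)
            s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
            si = np.linspace(0, s[-1], 1440, endpoint=False)
            c = Contour(np.column_stack([np.interp(si, s, x), np.interp(si, s, y)]))
            values.append(
                circularity_ratio(perimeter(c), diameter_fan(c, (0.0, 0.0)).mean_diameter)
            )
        assert np.all(np.diff(values) > 0)
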