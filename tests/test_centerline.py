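"""Central luminal line extraction and arc-length resampling."""

import numpy as np
import pytest

from shagginess.centerline import (
    Centerline,
    VolumeGrid,
    extract_centerline,
    smooth_and_resample,
)
from shagginess.errors import DisconnectedSeedsError, SeedError
from shagginess.phantom import CrossSectionSpec, PhantomSpec, rasterize_phantom
from shagginess.validation import centerline_rms_voxels


@pytest.fixture(scope="module")
def straight_tube():
    return rasterize_phantom(
        PhantomSpec(path="straight", length_mm=150.0, section=CrossSectionSpec("circle", R=10.0))
    )


@pytest.fixture(scope="module")
def arc_tube():
    # 90-degree bend: arc length = bend_radius * pi/2
    return rasterize_phantom(
        PhantomSpec(
            path="arc",
            length_mm=60.0 * np.pi / 2,
            bend_radius_mm=60.0,
            section=CrossSectionSpec("circle", R=10.0),
        )
    )


class TestExtractCenterline:
    def test_straight_tube_recovery(self, straight_tube):
        p, d = straight_tube.seed_points()
        cl = extract_centerline(straight_tube.volume, p, d)
        assert centerline_rms_voxels(straight_tube, cl) < 0.5

    def test_straight_tube_length(self, straight_tube):
        p, d = straight_tube.seed_points(inset_mm=3.0)
        cl = extract_centerline(straight_tube.volume, p, d)
        assert cl.length == pytest.approx(150.0 - 6.0, rel=0.01)

    def test_arc_tube_recovery(self, arc_tube):
        p, d = arc_tube.seed_points()
        cl = extract_centerline(arc_tube.volume, p, d)
        assert centerline_rms_voxels(arc_tube, cl) < 1.0

    def test_rigid_motion_equivariance(self, straight_tube):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.deg2rad(25.0) * np.array([1.0, 2.0, 0.5]) / np.sqrt(5.25))
        spec = straight_tube.spec
        rotated = rasterize_phantom(
            PhantomSpec(
                path="straight",
                length_mm=spec.length_mm,
                section=spec.section,
                rotation=tuple(R.as_matrix().ravel()),
            )
        )
        p, d = rotated.seed_points()
        cl = extract_centerline(rotated.volume, p, d)
        # compare to the rotated true axis
        assert centerline_rms_voxels(rotated, cl) < 0.5

    def test_empty_mask_rejected(self):
        vol = VolumeGrid(np.zeros((10, 10, 10)), np.eye(4))
        with pytest.raises(SeedError):
            extract_centerline(vol, (5.0, 5.0, 1.0), (5.0, 5.0, 8.0))

    def test_seed_outside_mask_rejected(self, straight_tube):
        p, d = straight_tube.seed_points()
        with pytest.raises(SeedError):
            extract_centerline(straight_tube.volume, p + np.array([30.0, 0, 0]), d)

    def test_disconnected_seeds_report_component_sizes(self):
        vox = np.zeros((9, 9, 20))
        vox[3:6, 3:6, 1:6] = 1.0    # 45 voxels
        vox[3:6, 3:6, 10:18] = 1.0  # 72 voxels
        vol = VolumeGrid(vox, np.eye(4))
        with pytest.raises(DisconnectedSeedsError) as ei:
            extract_centerline(vol, (4.0, 4.0, 3.0), (4.0, 4.0, 14.0))
        assert {ei.value.size_proximal, ei.value.size_distal} == {45, 72}


class TestSmoothAndResample:
    def test_straight_line_spacing_1p5(self):
        z = np.linspace(0.0, 150.0, 301)
        cl = smooth_and_resample(
            Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z])), 1.5
        )
        assert len(cl) == 101
        gaps = np.diff(cl.arclength)
        assert np.allclose(gaps, 1.5, atol=1e-6)
        steps = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.allclose(steps, 1.5, atol=1e-6)

    def test_upper_band_spacing_1p7(self):
        z = np.linspace(0.0, 170.0, 341)
        cl = smooth_and_resample(
            Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z])), 1.7
        )
        assert np.allclose(np.linalg.norm(np.diff(cl.points, axis=0), axis=1), 1.7, atol=1e-6)

    def test_helix_tangents_match_analytic(self):
        radius, pitch = 30.0, 40.0
        turn = np.hypot(2 * np.pi * radius, pitch)
        s = np.linspace(0.0, 2 * turn, 4001)
        phi = 2 * np.pi * s / turn
        pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), pitch * s / turn])
        cl = smooth_and_resample(Centerline(pts), 1.2, smooth_window_mm=0.0)
        phi_r = 2 * np.pi * cl.arclength / turn
        w = 2 * np.pi * radius / turn
        t_true = np.column_stack(
            [-w * np.sin(phi_r), w * np.cos(phi_r), np.full_like(phi_r, pitch / turn)]
        )
        dots = np.clip(np.sum(cl.tangents * t_true, axis=1), -1, 1)
        assert np.degrees(np.arccos(dots[1:-1])).max() < 1.0

    def test_idempotent_on_regular_input(self):
        z = np.arange(0.0, 150.1, 1.5)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        cl1 = smooth_and_resample(Centerline(pts), 1.5)
        cl2 = smooth_and_resample(cl1, 1.5)
        assert np.max(np.abs(cl2.points - cl1.points)) < 1e-6

    def test_spacing_exceeding_length_rejected(self):
        cl = Centerline(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]))
        with pytest.raises(ValueError):
            smooth_and_resample(cl, 5.0)

    def test_spacing_outside_band_rejected(self):
        cl = Centerline(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]]))
        with pytest.raises(ValueError):
            smooth_and_resample(cl, 0.2)


class TestDomainTypes:
    def test_tangents_unit_norm(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(size=(50, 3)), axis=0)
        cl = Centerline(pts)
        assert np.allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(cl.arclength) > 0)

    def test_singular_affine_rejected(self):
        with pytest.raises(ValueError):
            VolumeGrid(np.zeros((5, 5, 5)), np.zeros((4, 4)))

    def test_single_point_centerline_rejected(self):
        with pytest.raises(ValueError):
            Centerline(np.array([[0.0, 0.0, 0.0]]))
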