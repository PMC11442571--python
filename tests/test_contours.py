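"""Contour resampling, alignment, misalignment correction and I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_circle_stack, circle_points, ellipsoid_radii

from lvshape.cohort import inject_misalignment
from lvshape.contours import (
    ENDO,
    EPI,
    align_stack,
    correct_slice_misalignment,
    load_stack_json,
    resample_closed_contour,
    resample_stack_contours,
    resample_stack_to_slices,
    save_stack_json,
    stack_to_mesh,
    validate_stack,
)


class TestResampleClosedContour:
    def test_circle_preserves_radius_and_angular_spacing(self):
        # 400 = 5 x 80 input samples: every output lands on a vertex, so the
        # chord-walk introduces no sagitta error at all
        pts = resample_closed_contour(circle_points(10.0, 400), 80)
        radii = np.linalg.norm(pts, axis=1)
        assert np.allclose(radii, 10.0, atol=1e-6)
        ang = np.unwrap(np.arctan2(pts[:, 1], pts[:, 0]))
        gaps = np.diff(ang)
        assert np.allclose(gaps, gaps[0], atol=1e-6)

    def test_square_perimeter_preserved_exactly(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        pts = resample_closed_contour(square, 80)
        closed = np.vstack([pts, pts[:1]])
        perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert perimeter == pytest.approx(4.0, abs=1e-9)

    def test_equal_chord_polygon_is_fixed_point(self):
        # oracle re-walk: when all chords are equal the cumulative arc length
        # hits the targets exactly at the vertices, so resampling is identity
        poly = circle_points(10.0, 80)
        out = resample_closed_contour(poly, 80)
        assert np.allclose(out, poly, atol=1e-9)

    def test_near_idempotent_on_smooth_contour(self):
        # on smooth non-uniform contours resampling contracts toward the
        # equal-arc fixed point: a second pass moves points only marginally
        ang = np.linspace(0.0, 2 * np.pi, 400, endpoint=False)
        r = 20.0 + 2.0 * np.cos(2 * ang)
        raw = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        once = resample_closed_contour(raw, 80)
        twice = resample_closed_contour(once, 80)
        assert np.max(np.linalg.norm(twice - once, axis=1)) < 0.05

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError, match="zero perimeter"):
            resample_closed_contour(np.zeros((5, 2)), 80)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_perimeter_preserved_on_smooth_contours(self, seed):
        rng = np.random.default_rng(seed)
        # smooth star-shaped contour: radius with a few low-order harmonics
        ang = np.linspace(0.0, 2 * np.pi, 400, endpoint=False)
        r = 20.0 + sum(
            rng.uniform(-2, 2) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
            for k in range(1, 4)
        )
        raw = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        out = resample_closed_contour(raw, 80)

        def perim(p):
            closed = np.vstack([p, p[:1]])
            return np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()

        assert perim(out) == pytest.approx(perim(raw), rel=5e-3)


class TestResampleStackToSlices:
    def test_identity_on_matching_grid(self):
        stack = build_circle_stack(np.full(20, 20.0), spacing=4.0)
        out = resample_stack_to_slices(stack, 20)
        for surface in (ENDO, EPI):
            assert np.allclose(
                out.points3d(surface), stack.points3d(surface), atol=1e-9
            )

    def test_cylinder_constant_radius(self):
        stack = build_circle_stack(np.full(10, 20.0), spacing=8.0)
        out = resample_stack_to_slices(stack, 20)
        pts = out.points3d(ENDO)
        radii = np.linalg.norm(pts[:, :, :2], axis=2)
        assert np.allclose(radii, 20.0, atol=1e-9)

    def test_cone_linear_profile_interpolated_exactly(self):
        radii = np.linspace(30.0, 5.0, 10)  # linear in z
        stack = build_circle_stack(radii, spacing=8.0)
        out = resample_stack_to_slices(stack, 20)
        z_src = stack.z_positions(ENDO)
        z_new = out.z_positions(ENDO)
        expected = np.interp(-z_new, -z_src, radii)
        measured = np.linalg.norm(out.points3d(ENDO)[:, :, :2], axis=2).mean(axis=1)
        assert np.allclose(measured, expected, atol=1e-9)

    def test_too_few_slices_rejected(self):
        stack = build_circle_stack([20.0, 18.0], spacing=8.0)
        with pytest.raises(ValueError, match="at least 3"):
            resample_stack_to_slices(stack, 20)


class TestAlignStack:
    def test_already_aligned_stack_untouched(self):
        stack = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        aligned, t = align_stack(stack)
        # generator convention: anterior insertion at +60 degrees
        assert t.rotation_deg == pytest.approx(-60.0, abs=1e-9)
        realigned, t2 = align_stack(aligned)
        assert abs(t2.rotation_deg) < 1e-9
        assert np.allclose(t2.translation_mm, 0.0, atol=1e-9)

    def test_known_rotation_recovered(self):
        stack = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        _, t0 = align_stack(stack)
        rotated = build_circle_stack(
            ellipsoid_radii(20.0, 10, 8.0, 80.0), rv_angle_deg=90.0
        )
        _, t1 = align_stack(rotated)
        assert (t1.rotation_deg - t0.rotation_deg) == pytest.approx(-30.0, abs=1e-6)

    def test_pose_invariance(self, rng):
        base = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        moved = base.copy()
        theta = np.radians(37.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([13.0, -7.0])
        for c in moved.contours:
            c.points = c.points @ R.T + shift
        for marks in moved.rv_insertions.values():
            for k in marks:
                marks[k] = marks[k] @ R.T + shift
        a1, _ = align_stack(base)
        a2, _ = align_stack(moved)
        rms = np.sqrt(np.mean((a1.points3d(ENDO) - a2.points3d(ENDO)) ** 2))
        assert rms < 1e-6

    def test_transform_roundtrip_restores_input(self):
        stack = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        aligned, t = align_stack(stack)
        restored = t.invert(aligned)
        assert np.allclose(restored.points3d(ENDO), stack.points3d(ENDO), atol=1e-9)
        assert np.allclose(restored.points3d(EPI), stack.points3d(EPI), atol=1e-9)

    def test_missing_landmarks_rejected(self):
        stack = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        stack.rv_insertions = {}
        with pytest.raises(ValueError, match="insertion"):
            align_stack(stack)


class TestMisalignmentCorrection:
    def test_collinear_centroids_yield_zero_shifts(self):
        n = 12
        centers = np.column_stack([np.linspace(0, 5, n), np.linspace(0, -3, n)])
        stack = build_circle_stack(np.full(n, 20.0), centers=centers)
        corrected, t = correct_slice_misalignment(stack, degree=3)
        shifts = np.stack(list(t.slice_shifts_mm.values()))
        assert np.max(np.abs(shifts)) < 1e-9

    def test_noise_reduced_on_dense_straight_phantom(self):
        # dense phantom so the fitted curve's noise absorption (~degree+1
        # of n slices) does not mask the correction itself
        n = 100
        reductions = []
        for seed in range(10):
            stack = build_circle_stack(np.full(n, 20.0), spacing=1.0)
            noisy = inject_misalignment(stack, 2.0, seed=seed)
            corrected, _ = correct_slice_misalignment(noisy, degree=3)

            def rms_dev(s):
                cen = np.stack([c.centroid for c in s.surface_contours(ENDO)])
                return np.sqrt(np.mean(np.sum(cen**2, axis=1)))

            reductions.append(1.0 - rms_dev(corrected) / rms_dev(noisy))
        assert np.mean(reductions) >= 0.70

    def test_smooth_curved_axis_preserved(self):
        # genuine low-order curvature must not be flattened
        n = 20
        z = (np.arange(n) + 0.5) * 8.0
        centers = np.column_stack([0.05 * z + 2e-4 * z**2, -0.03 * z])
        stack = build_circle_stack(np.full(n, 20.0), centers=centers)
        _, t = correct_slice_misalignment(stack, degree=3)
        shifts = np.stack(list(t.slice_shifts_mm.values()))
        assert np.max(np.abs(shifts)) < 1e-6

    def test_too_few_slices_for_degree_rejected(self):
        stack = build_circle_stack(np.full(4, 20.0))
        with pytest.raises(ValueError, match="at least"):
            correct_slice_misalignment(stack, degree=3)

    def test_correction_is_rigid_per_slice(self):
        stack = build_circle_stack(np.full(12, 20.0))
        noisy = inject_misalignment(stack, 2.0, seed=5)
        corrected, _ = correct_slice_misalignment(noisy)
        for before, after in zip(
            noisy.surface_contours(ENDO), corrected.surface_contours(ENDO)
        ):
            d_before = np.linalg.norm(before.points[0] - before.points[40])
            d_after = np.linalg.norm(after.points[0] - after.points[40])
            assert d_after == pytest.approx(d_before, abs=1e-9)


class TestStackIO:
    def test_roundtrip_is_bit_exact_after_first_write(self, tmp_path):
        stack = build_circle_stack(ellipsoid_radii(20.0, 10, 8.0, 80.0))
        noisy = inject_misalignment(stack, 1.5, seed=3)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_stack_json(noisy, p1)
        loaded = load_stack_json(p1)
        save_stack_json(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        # 6-decimal contract: coordinates survive to the stored precision
        assert np.allclose(
            loaded.points3d(ENDO), noisy.points3d(ENDO), atol=5.1e-7
        )

    def test_validate_flags_containment_violation(self):
        stack = build_circle_stack(np.full(6, 20.0), wall=1.0)
        endo0 = stack.contour_at(ENDO, 2)
        endo0.points = endo0.points + np.array([3.0, 0.0])
        issues = validate_stack(stack)
        assert any("outside epicardium" in msg for msg in issues)

    def test_mesh_export_positive_volume(self, ellipsoid_stack, tmp_path):
        mesh = stack_to_mesh(ellipsoid_stack, ENDO)
        assert abs(mesh.volume) / 1000.0 == pytest.approx(67.0, rel=0.05)
        out = tmp_path / "endo.obj"
        mesh.export(str(out))
        assert out.read_text().startswith("v ") or "v " in out.read_text()


class TestCommutation:
    def test_resample_and_align_commute_on_landmarked_stack(self):
        radii = np.linspace(25.0, 10.0, 10)
        centers = np.column_stack([np.linspace(0, 4, 10), np.linspace(0, -2, 10)])
        stack = build_circle_stack(radii, centers=centers)
        a_then_r = resample_stack_to_slices(align_stack(stack)[0], 20)
        r_then_a = align_stack(resample_stack_to_slices(stack, 20))[0]
        diff = np.abs(a_then_r.points3d(ENDO) - r_then_a.points3d(ENDO))
        assert diff.max() < 1e-6
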