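"""Shared fixtures and stack builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lvshape.contours import ANTERIOR, INFERIOR, Contour, ContourStack, ENDO, EPI


def circle_points(radius: float, n: int, center=(0.0, 0.0), phase_rad: float = 0.0):
    """n points on a circle, counterclockwise, starting at angle ``phase_rad``."""
    ang = phase_rad + np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def build_circle_stack(
    radii,
    centers=None,
    spacing: float = 8.0,
    n_points: int = 80,
    wall: float = 6.0,
    subject_id: str = "phantom",
    phase: str = "ED",
    rv_angle_deg: float = 60.0,
) -> ContourStack:
    """Stack of circular contours with prescribed per-slice radii and centres.

    RV insertion landmarks sit on the epicardial circle at the anterior /
    inferior reference angles, mirroring the generator's convention.
    """
    radii = np.asarray(radii, dtype=float)
    n_slices = len(radii)
    if centers is None:
        centers = np.zeros((n_slices, 2))
    centers = np.asarray(centers, dtype=float)
    contours, rv = [], {}
    a_rad = np.radians(rv_angle_deg)
    i_rad = np.radians(360.0 - rv_angle_deg)
    for i, (r, c) in enumerate(zip(radii, centers)):
        z = -(i + 0.5) * spacing
        contours.append(Contour(ENDO, i, z, circle_points(r, n_points, c)))
        contours.append(Contour(EPI, i, z, circle_points(r + wall, n_points, c)))
        rv[i] = {
            ANTERIOR: c + (r + wall) * np.array([np.cos(a_rad), np.sin(a_rad)]),
            INFERIOR: c + (r + wall) * np.array([np.cos(i_rad), np.sin(i_rad)]),
        }
    return ContourStack(
        subject_id=subject_id,
        phase=phase,
        contours=contours,
        rv_insertions=rv,
        slice_spacing_mm=spacing,
    )


def ellipsoid_radii(basal_radius: float, n_slices: int, spacing: float, length: float):
    """Cross-section radii of a hemi-ellipsoid at plane centres (midpoints)."""
    z = (np.arange(n_slices) + 0.5) * spacing
    u = np.clip(z / length, 0.0, 1.0)
    return basal_radius * np.sqrt(np.clip(1.0 - u**2, 0.0, None))


@pytest.fixture
def ellipsoid_stack() -> ContourStack:
    """Untilted hemi-ellipsoid phantom (R=20 mm, L=80 mm) as a 20-slice stack."""
    return build_circle_stack(
        ellipsoid_radii(20.0, 20, 4.0, 80.0), spacing=4.0, n_points=160
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
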