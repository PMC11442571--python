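"""Parametric left-ventricular phantom geometry.

The synthetic ventricle is a tapered, truncated hemi-ellipsoid of revolution:
the endocardial surface has the radius profile

    r(u) = R_b * (1 - u**(2/taper))**0.5,   u = depth / length in [0, 1],

so ``taper = 1`` is an exact hemi-ellipsoid (cavity volume (2/3) pi R^2 L),
smaller taper approaches a cylinder and larger taper a cone-like apex.  The
general analytic cavity volume is ``pi R^2 L * 2 / (2 + taper)``.

The epicardium is the same family grown by the wall thickness in both radius
and length.  End-systole is an affine contraction of end-diastole: radii
scaled by (1 - contraction_radial) and length by (1 - contraction_long), with
the end-systolic wall thickness chosen so that myocardial wall volume is
conserved (incompressible myocardium).  An optional rigid tilt about the x
axis models a long axis oblique to the slice normal.

Slicing intersects the surface with planes perpendicular to the scanner z
axis at the acquisition spacing (slice thickness + gap), producing the
closed, counterclockwise, equally arc-length-sampled contours that the rest
of the package consumes, together with RV insertion landmarks synthesized at
fixed anatomical angles on the epicardial contour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .contours import (
    ANTERIOR,
    INFERIOR,
    Contour,
    ContourStack,
    ENDO,
    EPI,
    resample_closed_contour,
)

logger = logging.getLogger(__name__)

ANTERIOR_RV_ANGLE_DEG = 60.0
INFERIOR_RV_ANGLE_DEG = 300.0


@dataclass(frozen=True)
class VentricleParams:
    """Generative controls for one subject-phase pair.

    length_mm            base-plane-to-apex distance of the endocardium
    basal_radius_mm      endocardial radius at the base
    taper                conicity control in (0, 1.5]; 1 = hemi-ellipsoid
    wall_thickness_mm    epicardial offset at end-diastole
    apex_tilt_deg        angle between long axis and slice normal, [0, 25]
    basal_tilt_deg       tilt of the basal truncation plane, [0, 25]
    contraction_radial   fractional end-systolic radial shortening, [0, 1)
    contraction_long     fractional end-systolic longitudinal shortening, [0, 1)
    """

    length_mm: float
    basal_radius_mm: float
    taper: float = 1.0
    wall_thickness_mm: float = 6.0
    apex_tilt_deg: float = 0.0
    basal_tilt_deg: float = 0.0
    contraction_radial: float = 0.0
    contraction_long: float = 0.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.basal_radius_mm <= 0:
            raise ValueError("length and basal radius must be positive")
        if not 0 < self.taper <= 1.5:
            raise ValueError("taper must lie in (0, 1.5]")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")
        for tilt in (self.apex_tilt_deg, self.basal_tilt_deg):
            if not 0 <= tilt <= 25:
                raise ValueError("tilts must lie in [0, 25] degrees")
        for c in (self.contraction_radial, self.contraction_long):
            if not 0 <= c < 1:
                raise ValueError("contraction fractions must lie in [0, 1)")

    def ejection_fraction(self) -> float:
        """EF implied by the affine contraction model."""
        return 1.0 - (1.0 - self.contraction_radial) ** 2 * (1.0 - self.contraction_long)


@dataclass(frozen=True)
class RevolutionSurface:
    """One tapered hemi-ellipsoid of revolution, optionally tilted about x."""

    basal_radius_mm: float
    length_mm: float
    taper: float = 1.0
    apex_tilt_deg: float = 0.0
    basal_tilt_deg: float = 0.0

    def radius_profile(self, u) -> np.ndarray:
        """Cross-section radius at normalized depth u in [0, 1]."""
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        return self.basal_radius_mm * np.sqrt(
            np.clip(1.0 - u ** (2.0 / self.taper), 0.0, None)
        )

    def cavity_volume_ml(self) -> float:
        """Closed-form solid-of-revolution volume (tilt-invariant)."""
        R, L, t = self.basal_radius_mm, self.length_mm, self.taper
        return math.pi * R * R * L * 2.0 / (2.0 + t) / 1000.0

    # -- slicing ------------------------------------------------------------
    def _solve_u_grid(self, phi: np.ndarray, zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Depth parameter u(z, phi) where planes cut the surface.

        Solves all planes at once by vectorized bisection (the intersection
        condition mixes the radius profile with the tilt, so there is no
        closed form).  Returns (u, valid): ``valid[i]`` is False when plane i
        misses the surface or cuts it only partially (no closed contour),
        which happens above the tilted basal ring or below the apex.
        """
        alpha = math.radians(self.apex_tilt_deg)
        sa, ca = math.sin(alpha), math.cos(alpha)
        L = self.length_mm
        zs = np.atleast_1d(np.asarray(zs, dtype=float))
        if sa == 0.0:
            u = -zs / L
            valid = (u >= 0.0) & (u <= 1.0) & (self.radius_profile(u) >= 1e-3)
            return np.repeat(u[:, None], len(phi), axis=1), valid

        zcol = zs[:, None]
        sphi = np.sin(phi)[None, :]

        def g(u):
            return self.radius_profile(u) * sphi * sa - u * L * ca - zcol

        shape = (len(zs), len(phi))
        lo = np.zeros(shape)
        hi = np.ones(shape)
        valid = np.all(g(lo) > 0, axis=1) & np.all(g(hi) < 0, axis=1)
        for _ in range(52):
            mid = 0.5 * (lo + hi)
            pos = g(mid) > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        u = 0.5 * (lo + hi)
        valid &= np.min(self.radius_profile(u), axis=1) >= 1e-3
        return u, valid

    def points_at_zs(self, zs, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (x, y) surface points at given azimuths for many planes.

        Returns (points, valid) with points of shape (n_planes, n_phi, 2).
        """
        phi = np.asarray(phi, dtype=float)
        u, valid = self._solve_u_grid(phi, zs)
        alpha = math.radians(self.apex_tilt_deg)
        r = self.radius_profile(u)
        x = r * np.cos(phi)[None, :]
        y = r * np.sin(phi)[None, :] * math.cos(alpha) + u * self.length_mm * math.sin(
            alpha
        )
        return np.stack([x, y], axis=-1), valid

    def points_at_z(self, z: float, phi: np.ndarray) -> np.ndarray | None:
        """In-plane (x, y) surface points at the given azimuths and height z."""
        pts, valid = self.points_at_zs([z], np.asarray(phi, dtype=float))
        return pts[0] if valid[0] else None

    def contour_at_z(self, z: float, n_points: int = 320) -> np.ndarray | None:
        """Closed cross-section contour at height z, or None if missed."""
        phi = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
        return self.points_at_z(z, phi)

    def z_base_min(self) -> float:
        """Lowest z of the open basal ring; closed contours exist below it."""
        alpha = math.radians(self.apex_tilt_deg)
        beta = math.radians(self.basal_tilt_deg)
        return -self.basal_radius_mm * math.sin(max(alpha, beta))

    def mesh(self, n_u: int = 64, n_phi: int = 96):
        """Watertight triangle mesh (independent geometry oracle + export)."""
        from .contours import rings_to_mesh

        u = np.linspace(0.0, 1.0, n_u + 1)[:-1]
        phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
        alpha = math.radians(self.apex_tilt_deg)
        sa, ca = math.sin(alpha), math.cos(alpha)
        rings = []
        for ui in u:
            r = float(self.radius_profile(ui))
            x = r * np.cos(phi)
            y = r * np.sin(phi) * ca + ui * self.length_mm * sa
            z = r * np.sin(phi) * sa - ui * self.length_mm * ca
            rings.append(np.column_stack([x, y, z]))
        # collapse toward the apex point for the final cap ring
        apex = np.array([0.0, self.length_mm * sa, -self.length_mm * ca])
        rings.append(np.tile(apex, (n_phi, 1)) * 0.999 + rings[-1] * 0.001)
        return rings_to_mesh(np.stack(rings))


def _epi_surface(endo: RevolutionSurface, wall_mm: float) -> RevolutionSurface:
    return replace(
        endo,
        basal_radius_mm=endo.basal_radius_mm + wall_mm,
        length_mm=endo.length_mm + wall_mm,
    )


def _es_wall_thickness(params: VentricleParams) -> float:
    """ES wall offset conserving myocardial wall volume under contraction."""
    endo_ed = RevolutionSurface(
        params.basal_radius_mm, params.length_mm, params.taper
    )
    wall_ed = (
        _epi_surface(endo_ed, params.wall_thickness_mm).cavity_volume_ml()
        - endo_ed.cavity_volume_ml()
    )
    R_es = params.basal_radius_mm * (1.0 - params.contraction_radial)
    L_es = params.length_mm * (1.0 - params.contraction_long)
    endo_es = RevolutionSurface(R_es, L_es, params.taper)

    def f(w):
        return (
            _epi_surface(endo_es, w).cavity_volume_ml()
            - endo_es.cavity_volume_ml()
            - wall_ed
        )

    return brentq(f, 1e-3, 60.0, xtol=1e-10)


def generate_ventricle_surfaces(
    params: VentricleParams, phase: str
) -> tuple[RevolutionSurface, RevolutionSurface]:
    """Endocardial and epicardial surfaces for one phase.

    ES surfaces are the ED surfaces with radii scaled by
    (1 - contraction_radial) and length by (1 - contraction_long); zero
    contraction reproduces the ED geometry exactly.
    """
    if phase not in ("ED", "ES"):
        raise ValueError("phase must be 'ED' or 'ES'")
    R, L = params.basal_radius_mm, params.length_mm
    wall = params.wall_thickness_mm
    if phase == "ES":
        R *= 1.0 - params.contraction_radial
        L *= 1.0 - params.contraction_long
        if params.contraction_radial > 0 or params.contraction_long > 0:
            wall = _es_wall_thickness(params)
    endo = RevolutionSurface(
        R, L, params.taper, params.apex_tilt_deg, params.basal_tilt_deg
    )
    ed_endo = RevolutionSurface(
        params.basal_radius_mm, params.length_mm, params.taper
    )
    if endo.cavity_volume_ml() > ed_endo.cavity_volume_ml() + 1e-12:
        raise ValueError("derived ES cavity volume exceeds ED cavity volume")
    return endo, _epi_surface(endo, wall)


def slice_surfaces_to_stack(
    surfaces: tuple[RevolutionSurface, RevolutionSurface],
    n_slices: int,
    points_per_contour: int = 80,
    slice_thickness_mm: float = 6.0,
    slice_gap_mm: float = 2.0,
    subject_id: str = "phantom",
    phase: str = "ED",
) -> ContourStack:
    """Intersect the surfaces with short-axis planes into a ContourStack.

    Planes are perpendicular to the scanner z axis at spacing
    (thickness + gap), base to apex, the first centred half a spacing below
    the basal plane.  Each plane-surface intersection is resampled to
    ``points_per_contour`` equally arc-length-spaced points (counterclockwise,
    origin at azimuth 0).  Planes that miss either surface, or cut it without
    a closed contour, are omitted and the count is logged.  RV insertion
    landmarks are synthesized on the epicardial contour at fixed anatomical
    angles (anterior 60 deg, inferior 300 deg).
    """
    if n_slices < 3:
        raise ValueError("need at least 3 slices")
    endo_s, epi_s = surfaces
    spacing = slice_thickness_mm + slice_gap_mm
    z0 = min(endo_s.z_base_min(), epi_s.z_base_min())
    zs = z0 - (np.arange(n_slices) + 0.5) * spacing
    phi = np.linspace(0.0, 2.0 * math.pi, 320, endpoint=False)
    rv_phi = np.radians([ANTERIOR_RV_ANGLE_DEG, INFERIOR_RV_ANGLE_DEG])
    endo_pts, endo_ok = endo_s.points_at_zs(zs, phi)
    epi_pts, epi_ok = epi_s.points_at_zs(zs, phi)
    marks, marks_ok = epi_s.points_at_zs(zs, rv_phi)
    ok = endo_ok & epi_ok
    contours: list[Contour] = []
    rv: dict[int, dict[str, np.ndarray]] = {}
    omitted = int(np.sum(~ok))
    out_idx = 0
    for k in range(n_slices):
        if not ok[k]:
            continue
        z = float(zs[k])
        contours.append(
            Contour(
                ENDO, out_idx, z, resample_closed_contour(endo_pts[k], points_per_contour)
            )
        )
        contours.append(
            Contour(
                EPI, out_idx, z, resample_closed_contour(epi_pts[k], points_per_contour)
            )
        )
        if marks_ok[k]:
            rv[out_idx] = {ANTERIOR: marks[k, 0], INFERIOR: marks[k, 1]}
        out_idx += 1
    if omitted:
        logger.info(
            "slice_surfaces_to_stack: omitted %d of %d planes missing the surface",
            omitted,
            n_slices,
        )
    if not contours:
        raise ValueError("no slicing plane intersected the surfaces")
    return ContourStack(
        subject_id=subject_id,
        phase=phase,
        contours=contours,
        rv_insertions=rv,
        slice_spacing_mm=spacing,
    )
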