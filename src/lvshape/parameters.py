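"""Traditional LV shape parameters and quantitative mode ascription.

Nine descriptors summarize an aligned, misalignment-corrected 20-slice x
80-point stack:

* length: basal endocardial centroid to the apex point, where the apex is
  the apical centroid extended by half a slice spacing along the fitted
  long axis;
* width: maximum caliper (largest pairwise point distance) over all
  endocardial contours;
* sphericity: width / length (higher = rounder ventricle);
* wall thickness: mean endo-to-epi radial distance over the middle third of
  slices (absent when no epicardium is stored);
* conicity: caliper diameter of the 2nd most apical slice divided by that of
  the middle slice (indices 18 and 10 of 20);
* curvedness: mean absolute curvature of the meridian radius profile r(z)
  (a proxy for surface curvedness on contours-of-revolution data, in 1/mm);
* apex orientation: angle between the base-to-apex vector and the slice
  normal;
* basal area: shoelace area of the most basal endocardial contour;
* basal orientation: angle between the best-fit plane normal of the basal
  contour and the fitted long axis.

Mode ascription replaces the visual matching of modes to parameters with a
reproducible rule: Spearman correlation of mode scores against every
parameter across subjects, labelling a mode with the best parameter when the
winning absolute correlation reaches the threshold (0.5 by default), and
"unascribed" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .contours import ContourStack, ENDO, EPI
from .pca import ShapePCAModel
from .volumetrics import polygon_area_mm2

PARAMETER_ORDER = (
    "length_mm",
    "width_mm",
    "sphericity",
    "wall_thickness_mm",
    "conicity",
    "curvedness_per_mm",
    "apex_orientation_deg",
    "basal_area_mm2",
    "basal_orientation_deg",
)

UNASCRIBED = "unascribed"


@dataclass
class ShapeParameters:
    length_mm: float
    width_mm: float
    sphericity: float
    wall_thickness_mm: float | None
    conicity: float
    curvedness_per_mm: float
    apex_orientation_deg: float
    basal_area_mm2: float
    basal_orientation_deg: float


def _caliper(points2d: np.ndarray) -> float:
    return float(pdist(points2d).max())


def _fitted_axis(centroids: np.ndarray) -> np.ndarray:
    """Unit direction of the least-squares line through slice centroids,
    oriented base to apex (decreasing z)."""
    c = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    if d[2] > 0:
        d = -d
    return d


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two directions folded into [0, 90] degrees."""
    cosv = abs(float(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosv, 0.0, 1.0))))


def compute_shape_parameters(stack: ContourStack) -> ShapeParameters:
    """All nine traditional parameters from one preprocessed stack."""
    endo = stack.points3d(ENDO)  # (ns, np, 3)
    ns = endo.shape[0]
    if ns < 5:
        raise ValueError("need at least 5 slices for shape parameters")
    spacing = stack.slice_spacing_mm
    centroids = endo.mean(axis=1)
    axis = _fitted_axis(centroids)
    apex = centroids[-1] + 0.5 * spacing * axis
    base_c = centroids[0]
    length = float(np.linalg.norm(apex - base_c))

    calipers = np.array([_caliper(endo[i, :, :2]) for i in range(ns)])
    width = float(calipers.max())
    sphericity = width / length
    conicity = float(calipers[ns - 2] / calipers[ns // 2])

    # meridian radius profile and its discrete curvature
    rel = endo[:, :, :2] - centroids[:, None, :2]
    r_prof = np.linalg.norm(rel, axis=2).mean(axis=1)
    z = centroids[:, 2]
    dr = np.gradient(r_prof, z)
    d2r = np.gradient(dr, z)
    curvature = np.abs(d2r) / (1.0 + dr**2) ** 1.5
    curvedness = float(curvature.mean())

    apex_orientation = _angle_deg(apex - base_c, np.array([0.0, 0.0, 1.0]))
    basal_area = polygon_area_mm2(endo[0, :, :2])

    basal_pts = endo[0] - endo[0].mean(axis=0)
    _, _, vt = np.linalg.svd(basal_pts, full_matrices=False)
    basal_normal = vt[-1]
    basal_orientation = _angle_deg(basal_normal, axis)

    wall = None
    if stack.surface_contours(EPI):
        epi = stack.points3d(EPI)
        lo, hi = ns // 3, 2 * ns // 3 + 1
        d_epi = np.linalg.norm(
            epi[lo:hi, :, :2] - centroids[lo:hi, None, :2], axis=2
        )
        d_endo = np.linalg.norm(
            endo[lo:hi, :, :2] - centroids[lo:hi, None, :2], axis=2
        )
        wall = float((d_epi - d_endo).mean())

    return ShapeParameters(
        length_mm=length,
        width_mm=width,
        sphericity=sphericity,
        wall_thickness_mm=wall,
        conicity=conicity,
        curvedness_per_mm=curvedness,
        apex_orientation_deg=apex_orientation,
        basal_area_mm2=basal_area,
        basal_orientation_deg=basal_orientation,
    )


def parameters_table(
    stacks: dict[str, ContourStack] | dict[tuple[str, str], ContourStack],
    phase: str | None = None,
) -> pd.DataFrame:
    """Subject x 9-parameter table for one phase.

    Accepts either {subject_id: stack} or {(subject_id, phase): stack} (the
    cohort layout; ``phase`` selects which stacks to use in the latter case).
    """
    rows = []
    for key, stack in stacks.items():
        if isinstance(key, tuple):
            sid, ph = key
            if phase is not None and ph != phase:
                continue
        else:
            sid = key
        p = compute_shape_parameters(stack)
        rows.append({"subject_id": sid, **p.__dict__})
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class ModeAscription:
    """Label assigned to one PCA mode by score-parameter correlation."""

    mode_index: int
    parameter: str
    correlation: float
    correlations: dict[str, float]


def ascribe_modes(
    model: ShapePCAModel,
    parameters: pd.DataFrame,
    threshold: float = 0.5,
) -> list[ModeAscription]:
    """Ascribe each retained mode to the best-correlated traditional parameter.

    ``parameters`` must be indexed by subject_id matching the model's score
    rows.  For every mode the Spearman correlation against each available
    parameter is computed; the mode is labelled with the argmax-|r| parameter
    when that |r| reaches the threshold, else "unascribed".  Ties break
    deterministically in the canonical parameter order.
    """
    if model.subject_ids is not None:
        params = parameters.loc[model.subject_ids]
    else:
        if len(parameters) != model.scores.shape[0]:
            raise ValueError("parameter table does not match model subjects")
        params = parameters
    out: list[ModeAscription] = []
    for m in range(model.n_modes):
        scores = model.scores[:, m]
        corrs: dict[str, float] = {}
        best_name, best_abs, best_val = UNASCRIBED, 0.0, 0.0
        if np.std(scores) == 0:
            out.append(ModeAscription(m, UNASCRIBED, 0.0, {}))
            continue
        for name in PARAMETER_ORDER:
            if name not in params.columns:
                continue
            vals = params[name].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or np.std(vals) == 0:
                corrs[name] = np.nan
                continue
            rho = float(spearmanr(scores, vals).statistic)
            corrs[name] = rho
            if abs(rho) > best_abs:
                best_name, best_abs, best_val = name, abs(rho), rho
        if best_abs < threshold:
            best_name, best_val = UNASCRIBED, best_val
        out.append(ModeAscription(m, best_name, best_val, corrs))
    return out


def orient_modes_by_ascription(
    model: ShapePCAModel, ascriptions: list[ModeAscription]
) -> ShapePCAModel:
    """Flip ascribed modes so scores correlate positively with their parameter.

    Unascribed modes keep the fitting convention (largest element positive).
    Returns the same model object, modified in place for convenience.
    """
    for asc in ascriptions:
        if asc.parameter != UNASCRIBED and asc.correlation < 0:
            model.modes[asc.mode_index] *= -1.0
            model.scores[:, asc.mode_index] *= -1.0
            asc.correlation = -asc.correlation
            asc.correlations = {k: -v for k, v in asc.correlations.items()}
    return model


def ascription_table(ascriptions: list[ModeAscription]) -> pd.DataFrame:
    rows = []
    for asc in ascriptions:
        row = {
            "mode": asc.mode_index + 1,
            "parameter": asc.parameter,
            "correlation": asc.correlation,
        }
        row.update({f"r_{k}": v for k, v in asc.correlations.items()})
        rows.append(row)
    return pd.DataFrame(rows)
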