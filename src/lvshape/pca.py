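"""Point-distribution models: shape vectors, covariate adjustment, PCA.

Each subject-phase contributes a shape vector of flattened endocardial
landmark coordinates from its aligned, misalignment-corrected, 20-slice x
80-point stack: ordering is phase -> slice (base to apex) -> point ->
coordinate (x, y, z), i.e. 4800 values per phase and 9600 for the combined
end-diastole + end-systole analysis (optionally doubled when the epicardium
is included).  The combined vector concatenates the ED block then the ES
block and is centred as one whole vector, so its modes express the shape
change between the phases, not two independent shape spaces.

PCA is computed by thin singular value decomposition of the centred data
matrix; with 70 subjects and up to 19200 coordinates the d x d covariance
route would be wasteful, and the covariance eigendecomposition is retained
in the test suite as an independent oracle.  Mode signs are arbitrary in
PCA; here each mode is oriented so its largest-magnitude element is
positive, and the pipeline re-orients ascribed modes so that scores increase
with the ascribed traditional parameter.

Covariate adjustment offers two mechanisms:

* ``regress``: each coordinate column is replaced by its least-squares
  residual on the centred covariate plus the column mean (statistical
  confounder adjustment; scores of the fitted model are exactly
  uncorrelated with the covariate);
* ``scale``: each subject's vector is divided by covariate**exponent
  (geometric normalization; exponent 1/3 for a volume covariate, 1/2 for an
  area-like covariate such as BSA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .contours import ContourStack, ENDO, EPI

ANALYSIS_PHASES = ("ED", "ES", "combined")
ADJUSTMENTS = ("none", "BSA", "EDV")


def build_shape_vector(
    stacks: Mapping[str, ContourStack],
    analysis_phase: str,
    include_epi: bool = False,
    n_slices: int = 20,
    points_per_contour: int = 80,
) -> np.ndarray:
    """Flatten one subject's aligned stacks into a shape vector.

    ``stacks`` maps phase name to the subject's preprocessed stack.  The
    combined analysis concatenates the ED block then the ES block.
    """
    if analysis_phase not in ANALYSIS_PHASES:
        raise ValueError(f"analysis_phase must be one of {ANALYSIS_PHASES}")
    phases = ("ED", "ES") if analysis_phase == "combined" else (analysis_phase,)
    blocks = []
    for phase in phases:
        stack = stacks[phase]
        surfaces = (ENDO, EPI) if include_epi else (ENDO,)
        for surface in surfaces:
            pts = stack.points3d(surface)
            if pts.shape[0] != n_slices or pts.shape[1] != points_per_contour:
                raise ValueError(
                    f"{phase}/{surface}: expected {n_slices} slices x "
                    f"{points_per_contour} points, got {pts.shape[0]} x {pts.shape[1]}"
                )
            blocks.append(pts.reshape(-1))
    return np.concatenate(blocks)


def build_shape_matrix(
    cohort_stacks: Mapping[str, Mapping[str, ContourStack]],
    analysis_phase: str,
    include_epi: bool = False,
    n_slices: int = 20,
    points_per_contour: int = 80,
) -> tuple[list[str], np.ndarray]:
    """Stack per-subject shape vectors into a subjects x d matrix."""
    ids = list(cohort_stacks)
    X = np.stack(
        [
            build_shape_vector(
                cohort_stacks[sid],
                analysis_phase,
                include_epi=include_epi,
                n_slices=n_slices,
                points_per_contour=points_per_contour,
            )
            for sid in ids
        ]
    )
    return ids, X


def adjust_for_covariate(
    vectors: np.ndarray,
    covariate: np.ndarray,
    method: str = "regress",
    exponent: float = 1.0,
) -> np.ndarray:
    """Remove a size covariate from the shape matrix before PCA."""
    X = np.asarray(vectors, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if X.shape[0] != c.shape[0]:
        raise ValueError("one covariate value per subject is required")
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate must be finite")
    if method == "regress":
        cc = c - c.mean()
        denom = float(cc @ cc)
        if denom == 0.0:
            raise ValueError("zero-variance covariate cannot be regressed out")
        beta = (cc @ X) / denom
        return X - np.outer(cc, beta)
    if method == "scale":
        if np.any(c <= 0):
            raise ValueError("scale adjustment requires a positive covariate")
        return X / (c[:, None] ** exponent)
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass
class ShapePCAModel:
    """A fitted point-distribution model.

    ``modes`` is (k, d) orthonormal, ``variances`` the per-mode score
    variances (descending), ``explained_fraction`` their share of the total
    coordinate-wise variance, ``scores`` the (n, k) projections of the
    centred data onto the modes.
    """

    analysis_phase: str
    adjustment: str
    mean_shape: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    explained_fraction: np.ndarray
    scores: np.ndarray
    total_variance: float
    subject_ids: list[str] | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def fit_shape_pca(
    vectors: np.ndarray,
    n_modes: int = 7,
    subject_ids: list[str] | None = None,
    analysis_phase: str = "ED",
    adjustment: str = "none",
) -> ShapePCAModel:
    """Fit the PCA point-distribution model by thin SVD of the centred data."""
    X = np.asarray(vectors, dtype=float)
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if d < n_modes:
        raise ValueError("fewer coordinates than requested modes")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(S[0], 1.0) * 1e-12
    rank = int(np.sum(S > tol))
    variances_all = S**2 / (n - 1)
    total = float(variances_all[:rank].sum())
    k = min(n_modes, rank)
    if k < n_modes:
        warnings.warn(
            f"requested {n_modes} modes but attainable rank is {rank}; truncating",
            stacklevel=2,
        )
    modes = Vt[:k].copy()
    scores = (U[:, :k] * S[:k]).copy()
    # deterministic sign: largest-magnitude mode element positive
    for m in range(k):
        j = int(np.argmax(np.abs(modes[m])))
        if modes[m, j] < 0:
            modes[m] *= -1.0
            scores[:, m] *= -1.0
    variances = variances_all[:k]
    return ShapePCAModel(
        analysis_phase=analysis_phase,
        adjustment=adjustment,
        mean_shape=mean,
        modes=modes,
        variances=variances,
        explained_fraction=variances / total if total > 0 else variances * 0.0,
        scores=scores,
        total_variance=total,
        subject_ids=subject_ids,
    )


def reconstruct(model: ShapePCAModel, scores: np.ndarray) -> np.ndarray:
    """Rebuild a shape vector from a score vector over the retained modes."""
    return model.mean_shape + np.asarray(scores) @ model.modes


@dataclass
class ModeExtremes:
    """The +/- z SD shapes of one mode, for mesh visualisation."""

    mode_index: int
    shape_minus: np.ndarray
    shape_plus: np.ndarray
    z: float


def reconstruct_mode_extremes(
    model: ShapePCAModel, mode: int, z: float = 1.96
) -> ModeExtremes:
    """Mean shape +/- z standard deviations along one retained mode."""
    if z < 0:
        raise ValueError("z must be non-negative")
    if not 0 <= mode < model.n_modes:
        raise ValueError(f"mode {mode} not retained in model")
    step = z * np.sqrt(model.variances[mode]) * model.modes[mode]
    return ModeExtremes(
        mode_index=mode,
        shape_minus=model.mean_shape - step,
        shape_plus=model.mean_shape + step,
        z=z,
    )


def explained_variance_report(model: ShapePCAModel) -> pd.DataFrame:
    """Per-mode and cumulative explained variance in percent."""
    pct = 100.0 * model.explained_fraction
    return pd.DataFrame(
        {
            "mode": np.arange(1, model.n_modes + 1),
            "variance": model.variances,
            "explained_pct": pct,
            "cumulative_pct": np.cumsum(pct),
        }
    )


def shape_vector_to_rings(
    vector: np.ndarray, n_slices: int = 20, points_per_contour: int = 80
) -> list[np.ndarray]:
    """Split a shape vector back into (n_slices, n_points, 3) ring blocks.

    A single-phase endocardium-only vector yields one block; combined or
    epicardium-inclusive vectors yield one block per phase/surface in the
    flattening order.
    """
    vec = np.asarray(vector, dtype=float)
    block = n_slices * points_per_contour * 3
    if vec.size % block:
        raise ValueError("vector length is not a multiple of one surface block")
    return [
        vec[i * block : (i + 1) * block].reshape(n_slices, points_per_contour, 3)
        for i in range(vec.size // block)
    ]


def export_mode_extremes_obj(
    model: ShapePCAModel,
    mode: int,
    out_dir,
    z: float = 1.96,
    n_slices: int = 20,
    points_per_contour: int = 80,
) -> list:
    """Write +/- z SD extreme meshes of a mode as OBJ files; returns paths."""
    from pathlib import Path

    from .contours import rings_to_mesh

    ext = reconstruct_mode_extremes(model, mode, z)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tag, shape in (("minus", ext.shape_minus), ("plus", ext.shape_plus)):
        for b, rings in enumerate(
            shape_vector_to_rings(shape, n_slices, points_per_contour)
        ):
            path = out / (
                f"{model.analysis_phase}_{model.adjustment}_mode{mode + 1}_"
                f"{tag}_block{b}.obj"
            )
            rings_to_mesh(rings).export(str(path))
            paths.append(path)
    return paths
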