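"""End-to-end orchestration of the shape-analysis study.

Stage order is fixed: cohort generation (or loading) -> per-contour
resampling -> slice-misalignment correction -> rigid alignment -> 20-slice
resampling -> volumetrics -> shape vectors -> PCA across the 3 analyses
(ED, ES, combined) x 3 adjustments (none, BSA, EDV) grid -> traditional
parameters and mode ascription -> nonparametric group statistics -> report.

Volumes are computed on the misalignment-corrected stacks at the acquisition
slice spacing; shape vectors on the aligned 20 x 80 stacks.  The BSA
adjustment defaults to residualization (confounder regression) and the EDV
adjustment to geometric scaling with exponent 1/3; both mechanisms are
available for both covariates.  Ascription for the combined analysis uses
the end-diastolic parameter table (the traditional descriptors are defined
per phase; end-diastole is the conventional reporting phase).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, generate_cohort, load_cohort
from .contours import (
    ContourStack,
    align_stack,
    correct_slice_misalignment,
    resample_stack_contours,
    resample_stack_to_slices,
)
from .parameters import (
    ascribe_modes,
    ascription_table,
    orient_modes_by_ascription,
    parameters_table,
)
from .pca import (
    ADJUSTMENTS,
    ANALYSIS_PHASES,
    ShapePCAModel,
    adjust_for_covariate,
    build_shape_vector,
    explained_variance_report,
    export_mode_extremes_obj,
    fit_shape_pca,
)
from .stats import GroupComparison, categorical_test, comparison_table, group_compare
from .volumetrics import bsa_mosteller, metrics_summary, metrics_table

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Declarative configuration of one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # load stacks+covariates instead of generating
    n_modes: int = 7
    z_extreme: float = 1.96
    n_slices: int = 20
    points_per_contour: int = 80
    correction_degree: int = 3
    include_epi: bool = False
    bsa_adjust_method: str = "regress"
    bsa_exponent: float = 0.5
    edv_adjust_method: str = "scale"
    edv_exponent: float = 1.0 / 3.0
    ascription_threshold: float = 0.5
    alpha: float = 0.05
    output_dir: str | None = None
    seed: int | None = None  # overrides cohort.seed when generating

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.z_extreme <= 0:
            raise ValueError("z_extreme must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class AnalysisReport:
    """All tables and models produced by one pipeline run."""

    config: AnalysisConfig
    metrics: pd.DataFrame
    metrics_summary: pd.DataFrame
    models: dict[tuple[str, str], ShapePCAModel]
    explained: pd.DataFrame
    ascriptions: dict[tuple[str, str], list]
    parameters: dict[str, pd.DataFrame]
    comparisons: dict[tuple[str, str], list[GroupComparison]]
    volumetric_comparisons: list[GroupComparison]
    sex_comparison: object
    provenance: dict


def preprocess_stack(
    stack: ContourStack,
    points_per_contour: int = 80,
    n_slices: int = 20,
    correction_degree: int = 3,
) -> tuple[ContourStack, ContourStack]:
    """Run the geometric preprocessing chain on one stack.

    Returns (corrected, analysis_ready): the misalignment-corrected stack at
    acquisition slice spacing (used for volumetry) and the aligned,
    20-slice resampled stack (used for shape vectors and parameters).
    """
    s = resample_stack_contours(stack, points_per_contour)
    s, _ = correct_slice_misalignment(s, degree=correction_degree)
    aligned, _ = align_stack(s)
    analysis = resample_stack_to_slices(aligned, n_slices)
    return s, analysis


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    t_start = time.perf_counter()

    def stage(name, t0):
        logger.info("stage %-22s %6.2f s", name, time.perf_counter() - t0)
        return time.perf_counter()

    # --- stage 1: cohort -------------------------------------------------
    t0 = time.perf_counter()
    if config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
    else:
        cc = config.cohort
        if config.seed is not None:
            cc = dataclasses.replace(cc, seed=config.seed)
        if set(cc.phases) != {"ED", "ES"}:
            raise ValueError("the full pipeline needs both ED and ES phases")
        cohort = generate_cohort(cc)
    t0 = stage("cohort", t0)

    # --- stage 2: preprocessing -----------------------------------------
    corrected: dict[tuple[str, str], ContourStack] = {}
    analysis_stacks: dict[str, dict[str, ContourStack]] = {}
    for (sid, phase), stk in cohort.stacks.items():
        corr, ana = preprocess_stack(
            stk,
            points_per_contour=config.points_per_contour,
            n_slices=config.n_slices,
            correction_degree=config.correction_degree,
        )
        corrected[(sid, phase)] = corr
        analysis_stacks.setdefault(sid, {})[phase] = ana
    t0 = stage("preprocess", t0)

    # --- stage 3: volumetrics -------------------------------------------
    metrics = metrics_table(corrected, cohort.covariates)
    summary = metrics_summary(metrics)
    groups = metrics["group"].to_numpy()
    vol_comparisons = [
        group_compare(metrics[col].to_numpy(), groups, col)
        for col in metrics.columns
        if col not in ("subject_id", "group") and metrics[col].notna().all()
    ]
    sex_tab = pd.crosstab(cohort.covariates["group"], cohort.covariates["sex"])
    if sex_tab.shape[1] >= 2 and (sex_tab.to_numpy().sum(axis=0) > 0).all():
        sex_comparison = categorical_test(sex_tab.to_numpy())
    else:
        logger.warning("sex distribution degenerate; skipping categorical test")
        sex_comparison = None
    t0 = stage("volumetrics", t0)

    # --- stage 4: shape PCA grid ----------------------------------------
    ids = cohort.subject_ids
    bsa = np.array(
        [
            bsa_mosteller(r.height_cm, r.weight_kg)
            for r in cohort.covariates.itertuples(index=False)
        ]
    )
    edv = metrics.set_index("subject_id").loc[ids, "edv_ml"].to_numpy()
    covs = {"BSA": (bsa, config.bsa_adjust_method, config.bsa_exponent),
            "EDV": (edv, config.edv_adjust_method, config.edv_exponent)}

    models: dict[tuple[str, str], ShapePCAModel] = {}
    for analysis in ANALYSIS_PHASES:
        X = np.stack(
            [
                build_shape_vector(
                    analysis_stacks[sid],
                    analysis,
                    include_epi=config.include_epi,
                    n_slices=config.n_slices,
                    points_per_contour=config.points_per_contour,
                )
                for sid in ids
            ]
        )
        for adjustment in ADJUSTMENTS:
            if adjustment == "none":
                Xa = X
            else:
                cov, method, exponent = covs[adjustment]
                Xa = adjust_for_covariate(X, cov, method=method, exponent=exponent)
            models[(analysis, adjustment)] = fit_shape_pca(
                Xa,
                n_modes=config.n_modes,
                subject_ids=ids,
                analysis_phase=analysis,
                adjustment=adjustment,
            )
    t0 = stage("shape-pca", t0)

    # --- stage 5: parameters + ascription --------------------------------
    parameters = {
        phase: parameters_table(
            {sid: analysis_stacks[sid][phase] for sid in ids}
        )
        for phase in ("ED", "ES")
    }
    ascriptions = {}
    for key, model in models.items():
        analysis, _ = key
        ptable = parameters["ES" if analysis == "ES" else "ED"]
        asc = ascribe_modes(model, ptable, threshold=config.ascription_threshold)
        orient_modes_by_ascription(model, asc)
        ascriptions[key] = asc
    t0 = stage("parameters", t0)

    # --- stage 6: group statistics ---------------------------------------
    group_by_id = dict(
        zip(cohort.covariates["subject_id"], cohort.covariates["group"])
    )
    labels = np.array([group_by_id[s] for s in ids])
    comparisons = {}
    for key, model in models.items():
        comparisons[key] = [
            group_compare(model.scores[:, m], labels, f"mode{m + 1}")
            for m in range(model.n_modes)
        ]
    t0 = stage("group-stats", t0)

    # --- stage 7: report --------------------------------------------------
    explained_rows = []
    for (analysis, adjustment), model in models.items():
        rep = explained_variance_report(model)
        rep.insert(0, "analysis", analysis)
        rep.insert(1, "adjustment", adjustment)
        explained_rows.append(rep)
    explained = pd.concat(explained_rows, ignore_index=True)

    provenance = {
        "software": "lvshape",
        "version": __version__,
        "seed": config.seed if config.seed is not None else config.cohort.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
    }
    report = AnalysisReport(
        config=config,
        metrics=metrics,
        metrics_summary=summary,
        models=models,
        explained=explained,
        ascriptions=ascriptions,
        parameters=parameters,
        comparisons=comparisons,
        volumetric_comparisons=vol_comparisons,
        sex_comparison=sex_comparison,
        provenance=provenance,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    stage("report", t0)
    logger.info("pipeline done in %.2f s", time.perf_counter() - t_start)
    return report


def write_report(report: AnalysisReport, out_dir) -> None:
    """Persist all tables, score matrices and mode-extreme meshes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.metrics.to_csv(out / "metrics.csv", index=False, float_format=fmt)
    report.metrics_summary.to_csv(out / "metrics_summary.csv")
    report.explained.to_csv(out / "explained_variance.csv", index=False, float_format=fmt)
    for phase, table in report.parameters.items():
        table.to_csv(out / f"parameters_{phase}.csv", float_format=fmt)

    asc_rows = []
    for (analysis, adjustment), asc in report.ascriptions.items():
        tab = ascription_table(asc)
        tab.insert(0, "analysis", analysis)
        tab.insert(1, "adjustment", adjustment)
        asc_rows.append(tab)
    pd.concat(asc_rows, ignore_index=True).to_csv(
        out / "ascriptions.csv", index=False, float_format=fmt
    )

    comp_rows = []
    for (analysis, adjustment), comps in report.comparisons.items():
        tab = comparison_table(comps)
        tab.insert(0, "analysis", analysis)
        tab.insert(1, "adjustment", adjustment)
        comp_rows.append(tab)
    pd.concat(comp_rows, ignore_index=True).to_csv(
        out / "mode_comparisons.csv", index=False, float_format=fmt
    )
    comparison_table(report.volumetric_comparisons).to_csv(
        out / "volumetric_comparisons.csv", index=False, float_format=fmt
    )

    for (analysis, adjustment), model in report.models.items():
        scores = pd.DataFrame(
            model.scores,
            index=model.subject_ids,
            columns=[f"mode{m + 1}" for m in range(model.n_modes)],
        )
        scores.index.name = "subject_id"
        scores.to_csv(out / f"scores_{analysis}_{adjustment}.csv", float_format=fmt)

    mesh_dir = out / "meshes"
    for (analysis, adjustment), model in report.models.items():
        for m in range(model.n_modes):
            export_mode_extremes_obj(
                model,
                m,
                mesh_dir,
                z=report.config.z_extreme,
                n_slices=report.config.n_slices,
                points_per_contour=report.config.points_per_contour,
            )

    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=1, default=str)


def rerender_comparisons(out_dir) -> pd.DataFrame:
    """Recompute the mode-comparison table from stored score CSVs.

    Lets a user re-render statistics after editing nothing but the stored
    intermediates (the ``report`` CLI subcommand).
    """
    out = Path(out_dir)
    cov = pd.read_csv(out.parent / "cohort" / "covariates.csv") if (
        out.parent / "cohort" / "covariates.csv"
    ).exists() else pd.read_csv(out / "metrics.csv")[["subject_id", "group"]]
    group_by_id = dict(zip(cov["subject_id"], cov["group"]))
    rows = []
    found = {}
    for path in out.glob("scores_*.csv"):
        _, analysis, adjustment = path.stem.split("_", 2)
        found[(analysis, adjustment)] = path
    # keep the pipeline's grid order so re-rendering is byte-stable
    for analysis in ANALYSIS_PHASES:
        for adjustment in ADJUSTMENTS:
            path = found.get((analysis, adjustment))
            if path is None:
                continue
            scores = pd.read_csv(path).set_index("subject_id")
            labels = np.array([group_by_id[s] for s in scores.index])
            comps = [
                group_compare(scores[col].to_numpy(), labels, col)
                for col in scores.columns
            ]
            tab = comparison_table(comps)
            tab.insert(0, "analysis", analysis)
            tab.insert(1, "adjustment", adjustment)
            rows.append(tab)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "mode_comparisons.csv", index=False, float_format="%.10g")
    return table
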