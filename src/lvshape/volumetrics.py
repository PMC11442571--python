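"""Clinical volumetric and functional LV metrics from contour stacks.

Volumes use short-axis disc summation: per-slice shoelace polygon area times
the slice spacing (thickness + gap), summed over slices.  LV mass is the
wall volume (epicardial minus endocardial) times the myocardial density
1.05 g/ml.  Body surface area uses the Mosteller formula.  Volumes should be
computed on misalignment-corrected stacks; in-plane rigid motion of a slice
does not change its polygon area, but residual motion biases how areas stack
in 3D, which is why correction precedes volumetry in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import ContourStack, ENDO, EPI

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m^2: sqrt(height_cm * weight_kg / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def polygon_area_mm2(points: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return abs(0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def cavity_volume(stack: ContourStack, surface: str = ENDO, check: bool = True) -> float:
    """Disc-summation volume in ml of one surface of the stack.

    With ``check`` enabled, self-intersecting contours raise; degenerate
    (zero-area) contours contribute nothing.
    """
    total_mm3 = 0.0
    for c in stack.surface_contours(surface):
        area = polygon_area_mm2(c.points)
        if check and area > 0:
            from shapely.geometry import LinearRing

            if not LinearRing(c.points).is_simple:
                raise ValueError(
                    f"self-intersecting {surface} contour on slice {c.slice_index}"
                )
        total_mm3 += area * stack.slice_spacing_mm
    return total_mm3 / 1000.0


def lv_mass(endo_volume_ml: float, epi_volume_ml: float) -> float:
    """LV mass in grams from cavity and epicardial disc volumes."""
    if epi_volume_ml < endo_volume_ml:
        raise ValueError("epicardial volume smaller than endocardial volume")
    return (epi_volume_ml - endo_volume_ml) * MYOCARDIAL_DENSITY_G_PER_ML


@dataclass
class VolumeMetrics:
    """Per-subject volumetric and functional metrics (the clinical table)."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_percent: float
    lvm_g: float | None
    bsa_m2: float
    edv_per_bsa: float
    esv_per_bsa: float
    lvm_per_bsa: float | None
    co_l_min: float
    ci_l_min_m2: float


def function_metrics(
    edv_ml: float,
    esv_ml: float,
    hr_bpm: float,
    bsa_m2: float,
    lvm_g: float | None = None,
) -> VolumeMetrics:
    """Derive stroke volume, EF, cardiac output/index and BSA-indexed volumes."""
    if not (edv_ml >= esv_ml >= 0):
        raise ValueError("need edv >= esv >= 0")
    if hr_bpm <= 0 or bsa_m2 <= 0:
        raise ValueError("heart rate and BSA must be positive")
    sv = edv_ml - esv_ml
    ef = 100.0 * sv / edv_ml if edv_ml > 0 else 0.0
    co = sv * hr_bpm / 1000.0
    return VolumeMetrics(
        edv_ml=edv_ml,
        esv_ml=esv_ml,
        sv_ml=sv,
        ef_percent=ef,
        lvm_g=lvm_g,
        bsa_m2=bsa_m2,
        edv_per_bsa=edv_ml / bsa_m2,
        esv_per_bsa=esv_ml / bsa_m2,
        lvm_per_bsa=None if lvm_g is None else lvm_g / bsa_m2,
        co_l_min=co,
        ci_l_min_m2=co / bsa_m2,
    )


def subject_metrics(
    ed_stack: ContourStack,
    es_stack: ContourStack,
    height_cm: float,
    weight_kg: float,
    hr_bpm: float,
) -> VolumeMetrics:
    """Full metric set for one subject from its two corrected phase stacks."""
    edv = cavity_volume(ed_stack, ENDO)
    esv = cavity_volume(es_stack, ENDO)
    lvm = None
    if ed_stack.surface_contours(EPI):
        lvm = lv_mass(edv, cavity_volume(ed_stack, EPI))
    bsa = bsa_mosteller(height_cm, weight_kg)
    return function_metrics(edv, esv, hr_bpm, bsa, lvm_g=lvm)


def metrics_table(
    stacks: dict[tuple[str, str], ContourStack], covariates: pd.DataFrame
) -> pd.DataFrame:
    """One row of VolumeMetrics per subject; column names match the fields."""
    rows = []
    for rec in covariates.itertuples(index=False):
        sid = rec.subject_id
        m = subject_metrics(
            stacks[(sid, "ED")],
            stacks[(sid, "ES")],
            rec.height_cm,
            rec.weight_kg,
            rec.heart_rate,
        )
        row = {"subject_id": sid, "group": rec.group}
        row.update(m.__dict__)
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_summary(metrics: pd.DataFrame, precision: int = 1) -> pd.DataFrame:
    """Group-wise ``median (min-max)`` strings mirroring a clinical table."""
    from .stats import summarize_median_range

    value_cols = [
        c for c in metrics.columns if c not in ("subject_id", "group")
    ]
    groups = list(pd.unique(metrics["group"]))
    out = {}
    for col in value_cols:
        out[col] = {
            g: summarize_median_range(
                metrics.loc[metrics["group"] == g, col].dropna().to_numpy(),
                precision=precision,
            )
            for g in groups
        }
    return pd.DataFrame(out).T[groups]
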