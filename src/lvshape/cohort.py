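"""Synthetic LV cohort generation.

Emulates a three-group adolescent study population (preterm born after fetal
growth restriction, preterm with appropriate birthweight, term controls)
whose ventricles differ systematically only in sphericity, graded
term AGA < preterm AGA < preterm FGR.  Everything else — body surface area,
the BSA-to-EDV relationship, ejection fraction, LV mass, heart rate, taper,
long-axis tilt, slice misalignment — varies within groups but not between
them, so that downstream analyses face a single recoverable group effect.

Calibration choices (see docs/methods.md for rationale):

* group sizes default to 22 / 22 / 26;
* BSA is a truncated normal on a plausible adolescent range (1.2-2.2 m^2);
* EDV is linear in BSA around ~85 ml/m^2 with the noise SD set so the
  population squared correlation between BSA and EDV equals the
  ``edv_bsa_r2`` target (0.53 by default);
* ejection fraction is drawn around 55% and converted into the affine
  radial/longitudinal contraction fractions of the phantom model;
* per-slice misalignment is an independent in-plane Gaussian shift, shared
  between the ED and ES stacks of a subject (breath-hold position is a
  property of the slice acquisition, not of the cardiac phase).

All randomness flows from a single master seed through per-subject derived
seeds, so any subset of the cohort is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .contours import ContourStack, load_stack_json, save_stack_json
from .phantom import (
    RevolutionSurface,
    VentricleParams,
    generate_ventricle_surfaces,
    slice_surfaces_to_stack,
    _epi_surface,
)

GROUPS = ("preterm_FGR", "preterm_AGA", "term_AGA")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    ``group_sphericity_medians`` are target width/length ratios per group in
    the order (preterm FGR, preterm AGA, term AGA); the default grading
    0.56 / 0.53 / 0.50 encodes the generative assumption that sphericity
    increases from term controls over preterm AGA to preterm FGR.
    """

    n_per_group: tuple[int, int, int] = (22, 22, 26)
    group_names: tuple[str, str, str] = GROUPS
    group_sphericity_medians: tuple[float, float, float] = (0.60, 0.53, 0.47)
    sphericity_log_sd: float = 0.06

    bsa_mean_m2: float = 1.6
    bsa_sd_m2: float = 0.2
    bsa_range_m2: tuple[float, float] = (1.2, 2.2)
    edv_slope_ml_per_m2: float = 85.0
    edv_intercept_ml: float = 0.0
    edv_bsa_r2: float = 0.53

    ef_mean: float = 0.55
    ef_sd: float = 0.025
    ef_range: tuple[float, float] = (0.47, 0.65)
    long_contraction_range: tuple[float, float] = (0.12, 0.18)

    lvm_mean_g: float = 72.0
    lvm_sd_g: float = 10.0
    lvm_range_g: tuple[float, float] = (45.0, 115.0)

    taper_mean: float = 1.0
    taper_sd: float = 0.05
    taper_range: tuple[float, float] = (0.85, 1.15)
    apex_tilt_sd_deg: float = 2.0
    apex_tilt_max_deg: float = 6.0

    height_mean_cm: float = 166.0
    height_sd_cm: float = 8.0
    height_range_cm: tuple[float, float] = (148.0, 190.0)
    hr_mean_bpm: float = 76.0
    hr_sd_bpm: float = 10.0
    hr_range_bpm: tuple[float, float] = (45.0, 128.0)

    misalignment_sd_mm: float = 1.5
    slice_thickness_mm: float = 6.0
    slice_gap_mm: float = 2.0
    points_per_contour: int = 80
    phases: tuple[str, ...] = ("ED", "ES")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group counts must be positive")
        if self.misalignment_sd_mm < 0:
            raise ValueError("misalignment SD must be non-negative")
        if not 0 < self.edv_bsa_r2 < 1:
            raise ValueError("target squared correlation must lie in (0, 1)")

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    def edv_noise_sd_ml(self) -> float:
        """Noise SD calibrated so the BSA-EDV squared correlation hits target.

        R^2 = b^2 Var(BSA) / (b^2 Var(BSA) + sd^2) solved for sd, with
        Var(BSA) the exact variance of the truncated normal BSA model.
        """
        a = (self.bsa_range_m2[0] - self.bsa_mean_m2) / self.bsa_sd_m2
        b = (self.bsa_range_m2[1] - self.bsa_mean_m2) / self.bsa_sd_m2
        bsa_sd = sps.truncnorm.std(a, b, loc=self.bsa_mean_m2, scale=self.bsa_sd_m2)
        r2 = self.edv_bsa_r2
        return abs(self.edv_slope_ml_per_m2) * bsa_sd * math.sqrt((1 - r2) / r2)


def inject_misalignment(stack: ContourStack, sd_mm: float, seed: int) -> ContourStack:
    """Rigidly shift each slice in-plane by an independent Gaussian 2-vector.

    The same shift is applied to the endocardium, epicardium and RV landmarks
    of a slice (the artifact is a breath-hold position change of the whole
    acquisition plane).  Deterministic given the seed; sd_mm = 0 leaves the
    stack unchanged.
    """
    if sd_mm < 0:
        raise ValueError("sd_mm must be non-negative")
    rng = np.random.default_rng(seed)
    indices = sorted({c.slice_index for c in stack.contours})
    shifts = {idx: rng.normal(0.0, sd_mm, 2) for idx in indices}
    out = stack.copy()
    for c in out.contours:
        c.points = c.points + shifts[c.slice_index]
    for idx, marks in out.rv_insertions.items():
        for k in marks:
            marks[k] = marks[k] + shifts[idx]
    return out


# ---------------------------------------------------------------------------
# per-subject draws
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _geometry_from_targets(edv_ml: float, sphericity: float, taper: float):
    """Invert (EDV, sphericity, taper) into (length, basal radius).

    sphericity = 2 R / L and V = pi R^2 L * 2/(2+taper) give
    L = (2 V (2+taper) / (pi s^2))^(1/3).
    """
    v_mm3 = edv_ml * 1000.0
    length = (2.0 * v_mm3 * (2.0 + taper) / (math.pi * sphericity**2)) ** (1.0 / 3.0)
    radius = sphericity * length / 2.0
    return length, radius


def _wall_for_mass(length, radius, taper, lvm_g):
    """Wall offset reproducing the target LV mass at 1.05 g/ml density."""
    endo = RevolutionSurface(radius, length, taper)
    v_endo = endo.cavity_volume_ml()

    def f(w):
        return (_epi_surface(endo, w).cavity_volume_ml() - v_endo) * 1.05 - lvm_g

    return brentq(f, 0.2, 40.0, xtol=1e-9)


def _draw_subject(rng: np.random.Generator, cfg: CohortConfig, group: str, sphericity_median: float) -> dict:
    for _ in range(20):
        try:
            height = _trunc_normal(
                rng, cfg.height_mean_cm, cfg.height_sd_cm, *cfg.height_range_cm
            )
            a = (cfg.bsa_range_m2[0] - cfg.bsa_mean_m2) / cfg.bsa_sd_m2
            b = (cfg.bsa_range_m2[1] - cfg.bsa_mean_m2) / cfg.bsa_sd_m2
            bsa = float(
                sps.truncnorm.rvs(
                    a, b, loc=cfg.bsa_mean_m2, scale=cfg.bsa_sd_m2, random_state=rng
                )
            )
            weight = 3600.0 * bsa * bsa / height  # Mosteller inverse
            hr = _trunc_normal(rng, cfg.hr_mean_bpm, cfg.hr_sd_bpm, *cfg.hr_range_bpm)
            sex = "F" if rng.random() < 0.5 else "M"

            edv = (
                cfg.edv_intercept_ml
                + cfg.edv_slope_ml_per_m2 * bsa
                + rng.normal(0.0, cfg.edv_noise_sd_ml())
            )
            edv = float(np.clip(edv, 60.0, 230.0))
            sph = float(
                np.exp(rng.normal(math.log(sphericity_median), cfg.sphericity_log_sd))
            )
            taper = _trunc_normal(rng, cfg.taper_mean, cfg.taper_sd, *cfg.taper_range)
            tilt = float(
                min(abs(rng.normal(0.0, cfg.apex_tilt_sd_deg)), cfg.apex_tilt_max_deg)
            )
            ef = _trunc_normal(rng, cfg.ef_mean, cfg.ef_sd, *cfg.ef_range)
            c_long = float(rng.uniform(*cfg.long_contraction_range))
            c_rad = 1.0 - math.sqrt((1.0 - ef) / (1.0 - c_long))
            lvm = _trunc_normal(rng, cfg.lvm_mean_g, cfg.lvm_sd_g, *cfg.lvm_range_g)

            length, radius = _geometry_from_targets(edv, sph, taper)
            wall = _wall_for_mass(length, radius, taper, lvm)
            params = VentricleParams(
                length_mm=length,
                basal_radius_mm=radius,
                taper=taper,
                wall_thickness_mm=wall,
                apex_tilt_deg=tilt,
                contraction_radial=c_rad,
                contraction_long=c_long,
            )
            break
        except ValueError:
            continue
    else:  # pragma: no cover - bounded-retry safety net
        raise RuntimeError("could not draw a feasible subject in 20 attempts")

    esv = edv * (1.0 - c_rad) ** 2 * (1.0 - c_long)
    return {
        "group": group,
        "sex": sex,
        "height_cm": height,
        "weight_kg": weight,
        "heart_rate": round(hr),
        "bsa_true_m2": bsa,
        "edv_true_ml": edv,
        "esv_true_ml": esv,
        "ef_true": ef,
        "lvm_true_g": lvm,
        "sphericity_ed_true": sph,
        "sphericity_es_true": sph * (1.0 - c_rad) / (1.0 - c_long),
        "length_mm": length,
        "basal_radius_mm": radius,
        "taper": taper,
        "wall_thickness_mm": wall,
        "apex_tilt_deg": tilt,
        "contraction_radial": c_rad,
        "contraction_long": c_long,
        "misalign_seed": int(rng.integers(0, 2**31 - 1)),
    }


def generate_truth_table(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw all subjects' covariates and generative truth (no stacks).

    Returns (covariates, truth); ``generate_cohort`` builds its stacks from
    exactly these rows, so calibration studies that only need the scalar
    truth (volumes, sphericity) can use this fast path and see the same
    numbers as a full cohort at the same seed.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(sum(config.n_per_group))
    rows = []
    i = 0
    for group, n, sph_med in zip(
        config.group_names, config.n_per_group, config.group_sphericity_medians
    ):
        for k in range(n):
            rng = np.random.default_rng(children[i])
            row = _draw_subject(rng, config, group, sph_med)
            row["subject_id"] = f"{group}_{k + 1:02d}"
            rows.append(row)
            i += 1
    truth = pd.DataFrame(rows)
    cov_cols = ["subject_id", "group", "sex", "height_cm", "weight_kg", "heart_rate"]
    covariates = truth[cov_cols].copy()
    truth = truth[
        ["subject_id"] + [c for c in truth.columns if c != "subject_id"]
    ]
    return covariates, truth


@dataclass
class Cohort:
    """A generated (or loaded) cohort: stacks, covariates, generative truth."""

    config: CohortConfig | None
    covariates: pd.DataFrame
    truth: pd.DataFrame | None
    stacks: dict[tuple[str, str], ContourStack]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates["subject_id"])

    def stack(self, subject_id: str, phase: str) -> ContourStack:
        return self.stacks[(subject_id, phase)]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "stacks").mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)
        if self.config is not None:
            with open(out / "cohort_config.json", "w") as fh:
                json.dump(dataclasses.asdict(self.config), fh, indent=1)
        for (sid, phase), stack in self.stacks.items():
            save_stack_json(stack, out / "stacks" / f"{sid}_{phase}.json")


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort of contour stacks + tables."""
    covariates, truth = generate_truth_table(config)
    stacks: dict[tuple[str, str], ContourStack] = {}
    spacing = config.slice_spacing_mm
    for row in truth.itertuples(index=False):
        params = VentricleParams(
            length_mm=row.length_mm,
            basal_radius_mm=row.basal_radius_mm,
            taper=row.taper,
            wall_thickness_mm=row.wall_thickness_mm,
            apex_tilt_deg=row.apex_tilt_deg,
            contraction_radial=row.contraction_radial,
            contraction_long=row.contraction_long,
        )
        n_slices = int(
            math.ceil((row.length_mm + row.wall_thickness_mm) / spacing)
        ) + 2
        for phase in config.phases:
            surfaces = generate_ventricle_surfaces(params, phase)
            stack = slice_surfaces_to_stack(
                surfaces,
                n_slices=n_slices,
                points_per_contour=config.points_per_contour,
                slice_thickness_mm=config.slice_thickness_mm,
                slice_gap_mm=config.slice_gap_mm,
                subject_id=row.subject_id,
                phase=phase,
            )
            if config.misalignment_sd_mm > 0:
                # one seed per subject: breath-hold shifts are shared by phases
                stack = inject_misalignment(
                    stack, config.misalignment_sd_mm, row.misalign_seed
                )
            stacks[(row.subject_id, phase)] = stack
    return Cohort(config=config, covariates=covariates, truth=truth, stacks=stacks)


def load_cohort(in_dir) -> Cohort:
    """Load a cohort previously written with :meth:`Cohort.write`."""
    src = Path(in_dir)
    covariates = pd.read_csv(src / "covariates.csv")
    truth_path = src / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    config = None
    cfg_path = src / "cohort_config.json"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = json.load(fh)
        raw = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        config = CohortConfig(**raw)
    stacks = {}
    for path in sorted((src / "stacks").glob("*.json")):
        stack = load_stack_json(path)
        stacks[(stack.subject_id, stack.phase)] = stack
    return Cohort(config=config, covariates=covariates, truth=truth, stacks=stacks)
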