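# lvshape

Statistical shape analysis of the left ventricle (LV) from short-axis
contour stacks: point-distribution models, PCA modes of variation with
covariate adjustment, traditional shape descriptors, and nonparametric group
statistics — driven by a fully synthetic cohort generator so the whole
method can be exercised and validated without patient data.

## The problem

Routine clinical markers of LV remodeling (volume, ejection fraction, mass)
can miss early structural change. Statistical shape modeling quantifies the
*geometry* directly: each subject's manual delineations — closed endocardial
and epicardial contours on every short-axis slice, at end-diastole (ED) and
end-systole (ES) — are resampled to a fixed landmark grid (20 slices × 80
points per contour), rigidly aligned using the right-ventricular insertion
landmarks and the LV centre of gravity, and stacked into shape vectors
**x**ᵢ ∈ ℝ^d (d = 4800 per phase, 9600 for the combined ED+ES analysis).
PCA of the n × d landmark matrix yields modes of variation

  **x**ᵢ ≈ **x̄** + Σₘ bᵢₘ **φ**ₘ,

with orthonormal modes **φ**ₘ, per-mode variances λₘ and subject scores
bᵢₘ. The first seven modes are retained; each is rendered as its ±1.96 SD
extreme shapes and *ascribed* to a traditional shape parameter (length,
width, sphericity = width/length, wall thickness, conicity, curvedness,
apex orientation, basal area, basal orientation) via the Spearman
correlation of its scores with that parameter across subjects. Analyses run
unadjusted, BSA-adjusted (residualization on Mosteller body surface area)
and EDV-adjusted (division by end-diastolic volume^(1/3)). Group
differences in mode scores are tested with Kruskal–Wallis and Dunn's
post-hoc comparisons with Bonferroni adjustment.

The synthetic cohort emulates a three-group adolescent study (preterm-born
after fetal growth restriction, preterm with appropriate birthweight, term
controls; n = 22/22/26) whose only systematic group difference is a graded
increase in LV sphericity — term < preterm AGA < preterm FGR — on top of
realistic within-group variation in body size, volume, ejection fraction,
mass, taper, long-axis tilt and breath-hold slice misalignment.

## Worked example

```python
from lvshape import AnalysisConfig, CohortConfig, run_pipeline

report = run_pipeline(AnalysisConfig(cohort=CohortConfig(seed=1),
                                     output_dir="scratch/demo"))

ed_bsa = report.models[("ED", "BSA")]
print("explained %:", (100 * ed_bsa.explained_fraction).round(1))
print("mode 1 label:", report.ascriptions[("ED", "BSA")][0].parameter)
comp = report.comparisons[("ED", "BSA")][0]
print("mode 1 Kruskal-Wallis p:", round(comp.p_omnibus, 4))
for pw in comp.pairwise:
    print(f"  {pw.group_a} vs {pw.group_b}: p_adj = {pw.p_adjusted:.4f}")
```

prints (seed 1):

```
explained %: [72.3 12.7  3.9  3.2  2.1  1.8  1.6]
mode 1 label: sphericity
mode 1 Kruskal-Wallis p: 0.0
  preterm_FGR vs preterm_AGA: p_adj = 0.0818
  preterm_FGR vs term_AGA: p_adj = 0.0000
  preterm_AGA vs term_AGA: p_adj = 0.0000
```

The BSA-adjusted ED mode 1 is ascribed to sphericity, dominates the
adjusted shape variance, and separates the term group from both preterm
groups — the generator's built-in remodeling gradient, recovered end to end
from the contour stacks. `run_pipeline` writes per-model score tables,
explained-variance and ascription CSVs, group-comparison tables and OBJ
meshes of every mode's ±1.96 SD extremes to the output directory.

The same analyses are available from the shell:

```bash
lvshape synth-gen --seed 1 --out scratch/cohort
lvshape analyze --input-dir scratch/cohort --out scratch/report
lvshape report --dir scratch/report
```

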