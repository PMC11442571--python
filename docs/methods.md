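# Methods

This note documents the models, calibrations and numerical choices behind
`lvshape`: what the synthetic cohort emulates, how the shape analysis is
computed, which conventions were fixed where several defensible options
existed, and what the validation does and does not demonstrate.

## Coordinate and correspondence conventions

All coordinates are millimetres in a right-handed frame whose z axis is the
slice normal; z decreases from base to apex; contours are stored
counterclockwise viewed from the base. Point-to-point correspondence across
slices, phases and subjects is defined by equal arc-length resampling of
each closed contour with the index origin anchored at the anterior RV
insertion direction after alignment. The stack file format is versioned
JSON with coordinates written at a fixed 6-decimal precision, making
write→read→write byte-stable.

The preprocessing order is fixed: per-contour resampling (80 points) →
slice-misalignment correction → rigid alignment → resampling to 20 slices.
Correction must precede alignment because the centre of gravity and the
mean insertion direction are both biased by per-slice shifts; both precede
shape-vector assembly so every subject enters the model in the same pose
and at the same landmark resolution. Volumes are computed on the corrected
stacks at acquisition slice spacing; shape vectors and traditional
parameters on the aligned 20 × 80 stacks.

## Synthetic ventricle model

The endocardium is a tapered truncated hemi-ellipsoid of revolution with
radius profile r(u) = R·(1 − u^(2/taper))^(1/2), u = depth/length ∈ [0, 1].
taper = 1 is an exact hemi-ellipsoid; the analytic cavity volume is
π R² L · 2/(2 + taper), which anchors all volumetry tests. This family was
chosen as the simplest geometry in which every traditional shape parameter
is independently controllable: sphericity via 2R/L, conicity via taper,
apex/basal orientation via rigid tilt, wall thickness via the epicardial
offset. The epicardium is the same family grown by the wall thickness in
radius and length — an approximate (not exact-normal) offset surface,
sufficient because wall thickness only needs to be controllable, not
anatomically layered.

End-systole is an affine contraction of end-diastole: radii scaled by
(1 − c_r), length by (1 − c_l), giving EF = 1 − (1 − c_r)²(1 − c_l) in
closed form. No torsion is modelled; the combined ED+ES analysis therefore
expresses radial/longitudinal contraction only. The end-systolic wall
offset is solved (Brent) so myocardial wall volume is conserved
(incompressible myocardium).

Slicing intersects the surfaces with planes at the acquisition spacing
(slice thickness 6 mm + gap 2 mm by default), the first plane half a
spacing below the basal ring. For tilted surfaces the plane–surface
intersection has no closed form and is solved by vectorized bisection over
all planes and azimuths at once (52 iterations, resolution ~2⁻⁵² in the
depth parameter). Planes that miss the surface or cut it without a closed
contour (above the tilted basal ring, below the apex) are omitted and
counted. RV insertion landmarks are synthesized on the epicardial contour
at fixed anatomical angles (anterior 60°, inferior 300°), giving the
aligner a consistent landmark the way manual annotation does.

Slice misalignment is modelled as an independent in-plane Gaussian shift
per slice (default SD 1.5 mm), applied identically to both phases of a
subject because breath-hold position belongs to the slice acquisition, not
the cardiac phase. No rotation is injected — the correction step targets
translational breath-hold offsets.

## Cohort calibration

Defaults encode the study conditions the generator emulates; all draws flow
from one master seed through per-subject derived seeds.

| quantity | default | rationale |
| --- | --- | --- |
| group sizes | 22 / 22 / 26 (FGR, preterm AGA, term) | study design |
| BSA | truncated normal, 1.6 ± 0.2 m², range 1.2–2.2 | adolescent range |
| EDV | 85 ml/m² · BSA + ε | EDV/BSA medians ~80–88 ml/m² |
| ε SD | solved from target R² = 0.53 | BSA–EDV squared correlation |
| EF | 55 ± 2.5 %, clipped 47–65 % | group medians 54–56 % |
| LV mass | 72 ± 10 g, clipped 45–115 g | clinical range |
| sphericity medians | 0.60 / 0.53 / 0.47 (FGR / preterm AGA / term) | see below |
| within-group sphericity | lognormal, σ_log = 0.06 | ~6 % coefficient of variation |
| taper | 1.0 ± 0.05 | mild conicity variation |
| apex tilt | half-normal, σ = 2°, capped 6° | residual long-axis obliquity |
| heart rate | 76 ± 10 bpm | adolescent resting range |

The EDV noise SD is computed exactly from the truncated-normal BSA variance
so the *population* R² equals the 0.53 target; sample R² at n = 70 then
scatters around it (the acceptance script reports the 10-seed mean).

The sphericity gradient deserves comment. Because only 53 % of EDV variance
is explained by BSA, BSA-residualization necessarily leaves size variance
in the shape data, and the first adjusted mode mixes sphericity with
residual size. Within-group dispersion is not reported for the emulated
study, so the between-group gradient was calibrated — as a design step, on
a pre-declared grid of log-gaps with pilot replicates — to the smallest
round-number gradient at which the BSA-adjusted analysis recovers the
sphericity mode reliably at these group sizes (ascribed to sphericity,
|Spearman| ≥ 0.8 against the generative truth, Kruskal–Wallis p < 0.05).
The resulting medians, 0.60/0.53/0.47, remain inside the anatomically
plausible sphericity range. The gradient is therefore a *detectable-effect*
condition, not an estimate of any real cohort's effect size.

## Shape analysis

Shape vectors hold endocardial landmarks only by default (80 × 20 × 3
coordinates per phase), matching the fixed landmark budget of the analysis
design; an epicardium-inclusive variant (config switch) doubles the
dimension so wall-thickness modes can emerge. Combined ED+ES vectors
concatenate the two phase blocks and are centred as whole vectors, so their
modes express the shape change between phases.

PCA is computed by thin SVD of the centred n × d matrix (d up to 19 200
makes the explicit covariance wasteful); the covariance eigendecomposition
survives only as the test-suite oracle. Mode signs are fixed
deterministically: largest-magnitude element positive at fit time, then
re-oriented so scores correlate positively with the ascribed parameter.
Rank is bounded by n − 1; requesting more modes truncates with a warning.
No per-coordinate variance normalization is applied — all coordinates share
units (mm), so covariance-PCA is the faithful choice.

Covariate adjustment implements both plausible mechanisms, since the
adjustment used in the emulated analysis is not specified: residualization
(`regress`, each coordinate column replaced by its least-squares residual
on the centred covariate plus the column mean — scores are then exactly
uncorrelated with the covariate) and geometric scaling (`scale`, division
by covariate^exponent). Defaults: BSA → regress (confounder logic), EDV →
scale with exponent 1/3 (volume → length normalization). Neither is claimed
to be "the" original mechanism; both are exposed for both covariates.

## Traditional parameters and ascription

Definitions are fixed as follows where the field leaves latitude: length is
basal endocardial centroid to the apex point (apical centroid extended half
a slice spacing along the least-squares centroid axis); width is the
maximum caliper over all endocardial contours; conicity uses the 2nd most
apical of the 20 resampled slices over slice index 10; curvedness is the
mean absolute discrete curvature of the meridian radius profile r(z) — a
deliberate proxy for surface curvedness that is exact in spirit for
contours-of-revolution data; apex orientation is the angle between the
base→apex vector and the slice normal; basal orientation the angle between
the basal contour's best-fit plane normal and the centroid axis. Wall
thickness (mean endo–epi radial gap over the middle third of slices) is
reported absent when no epicardium is stored.

Two geometric caveats, verified in the test suite: (1) the centroid-locus
axis of a tilted ellipsoid deviates from the symmetry axis by
atan((a/c)² tan α), so tilt-recovery accuracy degrades for spherical
ventricles — the tolerance is honoured for slender phantoms; (2) sphericity
is the ratio width/length, so in data where a single size factor dominates,
length or width is always at least as rank-correlated with the dominant
mode as sphericity itself; sphericity becomes the uniquely best descriptor
only after size adjustment, which is precisely where sphericity modes are
scientifically expected.

Ascription replaces visual congruence with a reproducible rule: Spearman
correlation of mode scores against all nine parameters; label = argmax |ρ|
if ≥ 0.5 (configurable), ties broken in the canonical parameter order;
zero-variance scores are unascribed.

## Group statistics

Kruskal–Wallis (tie-corrected, χ² approximation) for the omnibus test;
Dunn's z tests on pooled mean ranks with Bonferroni adjustment as the
single post-hoc method (the "Dunn's or Bonferroni's, as appropriate"
ambiguity is resolved to one documented choice). Post-hoc p values are
always computed; omnibus significance is reported separately rather than
gating them. Pearson chi-square for categorical tables, switching to
Fisher's exact test (2 × 2) when any expected cell count is ≤ 5 — the
boundary is inclusive because a diagonal table of tens has expected counts
of exactly 5 and still needs the exact test. One structural fact worth
knowing: Dunn z statistics are computed on pooled ranks, so for adjacent
groups at n = 22/22/26 even complete separation floors the adjusted p at
1.01e-3.

All-identical samples return H = 0, p = 1 (no rank variation) rather than
an error. Summaries are "median (min–max)" strings with trailing zeros
trimmed.

## Validation design and problem sizes

The validation suite runs entirely on synthetic data at sizes chosen to
make each property sharp:

* PCA oracle equivalence and reconstruction at 20 subjects × 300
  dimensions (exact comparisons at 1e-8);
* volumetry on analytic phantoms — hemi-ellipsoid within 3 % at 20 slices,
  cylinder within 0.1 % at 160 contour points (the 80-point polygon alone
  biases area by −0.10 %, so the cylinder check uses the denser sampling);
* misalignment correction on a 100-slice straight-axis phantom averaged
  over 10 seeds. The density is deliberate: shifting slices onto a fitted
  degree-p curve leaves sqrt((p+1)/n) of the injected noise, so at 20
  slices a degree-3 fit can only remove ~55 % of the RMS deviation no
  matter how it is implemented; 100 slices isolates the correction itself
  (~80 % expected reduction). Genuine smooth axis curvature up to the fit
  degree is preserved exactly;
* sphericity recovery over 50 full-pipeline replicates at n = 22/22/26;
* test calibration over 1000 null-cohort replicates (type-I rate of the
  omnibus test within [4, 6.5] %; Dunn+Bonferroni family-wise error ≤ 5 %).

What passing does **not** show: the generator contains no papillary
muscles, trabeculation, segmentation error correlated along a contour,
through-plane motion, torsion, or inter-observer delineation variability;
contours are perfect surface intersections plus rigid in-plane shifts.
Recovery results therefore demonstrate correctness of the analysis chain
under its own assumptions, not clinical performance. Mode-score magnitudes
from any real cohort are not reproducible from synthetic data and are not
asserted anywhere; only relative and ordinal behaviour is tested.

## Known limitations

* The disc-summation model applies uniform spacing with no partial-volume
  handling at base or apex; at default spacing this biases cavity volumes
  by a few percent (downward for tilted ventricles), which cancels in EF.
* Basal orientation as measured from z-planar contour stacks is nearly
  degenerate with apex orientation; a genuinely oblique basal truncation
  cannot be represented in planar short-axis slices.
* The re-anchoring of point index 0 after alignment rolls to the nearest
  existing landmark (4.5° granularity at 80 points) rather than
  re-interpolating, preserving exact rigidity at the cost of up to half an
  index of angular offset.
* Combined-phase ascription uses end-diastolic parameters; ES-specific
  descriptors of contraction shape are not defined.
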