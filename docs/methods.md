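# Methods

This note documents the models, numerical choices and limitations behind
`cmrsport`. It is written for users who need to know exactly what the code
computes and what passing tests do and do not demonstrate.

## LV quantification

Volumes use slice summation: each short-axis slice contributes
`area × (slice thickness + interslice gap)`, with 8 mm contiguous slices as
the default geometry. Stroke volume and ejection fraction are derived
identities (`LVSV = LVEDV − LVESV`, `LVEF = 100·LVSV/LVEDV`), so they are
consistent with the reported volumes by construction. Myocardial mass is
muscle volume times 1.05 g/ml, the standard density convention for CMR mass
reporting.

**Conventional quantification (CQ).** Cavity area is the endocardial polygon
area by the shoelace formula on mm coordinates; mass comes from the
epi-minus-endo annulus at end-diastole. Because the endocardial contour is
drawn as a smooth cavity boundary, trabeculae and papillary muscles (TPM)
inside it are implicitly counted as blood.

**Threshold-based quantification (TQ).** Within the epicardial mask of each
slice, blood and muscle intensities are estimated by a two-class Otsu split
of the in-mask histogram, taking the class means as the estimates. This
per-slice estimation is the simplest faithful realization of a "spatially
varying" intensity model; commercial implementations are undocumented. The
classification cut sits at a fraction *f* between the estimates (default
0.5); voxels strictly above are blood, ties and below are muscle. Labelling
ties as muscle is the conservative choice toward mass. *f* = 1 is allowed as
the degenerate all-muscle limit. Slices whose histogram is flat or
effectively one-class fall back to estimates pooled over all slices of the
phase; if those are degenerate too, the error propagates.

Voxel membership in a contour is decided by a voxel-center-in-polygon test —
deterministic and convergent under grid refinement. Muscle voxels inside the
endocardial contour form the TPM compartment; all blood-labelled voxels count
toward the cavity. Every in-mask voxel therefore belongs to exactly one of
{cavity blood, compact myocardium, TPM}.

With multi-phase input, end-diastole is identified as the phase of maximal
contour-based cavity volume and end-systole as the minimal one; the phantom
supplies exactly two labelled phases.

## Wall thickness

The myocardial centerline of a slice is sampled by casting rays from the
cavity centroid and taking midpoints of the endo/epi boundary crossings;
tangents come from central differences over the closed curve. Thickness at a
sample is the length of the connected compact-wall crossing of the chord
through the sample perpendicular to the local tangent. Using the connected
component that contains the sample clips the chord at the first epicardial
crossing, so strongly asymmetric walls never contribute opposite-wall
lengths. TPM are inside the endocardial contour and never contribute.

360 chords per slice (1° steps) comfortably oversample relative to voxel
resolution. The maximum is taken over all slices; the minimum within the
slice of the maximum, which defines the max/min EDWT asymmetry ratio. Chords
that fail to produce a wall crossing are skipped and counted; above 10%
skipped the result carries a warning flag.

## Sport indices and classification

BSA uses Du Bois (`0.007184·height^0.725·weight^0.425`, cm/kg in, m² out);
the source data report BSA without naming a formula, and Du Bois is the
prevailing convention in CMR normal-value studies. `EDWT/LVEDVi` divides the
maximal wall thickness (mm) by the BSA-indexed end-diastolic volume
(ml/m²); `LVM/LVEDV` is deliberately unindexed (BSA cancels). Cut-off
comparisons are strict (`>`), matching the way the published cut-offs are
stated; a value exactly at the cut-off falls to the athlete range. The grey
zone is the inclusive interval [13, 16] mm of maximal EDWT — the source
states "13–16 mm" without bracket semantics, and inclusive bounds are the
natural reading of a measurement range.

## ROC analysis and group comparison

Candidate thresholds are midpoints between adjacent distinct observed values
plus ∓∞ sentinels, which makes the accuracy-maximizing threshold
well-defined without an arbitrary grid. The AUC is the trapezoidal area,
identical to the Mann–Whitney concordance probability with half credit for
ties (verified against an all-pairs oracle and an independent library
implementation). The reported cut-off maximizes `(TP+TN)/n`; ties break
toward the smaller threshold, i.e. the more sensitive operating point.
Confusion metrics with zero denominators are reported as undefined rather
than zero. Rounding happens only at the reporting layer (one decimal for
tabular output, nearest integer for prose-style PPV/NPV).

Paired AUCs of two indices on the same subjects are compared with DeLong's
structural-components test, the field standard for correlated ROC curves;
the variance estimate is validated against a subject-resampling bootstrap.
Group differences are estimated by least-squares regression of the outcome
on a group indicator plus age and heart rate, within strata (pairwise
comparisons); median regression for non-normal outcomes is out of scope, so
least squares is the sole comparison engine.

## Synthetic data

**Phantoms.** Each slice is an annulus with angular wall thickness
`t(θ) = base + amplitude·exp((cos(θ−θc)−1)/w²)` — a von-Mises-shaped bump
that reproduces both near-symmetric athlete-like walls and asymmetric
septal-thickening HCM-like walls with two parameters. Trabeculae are radial
ridges filling a prescribed area fraction of a 3 mm ring just inside the
endocardial border (8 ridges, duty cycle = trabecular fraction, so TPM
volume is exactly proportional to the fraction while compact wall volume is
untouched). Papillary muscles are two 5 mm-radius cylinders at ±60° from the
bump centre, present in the central 40% of slices. Exactly two phases are
rendered; end-systole shrinks the cavity at unchanged wall thickness
function. Defaults follow the acquisition geometry of the source cohort:
8 mm slices, no gap, ~1 mm in-plane spacing.

Images are rendered on a k-fold supersampled in-plane grid (default k = 4)
and block-averaged down, which produces genuine partial-volume intermediate
intensities at every interface — precisely what the 50% threshold must
handle. Noise is additive Gaussian at acquisition resolution; at the
signal-to-noise ratios of bSSFP cine, magnitude-image noise is
near-Gaussian, and no specific noise model is claimed by the method being
implemented. Ground truth is counted on the same supersampled grid,
independent of the quantification code, and the analytic thickness field is
evaluated directly from `t(θ)`.

Contour polygons are sampled with a vertex arc step matching the in-plane
spacing, like contours drawn on the image; polygon discretization error then
shrinks quadratically as the grid is refined, which is what makes the
recovery errors of *both* methods decrease monotonically over the
2 → 1 → 0.5 mm resolution ladder used in the tests.

**Cohorts.** Subject groups are simulated as independent Gaussians per index
from the published group means/SDs at the published sizes (101/108/49/86),
with non-positive draws rejected. Only marginal structure is available, so
joint-distribution quantities — the exact empirical AUCs (0.998/0.999 in the
source), printed sensitivities/specificities, or tail fractions like the
share of athletes in the grey zone — are *not* reproduced; the tests assert
marginal means (within 3 standard errors) and the robust ordering that
wall-to-volume indices outperform the max/min asymmetry ratio.

**What phantom tests show.** Recovery within 2% (volumes/masses) and 5%
(TPM mass) at 1 mm spacing demonstrates the correctness of the
implementation on idealized geometry. Real short-axis data add through-plane
motion, basal-slice ambiguity, trabecular complexity far beyond 8 ridges,
surface coils and flow artefacts; accuracy figures on phantoms do not
transfer to patients.

## Numerical choices and degenerate inputs

- Polygon validity, containment and chord intersections use exact predicates
  from a computational-geometry library; endocardial contours must lie
  strictly inside epicardial ones, and a zero-width wall is rejected.
- The supersampled class maps and all sampling are driven by a single seeded
  generator; identical specs give bit-identical phantoms and cohorts.
- A phantom whose epicardium would leave the grid raises a geometry error
  instead of silently clipping.
- Index values are required to be non-missing for ROC analysis; single-class
  inputs are rejected rather than returning a vacuous AUC.
- One known inconsistency in the source tables (the male conventional-method
  group means violate the SVi = EDVi − ESVi identity by 2.8 ml/m²) is not
  modelled: the identity is enforced throughout this package.

## Problem sizes

The test suite and acceptance script run phantoms at 64–256 voxel grids
(2 → 0.5 mm spacing, supersampling 4, 10 slices), cohorts at the full
published 344 subjects, a 10⁴-resample bootstrap for the DeLong variance
check, and exhaustive per-voxel oracles on 24²–32³ grids. These sizes keep
every oracle exact or statistically sharp while the whole suite completes in
well under a minute of compute for the numerical core.
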