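# cmrsport

Sport indices from cardiac MR short-axis cine imaging: left-ventricular
quantification, wall-thickness geometry and ROC cut-off diagnostics for
separating **athlete's heart** from **hypertrophic cardiomyopathy (HCM)**.

Intensive training thickens the left-ventricular wall; so does HCM, a leading
cause of sudden cardiac death in young athletes. In the diagnostic *grey zone*
(maximal end-diastolic wall thickness, EDWT, of 13–16 mm) the two phenotypes
overlap, and a wall-thickness criterion alone cannot separate physiological
from pathological hypertrophy. This package implements the CMR-based
differentiation workflow for that problem, aimed at researchers in cardiac
image analysis who want a fully testable, synthetic-data-backed reference
implementation.

## What it computes

**Two LV quantification methods** on short-axis cine stacks (slice summation,
myocardial density 1.05 g/ml):

- **CQ** — conventional contour-based: cavity volume from the endocardial
  polygon, so trabeculae and papillary muscles (TPM) count toward the blood
  pool; mass from the epi-minus-endo annulus.
- **TQ** — threshold-based voxel classification: per slice, blood and muscle
  signal intensities are estimated inside the epicardial contour (two-class
  histogram split) and every voxel is classified against a cut at a fixed
  fraction *f* (default 0.5) between them,
  `cut = SI_muscle + f·(SI_blood − SI_muscle)`. Muscle voxels inside the
  endocardial contour are the TPM; they join the mass and leave the blood pool.

**Wall geometry** — maximal EDWT measured perpendicular to the myocardial
centerline (mid-wall curve between the contours), the minimal EDWT in the same
slice, and their ratio max/min EDWT.

**Sport indices** per subject, with BSA by Du Bois
(`0.007184·h^0.725·w^0.425`):

- `EDWT/LVEDVi` (mm·m²/ml), per method — wall thickness relative to indexed
  end-diastolic volume;
- `LVM/LVEDV` (g/ml), per method — mass-to-volume ratio;
- `TPM% = 100·TPM/LVM` (TQ only);
- max/min EDWT (asymmetry).

**Diagnostics** — ROC curves (strict `>` classification, positive = HCM,
trapezoidal AUC = Mann–Whitney concordance), cut-offs chosen to maximize the
proportion of subjects correctly classified, sensitivity/specificity/PPV/NPV,
DeLong's paired test for correlated AUCs, and least-squares group comparisons
adjusted for age and heart rate. Default classification cut-offs:
`EDWT/LVEDVi_CQ > 0.14`, `EDWT/LVEDVi_TQ > 0.17`, `LVM/LVEDV_CQ > 0.82`,
`LVM/LVEDV_TQ > 1.27`, `max/min EDWT > 2.4`.

**Synthetic data** — voxelized LV phantoms (annular slices with a von-Mises
wall-thickness bump, trabecular ridges, papillary cylinders, partial volume by
supersampling, Gaussian noise) with analytic ground truth, and index-level
Gaussian cohorts at the published four-group statistics (101 male / 49 female
athletes, 108 male / 86 female HCM patients).

## Worked example

Generate a two-subject demo set (one athlete-like, one HCM-like phantom) and
run the full pipeline:

```bash
cmrsport demo --out demo --seed 3
cmrsport run --config demo/config.json --out demo/results
```

`demo/results/indices.csv` then contains one row per subject (excerpt):

| subject | group | max EDWT (mm) | max/min | EDWT/LVEDVi CQ | LVM/LVEDV TQ | classification |
|---|---|---|---|---|---|---|
| ath01 | athlete | 12.6 | 1.80 | 0.112 | 0.73 | athlete-range on all five rules |
| hcm01 | HCM | 22.0 | 2.55 | 0.274 | 1.62 | HCM-range on all five rules |

The athlete phantom sits below every cut-off (e.g. 0.112 < 0.14 mm·m²/ml);
the HCM phantom exceeds all of them, and `cutoff_table.csv` reports perfect
separation of this toy cohort. Individual stages are also exposed:

```bash
$ cmrsport edwt --contours demo/hcm01_contours.json --out edwt.json
max EDWT=22.0 mm (slice 0), min=8.6 mm, ratio=2.55
$ cmrsport quantify --method tq --stack demo/hcm01_stack \
    --contours demo/hcm01_contours.json --out tq.json
TQ: LVEDV=144.8 ml LVESV=51.5 ml LVEF=64.4% LVM=234.9 g
```

Here the 22.0 mm maximal wall thickness matches the phantom's analytic wall
field (base 8 mm + 14 mm septal bump), and the threshold-based mass includes
the TPM that the conventional method would have left in the blood pool.

Everything is equally scriptable from Python:

```python
from cmrsport import (hcm_like_spec, generate_phantom, cq_quantify,
                      tq_quantify, measure_edwt)

stack, contours, truth = generate_phantom(hcm_like_spec(seed=3))
tq = tq_quantify(stack, contours)
wall = measure_edwt(contours)
print(tq.lvm, tq.tpm_mass, wall.max_edwt, wall.max_min_ratio)
```

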