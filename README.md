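# renalseg

Automatic 3D kidney segmentation for diffusion-weighted MRI (DW-MRI), built
around a geometric (level-set) deformable boundary guided by a joint
Markov–Gibbs random field (MGRF) model of the image and its kidney/background
label map.

## Who this is for

Segmenting the kidney from its surrounding abdominal structures is the first
step of any DW-MRI renal analysis (ADC mapping, transplant monitoring).
DW-MRI makes this hard: low signal-to-noise ratio and low kidney/background
contrast — both worsening at high b-values — plus diffuse boundaries and
inter-patient anatomical variability.  `renalseg` implements a segmentation
framework designed for exactly these conditions, together with the
evaluation metrics (DSC, 95-percentile Hausdorff distance, volume
difference) and a synthetic multi-subject DW-MRI phantom generator, so the
entire method can be exercised and validated without clinical data.

## The model

A grayscale volume `g : R -> {0..Q-1}` on the voxel lattice `R` and its
binary map `m : R -> {0,1}` are modelled jointly as
`P(g, m) = P(g|m) · P_sp(m) · P_V(m)`:

- **First-order appearance, `P(g|m)`** — the marginal gray-level
  distribution is approximated by a *linear combination of discrete
  Gaussians* (LCDG): two positive dominant components (kidney, background)
  plus sign-alternating subordinate components, split into per-class
  likelihoods `Pr(q|l)`.
- **4th-order spatial interactions, `P_V(m)`** — a Gibbs distribution over
  pair, collinear-triple and planar 2×2 quadruple clique families on the
  26-neighborhood.  The potentials are estimated *analytically* from the
  label-equality frequencies of the current map, e.g.
  `V2:eq = 4(F_eq − 1/2)` for pairs, and `V4 = λ*(f4, f3, f2)` for
  quadruples with centred frequencies `f` — no iterative MRF learning.
- **Adaptive shape prior, `P_sp(m)`** — training b0 scans and expert maps
  are nonrigidly co-aligned (SSD-minimizing registration) into a shape
  database; for a test image, each voxel is mapped into the database and a
  growing search window collects training voxels of similar intensity, whose
  label frequencies give `Pr_sp:p(1)`.

The three factors combine per voxel into the kidney probability
`Pr_p(1) = Ω_kd / (Ω_kd + Ω_bg)` with
`Ω_kd = Pr(q|1)·Pr_V:p(1)·Pr_sp:p(1)` and
`Ω_bg = Pr(q|0)·(1−Pr_V:p(1))·(1−Pr_sp:p(1))`, which drives the level-set
speed: the boundary moves outward where the kidney label holds a strict
majority and inward otherwise, at a rate modulated by the local mean
curvature.  Each b-value scan is segmented separately with its own
appearance and spatial models but a shared shape prior adapted from the
test b0 scan.

## Worked example

Leave-one-subject-out segmentation of a synthetic 8-subject cohort
(48³ voxels, 1.28×1.28×4 mm, b ∈ {0, 500, 1000} s/mm², Rician noise,
bias fields, per-subject deformations):

```python
from renalseg import (PhantomSpec, generate_cohort, leave_one_out,
                      build_shape_database, segment_series, dsc, mhd95, pkvd)
from renalseg.shape_prior import select_reference
from renalseg.preprocess import preprocess_volume

spec = PhantomSpec(seed=7, n_subjects=8, b_values=(0.0, 500.0, 1000.0))
cohort = generate_cohort(spec)

fold, (test_series, truth), train = next(iter(leave_one_out(cohort)))
training = [(preprocess_volume(s.volumes[0]), t) for s, t in train]
ref = select_reference([v for v, _ in training],
                       preprocess_volume(test_series.volumes[0]))
db = build_shape_database(training, ref)

for res in segment_series(test_series, db):
    print(f"b={res.b_value:6.0f}  DSC={dsc(res.mask, truth):.3f}  "
          f"MHD95={mhd95(res.mask, truth, truth.spacing):.2f} mm  "
          f"PKVD={pkvd(res.mask, truth):.2f} %  "
          f"({res.n_iterations} level-set iterations)")
```

Output:

```
b=     0  DSC=0.998  MHD95=0.00 mm  PKVD=0.43 %  (12 level-set iterations)
b=   500  DSC=0.998  MHD95=0.00 mm  PKVD=0.39 %  (12 level-set iterations)
b=  1000  DSC=0.998  MHD95=0.00 mm  PKVD=0.49 %  (12 level-set iterations)
```

DSC is the Dice overlap with the ground-truth mask (1 = perfect), MHD95 the
95th percentile of symmetric boundary-to-boundary distances in mm (0 =
boundaries coincide), and PKVD the kidney volume error as a percentage of
the true volume.  The held-out subject never contributes to the shape
database, so the numbers measure generalization across the cohort's
anatomical variability.

The same workflow is available from the shell:

```bash
renalseg simulate --out-dir cohort --n-subjects 8 --seed 7
renalseg segment  --cohort-dir cohort --subject phantom00 --out-dir seg
renalseg evaluate --seg-dir seg --cohort-dir cohort --out-csv metrics.csv
```

## Layout

| module | contents |
| --- | --- |
| `renalseg.io_volumes` | `Volume` / `RegionMap` / `DWISeries`, NIfTI/Analyze/raw I/O |
| `renalseg.preprocess` | non-parametric bias correction, histogram equalization |
| `renalseg.lcdg` | LCDG appearance model and class splitting |
| `renalseg.mgrf4` | clique families, analytic Gibbs potentials, conditionals, sampler |
| `renalseg.shape_prior` | reference selection, nonrigid registration, adaptive prior |
| `renalseg.levelset` | signed distance, curvature, guidance, evolution, orchestration |
| `renalseg.metrics` | DSC, MHD95, PKVD, cohort reports |
| `renalseg.phantom` | synthetic DW-MRI kidney cohort generator |
| `renalseg.cli` | `renalseg` command-line tool |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
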