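# hipspace

Virtual hip populations for studying the **ischiofemoral space** — the
clearance between the lesser trochanter of the femur and the ischium.
A narrowed ischiofemoral space compresses the quadratus femoris muscle
(ischiofemoral impingement), a condition with a strong female
predominance that is thought to trace back to the obstetric adaptation
of the female pelvis.  `hipspace` is aimed at musculoskeletal
researchers who want to run population-scale, in-silico experiments on
this geometry: generate sex-specific virtual cohorts, measure discrete
hip morphometrics and the ischiofemoral distance both in stance and
through a gait cycle, and relate overall hip shape to the available
clearance.

## What is inside

* **Parametric hip generator** — corresponded pelvis + femur surface
  meshes whose discrete measures (neck–shaft angle, femoral anteversion,
  femoral offset, head radius, lesser-trochanter retroversion, femoral
  length, pelvic width, interspinous distance) and the neutral-pose
  ischiofemoral gap are *direct parameters*, drawn from sex-specific
  multivariate normal population distributions.  Every generated mesh
  shares one topology, so dense correspondence is exact by construction.
* **Point distribution model (PDM)** — the generative linear shape model

  `S = S̄ + Pᵀb`, with `bᵢ ~ N(0, λᵢ)`

  fitted by PCA of corresponded shapes; Monte-Carlo population sampling,
  reconstruction, and Mahalanobis-space scores `bᵢ/√λᵢ`
  (sklearn-style estimator: `fit` / `transform` / `inverse_transform`).
* **Morphometry** — landmark- and region-based measures, plus the
  ischiofemoral distance as an exact nearest-neighbor search between the
  lesser-trochanter vertex set and the pelvis.
* **Kinematics** — spherical hip joint (intrinsic
  flexion/adduction/internal-rotation Euler sequence), packaged
  normative gait waveforms, distance trajectories over the cycle and
  pure flexion/extension sweeps.
* **Statistics** — Welch sex-difference test, per-measure correlation
  tables, canonical correlation of shape scores with the distance,
  PLS-based shape-variance-explained, and ±k SD consensus shape
  regressions.
* **Pipeline CLI** — `hipspace generate|measure|gait|stats|all` driven
  by a YAML configuration, with seeded, byte-stable artifacts.

## Worked example

```python
from hipspace import (default_distributions, build_hip, measure_hip,
                      normative_gait, ifd_trajectory)

params = default_distributions("female").mean_params()
pelvis, femur = build_hip(params)
rec = measure_hip(pelvis, femur, sex="female")
print(f"neck-shaft angle      {rec.neck_shaft_angle:7.2f} deg")
print(f"interspinous distance {rec.interspinous_distance:7.2f} mm")
print(f"ischial spine ratio   {rec.ischial_spine_ratio:7.2f}")
print(f"ischiofemoral dist.   {rec.ischiofemoral_distance:7.2f} mm")
traj = ifd_trajectory(pelvis, femur, normative_gait("female"))
print(f"min IFD during gait   {traj.min_ifd:7.2f} mm at {traj.min_phase:.0f}%")
```

prints

```
neck-shaft angle       126.44 deg
interspinous distance  114.68 mm
ischial spine ratio      0.66
ischiofemoral dist.     22.24 mm
min IFD during gait     17.31 mm at 46%
```

The hip built at the female population means measures back exactly its
parameters (the generator is calibrated so morphometry inverts it), and
walking narrows the space from 22.2 mm to 17.3 mm with the minimum in
terminal stance (46% of the cycle), where hip extension peaks.

A cohort-level contrast (n = 500 per sex, seeded):

```python
from hipspace import generate_cohort, measure_cohort, sex_difference_test
m, _ = generate_cohort("male", 500, seed=1)
f, _ = generate_cohort("female", 500, seed=2)
res = sex_difference_test(measure_cohort(m, sex="male")["ischiofemoral_distance"],
                          measure_cohort(f, sex="female")["ischiofemoral_distance"])
# male   IFD 29.1 +/- 4.2 mm
# female IFD 22.0 +/- 4.3 mm
# Welch t = 26.5, p = 1.63e-117
```

The female ischiofemoral space is ~7 mm narrower at essentially equal
pelvic width — the sex difference is carried by the wider female
interspinous distance (hemipelvic version) and the smaller femoral
offset.

## Full pipeline from the shell

```bash
cat > config.yaml <<EOF
seed: 1
n: 2000
sexes: [female, male]
n_modes: 20
output_dir: out/
EOF
hipspace all --config config.yaml
```

writes per-sex mesh cohorts, ground-truth and morphometric tables, gait
trajectory summaries, the correlation table, CCA/PLSR summaries and the
±3 SD consensus shapes.

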