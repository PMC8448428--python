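# Methods

## The experiment

The package implements a Monte-Carlo, virtual-population study of the
ischiofemoral space.  Sex-specific hip anatomies are generated, each is
measured with a fixed set of discrete descriptors plus the minimal
ischiofemoral distance (IFD), gait rotations are imposed on a spherical
hip joint to obtain the IFD as a function of the gait cycle, and the
relation between overall hip shape and the IFD is quantified with
correlation, canonical correlation and partial-least-squares analyses.

Because no deposited training data exists for a real statistical shape
model of the lower limb, the cohort source is a *synthetic parametric
generator*: anatomy is assembled from geometric primitives whose
parameters are exactly the quantities the morphometry measures.  This
turns every population-level result into a recoverable ground truth and
makes the entire pipeline testable offline.  The trade-off is explicit:
the generator emulates the *distributional* structure of hip anatomy
(sex-specific means, spreads and selected correlations), not the
continuous surface detail of real bones.

## Coordinate and rotation conventions

Right-handed frame in millimetres: x left→right, y posterior→anterior,
z inferior→superior.  The neutral pose places the pelvis in this frame
with the femoral head center of the studied (right) hip at the origin.
Hip rotations are intrinsic Euler angles in the order
flexion(+)/extension(−) about x, adduction(+)/abduction(−) about y′,
internal(+)/external(−) rotation about z″, signs stated for a right
hip.  The default side is the right hip (with an exact mirrored-pair
generator for the left) because this sign convention is anatomically
consistent for the right side; building a left hip by default would
silently turn positive "adduction" into abduction.  The sequence label
is configurable wherever rotations enter.

## The synthetic generator

Each virtual subject is a 9-vector of parameters drawn from a
multivariate normal per sex:

| parameter | female | male | units |
|---|---|---|---|
| neck–shaft angle | 126.44 ± 5.51 | 125.22 ± 5.48 | deg |
| femoral anteversion | 10.82 ± 6.06 | 9.86 ± 7.07 | deg |
| femoral offset | 33.21 ± 6.80 | 38.05 ± 7.72 | mm |
| ischiofemoral gap | 22.24 ± 4.32 | 29.09 ± 4.12 | mm |
| head radius | 22.37 ± 1.02 | 25.29 ± 1.06 | mm |
| LT retroversion | 27.23 ± 8.31 | 27.17 ± 7.70 | deg |
| femoral length | 398.24 ± 19.99 | 427.68 ± 20.12 | mm |
| pelvic width | 172.92 ± 8.23 | 174.30 ± 8.36 | mm |
| interspinous distance | 114.68 ± 6.41 | 100.04 ± 7.01 | mm |

These are adult western-European population values.  The derived
interspinous/pelvic-width ratio then lands at 0.66 (female) and 0.57
(male).  Note this ratio is reported in some sources under the label
"pelvic/ischial-spine ratio" although numerically it is spine-width
divided by pelvic width; the package adopts the numerically consistent
reading.

The default correlation structure couples the gap positively to femoral
offset (+0.4) and negatively to the interspinous distance (−0.6).  The
*signs* mirror what is reported for real hips; the magnitudes are a
design choice that lets the statistics demonstrate sign recovery — they
are not claimed to reproduce any real-population r values, which depend
on a covariance structure no synthetic stand-in can supply.  The scale
of these couplings is configurable (`coupling_scale`), and arbitrary
correlation matrices can be passed.  Draws violating anatomical
invariants (e.g. neck–shaft angle outside 90–160°, interspinous wider
than the pelvis) are redrawn; at the default distributions this affects
a negligible fraction of draws, so means are effectively untruncated.

Geometry.  The bones are assemblies of parametric patches on fixed
grids (≈950 femur and ≈600 pelvis vertices), so all meshes share one
topology and vertex correspondence is exact.  The femoral head is an
exact sphere; the shaft is a symmetric cylinder whose principal axis is
the shaft axis; the neck base sits on that axis so the neck axis forms
exactly the neck–shaft angle and the head center sits exactly the
femoral offset off the axis; condylar landmarks define the posterior
condylar line for the projected (anteversion/retroversion) angles;
iliac and ischial-spine landmark vertices are placed exactly
pelvic-width and interspinous-distance apart.  The ischial surface is a
vertical cylindrical patch positioned so that its grid vertex nearest
the lesser-trochanter apex lies exactly `gap` millimetres away along
the apex's outward (posteromedial) direction; convexity of both facing
surfaces makes this pair the global minimizer, so the neutral-pose IFD
equals the gap parameter to machine precision on noise-free builds.
Build tolerances quoted throughout are ±0.5 mm for lengths and ±1.0°
for angles; the exact construction leaves all of that headroom to
optional vertex noise.

Cohort generation adds i.i.d. Gaussian vertex noise of 0.05 mm by
default — enough to emulate residual surface/correspondence noise and
to keep the shape model's spectrum realistic (noise spreads across all
modes), while more than an order of magnitude below the build
tolerance.  Mesh-resolution and noise choices keep a 2 000-hip cohort
(build + measure) under ~20 s on one CPU.

What the generator does *not* emulate: continuous anatomical surface
variation (everything is primitive-patch geometry), cartilage and soft
tissue, asymmetry between sides, and any age structure.  Tests passing
on this generator therefore validate the *pipeline* — measurement
correctness, model algebra, statistical machinery — not anatomical
fidelity of the shapes themselves.

## Morphometry

All measures are computed from named landmarks and vertex regions and
are rigid-invariant.  The anterior reference for the signed projected
angles is derived from the mesh's own chirality (distal shaft axis ×
lateral→medial condylar direction), so mirroring flips signed angles
and preserves all unsigned measures.  Femoral length is defined head
center → mid-condylar landmark; definitions of length vary in the
literature and any consistent choice works for round-trip calibration.

The IFD is the minimal Euclidean distance from the
`lesser_trochanter_area` vertex set to the *entire* pelvis vertex set,
found with a KD-tree that is exact (tests assert bitwise equality with
an exhaustive all-pairs scan).  A vertex-to-triangle variant
(`method="surface"`) is provided; at the packaged mesh density the two
differ by less than the build tolerance, and the vertex mode is the
default.  The returned closest pair lets users verify the minimum falls
on the ischium.

## Shape model

PCA of stacked pelvis+femur coordinate vectors (one joint model per
sex, capturing articulated covariation).  Eigenvalues are the
mode variances λᵢ; sampling draws bᵢ ~ N(0, λᵢ) untruncated (an
optional ±k SD clip exists, off by default).  Mode count defaults to 20
— with the ~9-parameter generator plus noise this captures ≥ 99.9% of
training variance; a cumulative-variance-fraction criterion is
available as the alternative retention rule.  Reconstruction copies the
shared topology, which is exactly the automatic landmark transfer the
virtual-population workflow requires.  Models serialize to a single
versioned `.npz` archive.

## Kinematics

The hip is a pure ball joint at the fitted head-sphere center: no
translation, pelvis fixed (an optional anterior-positive pelvic
pre-tilt is exposed).  The packaged normative gait curves are analytic
stand-ins with the canonical features of adult walking — peak flexion
≈ 30–32° near 0% and 100%, peak extension ≈ −10–11° near 50%, small
adduction/rotation excursions, slightly larger flexion range for the
female curve — and a CSV interface accepts measured curves.  The
default phase grid is 2% (51 evaluations per cycle), which keeps
trajectory discretization error below 0.1 mm on the default geometry.
Because the ischium lies posterior to the lesser trochanter, the IFD
shrinks in extension and grows in flexion; consequently the cohort
minimum falls in terminal stance / pre-swing (~46% of the cycle with
the packaged curves).  Trajectories only rotate the lesser-trochanter
vertices against a fixed pelvis KD-tree; this is algebraically
identical to posing the whole femur and re-measuring (asserted in
tests) and keeps cohort sweeps cheap.

## Statistics

* Sex difference: Welch's two-sample t (no equal-variance assumption),
  two-sided.
* Correlation table: per-sex Pearson r with raw two-sided p values,
  plus a clearly-labelled Bonferroni column as an extension.
* CCA: with a single response the canonical correlation equals the
  multiple correlation of the IFD on the Mahalanobis scores, and Rao's
  F approximation reduces exactly to the overall-regression F with
  (t, n − t − 1) degrees of freedom; that is how it is computed (a
  seeded permutation option exists for small n).  sklearn's CCA serves
  as an independent cross-check in the test suite only.  An optional
  size correction partials centroid size out of both sides; the default
  reports the uncorrected association alongside it.
* PLSR: distance → shape with one latent component (single covariate);
  the reported percentage is the centered shape sum-of-squares captured
  by the latent reconstruction.
* Shape regression: per-mode linear regression on the IFD (identical to
  one-component PLS for a single predictor), rendered at the mean and
  ±k SD (default 3).  Linearity guarantees the ±k shapes average to the
  mean shape exactly.

One empirical subtlety, found while validating the package and worth
recording: the PLS shape-variance-explained is *not* monotone in the
offset↔gap coupling, because the femoral offset also translates the
ischial patch (via the head-centered frame) in a direction that
partially cancels the gap's own geometric footprint.  Coupling the gap
through the interspinous distance — whose footprint is geometrically
disjoint from the gap's — is the clean dial, and that is what the
corresponding test uses (with common random numbers across coupling
settings).

## Numerical choices

* Sphere fit: closed-form algebraic least squares; coplanarity is
  rejected at a 1e-9 relative singular-value threshold.
* Shaft axis: leading right singular vector of the centered region,
  oriented distally by the condylar landmark.
* PDM degeneracy: total variance below 1e-12 of the mean squared
  coordinate is rejected (identical training shapes).
* Ties in the trajectory minimum resolve to the first phase.
* PLY output is binary little-endian with *double* precision —
  single-precision coordinates cannot honor the 1e-6 mm round-trip
  contract at anatomical scale.  OBJ output is text at 8 decimals.
  Readers never merge or reorder vertices (order is the
  correspondence).

## Problem sizes and determinism

Default study scale is 2 000 hips per sex (population-level means then
carry standard errors of ~0.1–0.2 mm; the statistical conclusions
depend on standard errors, not on matching a particular cohort size),
500 training shapes for model-capacity checks, and 300-hip cohorts in
the unit-test fixtures.  Every stochastic step takes an explicit seed;
cohort generation, the pipeline stages and the acceptance script are
reproducible to the byte for a fixed seed.

## Known limitations

* Synthetic anatomy only; no claim of surface realism beyond the
  measured descriptors, and real-population covariance-dependent
  quantities (correlation magnitudes, shape-variance-explained
  percentages) are demonstrated structurally, not reproduced.
* Gait is purely rotational and non-weight-bearing; no joint
  translation, contact or muscle forces.
* Pelvis-side landmarks beyond the measured set (e.g. acetabular rim)
  are not modelled; the acetabulum patch exists for joint congruence
  only.
* The normative gait waveform is an analytic stand-in, not recorded
  subject data.
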