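# Methods

## The measurement model

A joint's flexion angle is defined purely from bone geometry: each bone's
longitudinal axis is the unit vector from the center of its proximal base to
the center of its distal head, and the joint angle is the arccos of the
(clipped) dot product of the two articulating axes. Angles are unsigned in
[0°, 180°]; hyperextension is not distinguished from flexion. Interfaces use
degrees and millimetres throughout; radians appear only internally.

End centers are estimated from a ring of eight surface points picked around
the bone end's outer circumference at roughly 45° spacing. The default
estimator is the **arithmetic centroid**, which is exact for evenly spaced
points on a circle, permutation-invariant, and rigid-motion-equivariant. A
least-squares 3D circle fit (total-least-squares plane via SVD, Kåsa
algebraic seed, Gauss–Newton refinement of geometric residuals) is available
behind `estimate_center(..., method="circle_fit")` and doubles as the
cross-check in tests. On jittered rings the two estimators agree to a small
fraction of the ring radius; neither is uniformly better under the default
noise model, and the centroid is the simpler, assumption-free reading of
"determined on the basis of the coordinates of these eight points".

The hand coordinate frame is anchored at the dorsal concavity of the
capitate with y along the third metacarpal (proximal positive), x palmar,
z completing a right-handed frame (radial for a right hand). Locating the
capitate point anatomically is not algorithmic — the frame constructor takes
it as input. All reported angles are invariant under any common rigid motion
of the landmark data, so the frame only matters for exported geometry, not
for the statistics.

Missing bones produce explicit per-joint `status="missing"` records (12 rows
are always emitted per hand) rather than silent drops; the statistics layer
refuses unbalanced designs, so missingness is surfaced, never imputed.

## The synthetic hand

Real inputs would be CT-segmented bone meshes of ten adult men gripping
10/60/120 mm cylinders; those cannot be redistributed, so the generator
emulates the geometry the measurement procedure actually relies on.

**Bones** are capsule proxies: a cylindrical shaft with spherical end caps,
built as a watertight surface of revolution. The measurement needs only
near-circular end circumferences, which real condyles approximate.
`shaft_radius` (default 8.5 mm) is the *outer finger-segment* radius — bone
plus soft tissue — because that is the surface that contacts a gripped
cylinder. Segment lengths default to a 185.8 mm hand (index
68/42/25/18 mm for metacarpal/proximal/middle/distal, and correspondingly
for the other fingers), scaled linearly by `hand_length_mm`.

**Posing** is planar forward kinematics: one flexion axis per finger
(z-parallel, positive toward the palm), no abduction/adduction — flexion is
the only quantity reported downstream. Posed ground-truth centers reproduce
the commanded joint angles to 1e-9°.

**The grip solver** is a deterministic stand-in for human grasping, valid
for direction-of-effect conclusions only. It uses a circumscribed-polygon
wrap: every bone axis is a tangent line to the offset circle of radius
ρ = cylinder radius + shaft_radius, the metacarpal contacts at its midpoint,
and tangent lengths t propagate distally (t<sub>next</sub> = L − t), giving
joint angle 2·atan(t/ρ). Angles saturate at range-of-motion ceilings
(MP 90°, PIP 105°, DIP 70°, literature values for healthy adults); a
saturated joint releases distal contact, playing the role of the "adjacent
constraint" in the contact contract. A grip is infeasible when the
unclamped total wrap exceeds 360° (the chain would spiral); the error
reports the minimum feasible diameter, solved by bisection. With the
default hand all three study diameters are feasible, every joint angle
strictly decreases from 10 to 60 to 120 mm, unclamped segments are exactly
tangent to the cylinder surface, and a near-flat cylinder (10⁶ mm) leaves
all joints under 5°. The solver's absolute angles are *not* calibrated to
human data — only their ordering is asserted anywhere.

**Landmark noise.** Rings are sampled on the cap sphere's equator (the
plane through the true end center perpendicular to the axis), at nominal
360/n spacing with i.i.d. uniform angular jitter of ±10° and isotropic
Gaussian positional noise of SD 0.2 mm (comparable to picking error at
0.5 mm CT slice thickness). The centroid estimator is unbiased under this
model — the mean displacement over 1000 rings is ~0.01 mm — while the
*per-ring* RMS error is ~0.2–0.3 mm; axis directions divide that by bone
length, so measured angles carry ~0.5° mean absolute error under default
noise (the tests bound this at 2°) and <1e-13° without noise.

**The cohort simulator** produces the balanced long table the statistics
consume: n subjects × 3 diameters × 4 fingers × 3 joints. Cell means and
SDs default to published values for ten adult men gripping 10/60/120 mm
cylinders (e.g. index PIP at 10 mm: 105.5 (9.2)°). Each record is
μ<sub>cell</sub> + f·σ<sub>cell</sub>·z<sub>subject</sub> +
√(1−f²)·σ<sub>cell</sub>·ε with a single standard-normal intercept per
subject, so every cell's total SD equals its prescribed σ exactly. The
between/within split f (`subject_sd_fraction`, default 0.5) is a free
parameter: no per-subject raw data exist, so only total-SD fidelity can be
asserted. Angles are clipped to [0, 180); in extreme draws a PIP angle can
clip to 0, which makes that subject's coupling ratio undefined — such
records are flagged, and CR summaries either refuse them (`policy="strict"`)
or exclude them with reduced cell counts (`policy="omit_flagged"`). What
passing tests show, therefore, is that the *pipeline* recovers whatever
generative truth it is given — not that the generator reproduces the
biomechanics of real hands (it has Gaussian cells, a single shared intercept,
and no diameter-by-subject interaction structure).

## The repeated-measures ANOVA

The decomposition operates on the complete subjects × levels array by
inclusion–exclusion over marginal means: the effect term for an index subset
U is the alternating sum of marginal means over subsets of U, and its SS is
weighted by the observations per U-cell. Summed over all non-empty U this
reproduces the corrected total SS to 1e-10 relative, and on balanced fully
crossed designs Type III SS coincide with this sequential decomposition.
Each within effect is tested against its own effect×subject interaction:
F = (SS/df) / (SS<sub>err</sub>/df<sub>err</sub>) with df = Π(k−1) and
df<sub>err</sub> = df·(n−1).

Sphericity per effect uses the covariance of per-subject orthonormal
contrast scores (Kronecker products of per-factor contrasts, averaging
vectors for uninvolved factors). Mauchly's W uses Box's chi-square
approximation *with* the second-order term, matching R's
`stats::mauchly.test` and pingouin to 1e-8. Greenhouse–Geisser
ε = (Σλ)² / (p·Σλ²), clamped to [1/p, 1]. The correction is gated at
α = 0.05 per effect (the analysis' global α; `correction="gg"` forces it,
`"none"` disables); when applied it multiplies both dfs by ε, and the
reported mean square stays SS divided by the *reported* (corrected) df.
When the contrast covariance is singular — e.g. a 12-dimensional three-way
contrast with only 9 error df — Mauchly is reported as the W = 0 boundary
case with a warning and **no** correction is applied, which is also how
published tables in this design leave the three-way interaction uncorrected
while correcting testable effects. Note one subtlety: shrinking both dfs by
ε ≤ 1 enlarges p wherever the test is near rejection, but for F deep in the
null bulk the survival curves cross; the conservativeness guarantee is a
rejection-region property, and the tests state it that way.

Simple main effects re-run the one-way RM ANOVA of the target factor on the
records at each fixed combination of the other factors, i.e. with the
within-combination error term. Pairwise comparisons default to paired
t-tests on subject means (the common post-hoc when the original software is
unspecified), with a pooled-error variant (`method="pooled"`) behind a
switch; the Bonferroni family is the k(k−1)/2 comparisons within one fixed
combination (m = 3 for diameters or joints, 6 for fingers), with a global
family available. p-values below 5e-4 render as "<0.0005" in reports.

Coupling ratios are averaged as **mean of per-subject ratios**, never the
ratio of cell means — the two differ on heterogeneous cohorts. Marginal
"All" entries are equal-weight means of the collapsed cell means, exact on
the balanced designs this pipeline enforces. Sample SDs use n−1. Rounding
(1 dp angles, 2 dp CR) happens only at presentation.

## Problem sizes and numerical choices

The acceptance script and heavy tests use: 1000 replicates for the
spherical-null type-I calibration at the study's n = 10 (each effect's
rejection rate lands in [0.03, 0.07]; the Mauchly gate fires at ~5% under a
true null and only nudges rates conservatively); 20 simulated cohorts for
the cross-check against R's `aov` (agreement ~1e-13 relative, asserted at
1e-8); 200 cohorts for post-hoc power; 100 noise seeds for angle-recovery
error; 10000 subjects for generator-honesty checks (cell means within 3 SE).
These sizes give Monte-Carlo SEs comfortably below every asserted margin.

One power result is deliberately left failing rather than adjusted: the
10 mm vs 120 mm Bonferroni contrast should reject near-universally for every
finger × joint, but the index/DIP cell inherits the cohort's largest
reported SD (22.7° at 10 mm, against a 29.3° mean difference), capping its
paired-t power at α/3 around 0.85–0.92 at n = 10 under the documented
generator. That is a property of the published cell statistics plus the
stated generative model, not an implementation defect — the corresponding
measured contrast was also the weakest diameter effect in the source cohort
— and tuning the variance split to force it green would misrepresent the
generator. All other 11 cells reject in 100% of seeds.

Degenerate inputs are first-class: zero-variance responses flag F as
undefined instead of dividing by zero; dot products are clipped to [−1, 1]
before arccos; rings need ≥3 non-collinear points; single-subject summary
cells report SD 0 with n = 1 visible; empty input directories and unbalanced
tables are hard errors naming the offending cell.

## Known limitations

Bone shape is non-biofidelic (capsules); the thumb, abduction/adduction,
tendon mechanics, and contact forces are out of scope. The grip solver
validates direction-of-effect claims only. The cohort generator cannot
recover the true between/within variance split of the source cohort, so
inferential results on simulated data quantify pipeline correctness, not
new biomechanics.
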