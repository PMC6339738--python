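# cylgrip

Finger joint flexion angles during cylinder gripping, measured the way
CT-based bone morphometry measures them — from bone longitudinal axes rather
than skin-mounted markers or glove sensors — together with the
repeated-measures statistics used to analyse such cohorts.

When a hand power-grips a cylinder, every joint of the four fingers (DIP,
PIP, MP) flexes more as the cylinder gets thinner, and the ratio of DIP to
PIP flexion (the *coupling ratio*, CR) summarises how the two
interphalangeal joints share the work. Quantifying this matters for
prosthetic hand and robotic gripper design, where coupled joints reduce
actuator counts. The measurement itself is simple and robust: for each
phalanx or metacarpal, pick eight surface points around the outer
circumference of each bone end, estimate the end **center** from the ring,
form the longitudinal axis **u** = (head − base)/‖head − base‖, and define
the flexion angle of a joint as

θ = arccos(**u**<sub>prox</sub> · **u**<sub>dist</sub>) ∈ [0°, 180°]

between the axes of its two articulating bones. CR = θ<sub>DIP</sub> /
θ<sub>PIP</sub> per subject, finger, and grip.

Because CT scans of gripping hands cannot be shared, the package includes a
first-class synthetic generator: capsule-proxy bones posed by planar forward
kinematics with known ground-truth angles, a deterministic cylinder-wrap
grip solver, a noisy landmark-ring sampler, and a cohort simulator with
published per-cell means and SDs. Every downstream stage is therefore
testable against exact truth.

The statistical layer is a from-scratch balanced within-subject factorial
ANOVA (diameter × finger × joint) with Type III sums of squares, each effect
tested against its own effect×subject error term, Mauchly's sphericity test
on orthonormal effect contrasts, Greenhouse–Geisser df correction when
sphericity is rejected, simple main effects, and Bonferroni-adjusted paired
comparisons — validated against base R's `aov` error-strata decomposition
and pingouin's sphericity routines.

## Worked example

```python
from cylgrip import measure_hand, rm_anova
from cylgrip.synthetic_hand import (
    GripScenario, default_cohort_spec, default_hand,
    pose_finger_chain, sample_hand_rings, simulate_cohort, solve_grip_pose)
from cylgrip.landmark_geometry import FINGERS

hand = default_hand()                       # 185.8 mm reference hand
pose = solve_grip_pose(hand, GripScenario(60.0))
print({j: round(pose.angle("index", j), 1) for j in ("MP", "PIP", "DIP")})
# {'MP': 82.9, 'PIP': 23.5, 'DIP': 47.6}

placements = {f: pose_finger_chain(hand[f], pose) for f in FINGERS}
rings = sample_hand_rings(placements, seed=42)   # 10 deg jitter, 0.2 mm noise
print(measure_hand(rings).head(3))
#   finger joint  angle_deg status
# 0  index   DIP  48.629294     ok
# 1  index   PIP  23.771020     ok
# 2  index    MP  82.734437     ok
```

The measured angles recover the posed truth to well under a degree of mean
absolute error under the default landmark-picking noise, and exactly
(<1e-13°) without noise.

A simulated 10-subject cohort reproduces the full analysis chain:

```python
coh = simulate_cohort(default_cohort_spec(seed=42))   # 360 records
res = rm_anova(coh, "angle_deg", ["diameter_mm", "finger", "joint"], "subject")
print(res.to_markdown())
```

| Source | df | Type III SS | Mean square | F | P |
|---|---|---|---|---|---|
| diameter_mm | 2 | 198908.355 | 99454.178 | 1041.958 | <0.0005 |
| finger | 3 | 5363.006 | 1787.669 | 24.058 | <0.0005 |
| joint | 2 | 23969.305 | 11984.653 | 193.454 | <0.0005 |
| diameter_mm:finger | 6 | 1503.761 | 250.627 | 3.586 | 0.005 |
| diameter_mm:joint | 2.880 | 21645.656 | 7516.506 | 71.831 | <0.0005 |
| finger:joint | 6 | 3530.792 | 588.465 | 9.367 | <0.0005 |
| diameter_mm:finger:joint | 12 | 3136.229 | 261.352 | 2.671 | 0.004 |

The `diameter_mm:joint` row shows a Greenhouse–Geisser-corrected
(non-integer) df because Mauchly's test rejected sphericity for that effect;
diameter dominates every other source of variation, and all interactions are
significant — so the per-combination simple effects and Bonferroni pairwise
tables that `cylgrip analyze` also emits are the appropriate follow-up.

## Command line

```sh
cylgrip simulate -o run/ --seed 7     # meshes (PLY/STL), rings, cohort CSV
cylgrip measure  -i run/ -o angles.csv
cylgrip analyze  -i run/cohort_angles.csv -o analysis/
cylgrip report   -i analysis/ -o report.md
```

All randomness flows from the config seed; rerunning any stage with the same
inputs is byte-identical.

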