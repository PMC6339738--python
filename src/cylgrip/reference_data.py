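"""Published summary statistics used to parameterize the simulator.

These are cohort-level summary values for ten adult men power-gripping
10/60/120 mm cylinders, measured with the CT bone-model method this package
re-implements: per-cell mean (SD) flexion angles for every diameter x finger
x joint cell, and the corresponding per-cell coupling-ratio (DIP/PIP) means.
They serve as the default generative parameters of
:func:`cylgrip.synthetic_hand.simulate_cohort` and as worked-example inputs;
no raw per-subject data exist behind them here.
"""

from __future__ import annotations

DIAMETERS_MM = (10, 60, 120)
FINGERS = ("index", "middle", "ring", "small")
JOINTS = ("DIP", "PIP", "MP")

#: (diameter_mm, finger, joint) -> (mean flexion angle deg, SD deg), n=10.
CELL_ANGLE_STATS: dict[tuple[int, str, str], tuple[float, float]] = {
    (10, "index", "DIP"): (48.2, 22.7),
    (10, "index", "PIP"): (105.5, 9.2),
    (10, "index", "MP"): (65.6, 7.9),
    (10, "middle", "DIP"): (64.8, 16.4),
    (10, "middle", "PIP"): (104.8, 9.8),
    (10, "middle", "MP"): (75.9, 5.5),
    (10, "ring", "DIP"): (57.2, 16.8),
    (10, "ring", "PIP"): (110.5, 6.1),
    (10, "ring", "MP"): (76.6, 14.9),
    (10, "small", "DIP"): (65.8, 8.9),
    (10, "small", "PIP"): (93.0, 13.3),
    (10, "small", "MP"): (64.1, 12.1),
    (60, "index", "DIP"): (35.2, 6.8),
    (60, "index", "PIP"): (48.0, 7.7),
    (60, "index", "MP"): (39.7, 11.8),
    (60, "middle", "DIP"): (34.5, 7.5),
    (60, "middle", "PIP"): (48.1, 8.1),
    (60, "middle", "MP"): (46.3, 15.4),
    (60, "ring", "DIP"): (27.1, 7.1),
    (60, "ring", "PIP"): (48.7, 6.8),
    (60, "ring", "MP"): (38.7, 12.5),
    (60, "small", "DIP"): (30.0, 9.6),
    (60, "small", "PIP"): (32.8, 11.3),
    (60, "small", "MP"): (35.2, 15.9),
    (120, "index", "DIP"): (18.9, 6.1),
    (120, "index", "PIP"): (24.2, 6.5),
    (120, "index", "MP"): (32.2, 5.5),
    (120, "middle", "DIP"): (20.0, 12.0),
    (120, "middle", "PIP"): (25.9, 6.7),
    (120, "middle", "MP"): (22.9, 10.3),
    (120, "ring", "DIP"): (16.1, 6.4),
    (120, "ring", "PIP"): (24.7, 9.1),
    (120, "ring", "MP"): (15.1, 8.5),
    (120, "small", "DIP"): (11.9, 5.3),
    (120, "small", "PIP"): (15.2, 5.2),
    (120, "small", "MP"): (12.6, 5.7),
}

#: (diameter_mm, finger) -> mean coupling ratio DIP/PIP across the cohort.
CR_CELL_MEANS: dict[tuple[int, str], float] = {
    (10, "index"): 0.47, (10, "middle"): 0.62, (10, "ring"): 0.52, (10, "small"): 0.73,
    (60, "index"): 0.77, (60, "middle"): 0.75, (60, "ring"): 0.58, (60, "small"): 1.10,
    (120, "index"): 0.85, (120, "middle"): 0.96, (120, "ring"): 0.73, (120, "small"): 0.97,
}

#: Published Type III sums of squares from the cohort's three-way
#: repeated-measures ANOVA of flexion angle (uncorrected-df main effects),
#: used as worked-example inputs for table-consistency checks.
ANGLE_ANOVA_TYPE_III_SS = {"fingers": 4014.324, "joints": 26868.242}

#: Cohort anthropometrics (adult male, n=10): mean hand length in mm.
MEAN_HAND_LENGTH_MM = 185.8
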