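"""Published reference values for the *Hippocampus reidi* diet-switch experiment.

Juveniles from one captive-bred batch were switched from copepods to
*Artemia* nauplii at 6 days after release (diet A6) or 11 days (diet A11),
two rearing tanks per diet, and pooled tissue samples (n = 4 juveniles per
tank) were analysed for d13C/d15N at 6, 11, 18, 25, 32, 46 and 60 DAR.
This module records the study's reported per-diet mean dry weights, the
fitted kinetic parameters of both incorporation models, and the prey isotope
baselines.  These are *inputs* for the ``reproduce`` pipeline verb (which
recomputes every derived column from them), the defaults of the synthetic
generator, and validation of new analyses — they are never injected into a
fit of user data.
"""

from __future__ import annotations

DIETS = ("A6", "A11")
SWITCH_DAY = {"A6": 6, "A11": 11}
FINAL_DAY = 60
SAMPLING_DAYS = (6, 11, 18, 25, 32, 46, 60)

#: Reported analytical precision (1 sigma, permil) of the mass-spec laboratory.
ANALYTICAL_SD = 0.15

#: Mean dry weights (mg) per diet and day-after-release (two tanks pooled).
MEAN_DRY_WEIGHT_MG = {
    "A6": {6: 0.80, 11: 1.30, 18: 3.33, 25: 9.28, 32: 10.50, 46: 15.61, 60: 22.78},
    "A11": {11: 2.20, 18: 3.53, 25: 10.63, 32: 17.38, 46: 22.85, 60: 65.85},
}

#: Mean C:N mass ratios per diet and day (lipid-content proxy).
MEAN_CN = {
    "A6": {6: 5.75, 11: 3.03, 18: 3.20, 25: 3.07, 32: 2.88, 46: 2.80, 60: 2.85},
    "A11": {11: 3.14, 18: 3.07, 25: 3.29, 32: 3.14, 46: 3.05, 60: 2.91},
}

#: Prey isotope means +/- sd (permil): the pre-switch and post-switch diets.
PREY_VALUES = {
    "copepod": {"d13C": (-21.1, 0.7), "d15N": (5.2, 0.4)},
    "artemia": {"d13C": (-18.0, 1.9), "d15N": (12.3, 0.8)},
}

#: Precise Artemia baseline used for discrimination (full-precision means).
ARTEMIA_BASELINE = {"d13C": -18.03, "d15N": 12.27}

#: Reported growth-based (G) model estimates: delta_eq +/- SE, c +/- SE, R2.
MODEL_G_ESTIMATES = {
    ("A6", "d13C"): {"delta_eq": -16.3, "se_delta_eq": 0.5, "c": -1.474, "se_c": 0.489, "r2": 0.831},
    ("A11", "d13C"): {"delta_eq": -15.7, "se_delta_eq": 0.4, "c": -1.037, "se_c": 0.103, "r2": 0.776},
    ("A6", "d15N"): {"delta_eq": 14.1, "se_delta_eq": 0.3, "c": -1.326, "se_c": 0.269, "r2": 0.934},
    ("A11", "d15N"): {"delta_eq": 14.9, "se_delta_eq": 0.5, "c": -0.844, "se_c": 0.176, "r2": 0.959},
}

#: Reported time-based (D) model estimates: delta_eq +/- SE, m +/- SE, R2.
MODEL_D_ESTIMATES = {
    ("A6", "d13C"): {"delta_eq": -16.2, "se_delta_eq": 0.9, "m": 0.040, "se_m": 0.070, "r2": 0.816},
    ("A11", "d13C"): {"delta_eq": -15.6, "se_delta_eq": 0.8, "m": 0.035, "se_m": 0.047, "r2": 0.828},
    ("A6", "d15N"): {"delta_eq": 14.2, "se_delta_eq": 0.5, "m": 0.041, "se_m": 0.018, "r2": 0.916},
    ("A11", "d15N"): {"delta_eq": 14.6, "se_delta_eq": 0.1, "m": 0.030, "se_m": 0.008, "r2": 0.944},
}

#: Reported turnover columns per diet/isotope/model: G_50/G_95 (fold biomass)
#: and D_50/D_95 (days).  Each model's native scale is G (weight) or D (days);
#: the other pair in each row is the study's own cross-scale conversion, whose
#: exact transformation was not recomputable (see docs/methods.md).
REPORTED_TURNOVER = {
    ("A6", "d13C", "G"): {"g50": 1.6, "g95": 7.6, "d50": 8.4, "d95": 36.3},
    ("A11", "d13C", "G"): {"g50": 2.0, "g95": 43.7, "d50": 10.1, "d95": 74.4},
    ("A6", "d13C", "D"): {"g50": 2.5, "g95": 8.8, "d50": 6.8, "d95": 29.4},
    ("A11", "d13C", "D"): {"g50": 2.0, "g95": 8.5, "d50": 6.6, "d95": 28.6},
    ("A6", "d15N", "G"): {"g50": 1.7, "g95": 9.6, "d50": 9.3, "d95": 40.3},
    ("A11", "d15N", "G"): {"g50": 2.3, "g95": 34.8, "d50": 12.4, "d95": 57.3},
    ("A6", "d15N", "D"): {"g50": 2.5, "g95": 8.6, "d50": 6.7, "d95": 28.9},
    ("A11", "d15N", "D"): {"g50": 2.0, "g95": 9.4, "d50": 6.9, "d95": 30.1},
}

#: Reported growth/metabolism partition highlights: under the growth model,
#: diet A6 showed moderate metabolic contributions (25% for d13C, 19% for
#: d15N); every other cell had G_50 >= 2, i.e. no metabolic contribution.
REPORTED_PM_PERCENT = {("A6", "d13C", "G"): 25, ("A6", "d15N", "G"): 19}

#: Reported cross-model average discrimination factors (mean, sd; permil).
REPORTED_AVG_DISCRIMINATION = {
    ("A6", "d13C"): (1.8, 0.1),
    ("A6", "d15N"): (1.9, 0.1),
    ("A11", "d13C"): (2.9, 0.7),
    ("A11", "d15N"): (2.5, 0.2),
}

#: Reported trophic discrimination factors (permil) per diet/isotope/model.
#: The G/A11/d13C value (3.4) is the study's own, internally inconsistent with
#: its delta_eq (see docs/methods.md); kept verbatim because it feeds the
#: reported cross-model average 2.9 +/- 0.7.
REPORTED_DISCRIMINATION = {
    ("A6", "d13C"): {"G": 1.7, "D": 1.8},
    ("A11", "d13C"): {"G": 3.4, "D": 2.4},
    ("A6", "d15N"): {"G": 1.8, "D": 1.9},
    ("A11", "d15N"): {"G": 2.6, "D": 2.3},
}


def reference_growth_rate(diet: str) -> float:
    """Endpoint growth rate k (per day) from the reported mean dry weights."""
    from .core import growth_rate_k

    w = MEAN_DRY_WEIGHT_MG[diet]
    t0, t1 = SWITCH_DAY[diet], FINAL_DAY
    return growth_rate_k(w[t0], w[t1], t1 - t0)
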