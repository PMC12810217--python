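"""Reference cohort summary statistics (built-in generator defaults).

Published group-level summaries from a four-group cross-sectional cohort
of 43 men (young/old x athlete/control): anthropometrics, per-muscle
shell/centre fat fractions from six-point DIXON MRI, jumping-muscle
composite volumes / lean volumes / countermovement-jump peak powers, and
the age-group power-versus-volume regression lines.  These numbers are
the stated world the synthetic cohort generator emulates and the inputs
to the worked dynapenia-decomposition example.

All fat fractions are percent of the total 1H signal; volumes are ml;
powers are kW; values are (mean, SD) unless noted.
"""

from __future__ import annotations

GROUPS = ("young_athlete", "young_control", "old_athlete", "old_control")

#: Cohort anthropometrics: n, age (years), height (cm), body mass (kg).
ANTHROPOMETRICS = {
    "young_athlete": {"n": 10, "age_y": (24, 2), "height_cm": (180.2, 8.3), "mass_kg": (77.4, 14.0)},
    "young_control": {"n": 12, "age_y": (29, 4), "height_cm": (181.1, 6.5), "mass_kg": (73.6, 13.0)},
    "old_athlete": {"n": 10, "age_y": (65, 4), "height_cm": (177.6, 7.6), "mass_kg": (84.8, 33.8)},
    "old_control": {"n": 11, "age_y": (67, 5), "height_cm": (176.9, 5.6), "mass_kg": (79.8, 8.9)},
}

#: Shell / centre fat fraction per muscle and group:
#: (shell_mean, shell_sd, centre_mean, centre_sd, printed_delta).
#: The printed delta column was computed from unrounded means, so it can
#: differ from shell_mean - centre_mean by up to 0.1 (one printing unit).
SHELL_CENTRE_FF = {
    "gluteus_maximus": {
        "old_athlete": (15.3, 5.7, 5.4, 3.0, 9.9),
        "young_athlete": (8.9, 3.4, 2.4, 1.0, 6.5),
        "old_control": (27.9, 5.3, 11.1, 4.2, 16.8),
        "young_control": (15.0, 8.1, 4.8, 3.1, 10.2),
    },
    "gluteus_medius": {
        "old_athlete": (9.9, 3.9, 3.9, 2.8, 5.9),
        "young_athlete": (5.0, 1.8, 1.5, 1.0, 3.5),
        "old_control": (12.5, 3.4, 5.3, 2.6, 7.1),
        "young_control": (7.5, 3.7, 2.8, 2.3, 4.7),
    },
    "gluteus_minimus": {
        "old_athlete": (7.6, 2.5, 3.7, 2.2, 3.9),
        "young_athlete": (4.6, 1.5, 1.6, 0.8, 3.0),
        "old_control": (9.6, 2.7, 4.5, 1.9, 5.1),
        "young_control": (6.4, 3.2, 2.6, 1.9, 3.8),
    },
    "rectus_femoris": {
        "old_athlete": (6.4, 2.4, 2.3, 1.9, 4.0),
        "young_athlete": (3.9, 0.7, 1.1, 0.4, 2.8),
        "old_control": (8.9, 2.3, 3.1, 1.2, 5.7),
        "young_control": (5.0, 1.7, 1.5, 0.7, 3.6),
    },
    "vastus_intermedius": {
        "old_athlete": (4.9, 1.4, 2.8, 1.3, 2.1),
        "young_athlete": (3.0, 0.7, 1.5, 0.4, 1.5),
        "old_control": (6.2, 1.8, 3.4, 1.3, 2.8),
        "young_control": (3.7, 1.3, 2.1, 1.0, 1.6),
    },
    "vastus_medialis": {
        "old_athlete": (6.6, 1.6, 3.1, 1.1, 3.5),
        "young_athlete": (4.4, 0.9, 1.6, 0.3, 2.8),
        "old_control": (7.3, 1.7, 3.5, 1.5, 3.9),
        "young_control": (5.4, 1.6, 2.1, 0.8, 3.3),
    },
    "vastus_lateralis": {
        "old_athlete": (5.8, 1.4, 2.2, 1.0, 3.6),
        "young_athlete": (3.9, 0.7, 1.4, 0.4, 2.5),
        "old_control": (7.4, 2.0, 3.2, 1.4, 4.2),
        "young_control": (4.9, 1.5, 1.8, 0.9, 3.1),
    },
    "biceps_femoris_breve": {
        "old_athlete": (5.8, 1.5, 3.5, 1.8, 2.2),
        "young_athlete": (4.1, 1.0, 2.9, 1.2, 1.2),
        "old_control": (8.4, 1.5, 7.2, 2.4, 1.2),
        "young_control": (5.7, 1.6, 3.9, 1.7, 1.8),
    },
    "biceps_femoris_longum": {
        "old_athlete": (6.3, 1.3, 3.1, 1.3, 3.2),
        "young_athlete": (4.1, 1.2, 1.8, 0.8, 2.3),
        "old_control": (9.2, 2.4, 5.5, 2.3, 3.7),
        "young_control": (6.0, 2.1, 3.1, 1.6, 2.9),
    },
    "semimembranosus": {
        "old_athlete": (9.2, 4.6, 6.9, 5.2, 2.3),
        "young_athlete": (4.8, 1.1, 2.4, 0.6, 2.4),
        "old_control": (12.3, 3.7, 9.1, 3.7, 3.2),
        "young_control": (6.8, 2.3, 4.0, 2.1, 2.8),
    },
    "semitendinosus": {
        "old_athlete": (6.4, 4.1, 4.2, 3.9, 2.3),
        "young_athlete": (3.7, 1.2, 1.7, 0.7, 1.9),
        "old_control": (9.2, 2.2, 6.5, 2.4, 2.7),
        "young_control": (5.6, 2.3, 3.5, 2.0, 2.2),
    },
    "gracilis": {
        "old_athlete": (5.6, 1.3, 2.2, 0.9, 3.3),
        "young_athlete": (4.2, 1.0, 1.8, 0.7, 2.4),
        "old_control": (8.3, 2.0, 5.1, 2.1, 3.1),
        "young_control": (6.0, 2.1, 3.2, 1.6, 2.8),
    },
    "sartorius": {
        "old_athlete": (6.8, 1.6, 3.8, 1.3, 3.0),
        "young_athlete": (5.1, 0.9, 2.6, 0.8, 2.5),
        "old_control": (8.5, 2.0, 6.3, 2.7, 2.2),
        "young_control": (6.7, 2.5, 4.1, 2.2, 2.6),
    },
    "gastrocnemius_lateralis": {
        "old_athlete": (5.4, 1.3, 3.6, 1.4, 1.8),
        "young_athlete": (4.2, 0.9, 1.8, 0.5, 2.4),
        "old_control": (8.0, 2.4, 4.9, 1.6, 3.1),
        "young_control": (5.3, 1.2, 2.7, 1.0, 2.6),
    },
    "gastrocnemius_medialis": {
        "old_athlete": (5.5, 1.7, 3.5, 1.6, 2.0),
        "young_athlete": (3.5, 0.4, 2.0, 0.4, 1.6),
        "old_control": (8.3, 5.2, 6.2, 3.1, 2.2),
        "young_control": (4.7, 1.1, 3.1, 1.2, 1.7),
    },
    "soleus": {
        "old_athlete": (6.7, 1.9, 5.3, 2.0, 1.4),
        "young_athlete": (3.9, 0.5, 2.5, 0.5, 1.4),
        "old_control": (8.8, 2.9, 7.1, 2.0, 1.7),
        "young_control": (5.0, 1.4, 3.4, 1.3, 1.6),
    },
    "tibialis_anterior": {
        "old_athlete": (5.6, 0.9, 2.9, 1.0, 2.7),
        "young_athlete": (3.5, 0.5, 1.4, 0.4, 2.0),
        "old_control": (6.6, 2.2, 3.8, 1.4, 2.8),
        "young_control": (4.5, 1.0, 2.2, 0.8, 2.3),
    },
}

#: Jumping-muscle composite (glutei + quadriceps + triceps surae):
#: volume, lean volume (ml) and CMJ peak power (kW), (mean, SD), with n.
JUMPING_COMPOSITE = {
    "old_athlete": {"n": 10, "volume_ml": (5285, 895), "lean_volume_ml": (4988, 774), "peak_power_kw": (3.02, 0.56)},
    "old_control": {"n": 11, "volume_ml": (4379, 612), "lean_volume_ml": (3957, 637), "peak_power_kw": (2.63, 0.50)},
    "young_athlete": {"n": 10, "volume_ml": (5758, 1139), "lean_volume_ml": (5614, 1122), "peak_power_kw": (4.55, 0.95)},
    "young_control": {"n": 12, "volume_ml": (4781, 833), "lean_volume_ml": (4534, 767), "peak_power_kw": (3.63, 1.03)},
}

#: Peak power (kW) ~ composite volume (ml) regression per age group:
#: intercept (kW), slope (W/ml), Pearson R, n.
POWER_VOLUME_LINES = {
    "young": {"intercept_kw": -0.61, "slope_w_per_ml": 0.89, "r": 0.94, "n": 22},
    "old": {"intercept_kw": 0.67, "slope_w_per_ml": 0.45, "r": 0.67, "n": 21},
}

#: Slope used to convert effective-volume deficits into power (W/ml);
#: the young-subject regression slope.
REFERENCE_SLOPE_W_PER_ML = 0.89

#: The eight jumping muscles and their fixed share of the composite volume
#: (package design choice: glutei 0.30, quadriceps 0.45, triceps surae 0.25).
JUMPING_MUSCLE_FRACTIONS = {
    "gluteus_maximus": 0.200,
    "gluteus_medius": 0.075,
    "gluteus_minimus": 0.025,
    "rectus_femoris": 0.050,
    "vastus_intermedius": 0.130,
    "vastus_medialis": 0.120,
    "vastus_lateralis": 0.150,
    "gastrocnemius_medialis": 0.080,
    "gastrocnemius_lateralis": 0.040,
    "soleus": 0.130,
}

#: Soleus EMCL / IMCL (% of total 1H signal), (mean, SD) per group.
#: Package choices consistent with the qualitative findings: EMCL always
#: distinctly above IMCL, old-athlete EMCL about half of old controls,
#: IMCL below 2% even in old age.  (No numeric group means are published.)
MRS_LIPID_PCT = {
    "young_athlete": {"emcl": (2.0, 0.6), "imcl": (0.9, 0.25)},
    "young_control": {"emcl": (2.7, 0.8), "imcl": (1.1, 0.30)},
    "old_athlete": {"emcl": (3.5, 1.0), "imcl": (1.2, 0.30)},
    "old_control": {"emcl": (7.0, 1.8), "imcl": (1.6, 0.40)},
}
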