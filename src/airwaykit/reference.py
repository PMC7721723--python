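"""Published group summaries for the Dp16 Down-syndrome mouse upper-airway study.

These are the printed (mean, SD, n) rows of a wild-type vs Dp(16)1Yey mouse
comparison — craniofacial linear distances, whole-body plethysmography
parameters and CFD-derived airflow quantities. They serve as canonical
example inputs for :mod:`airwaykit.stats` (the raw per-animal data were never
deposited) and as realistic moments for synthetic morphometry cohorts.

Each entry is ``(mean_wt, sd_wt, n_wt, mean_dp16, sd_dp16, n_dp16)``.
One Dp16 mouse was excluded from all bone measurements (hydrocephalus),
hence n = 7 in the craniofacial rows but n = 8 elsewhere.
"""
from __future__ import annotations

# Craniofacial linear distances (mm); keys are the conventional measure ids
# a..w (skull/mandible) and x, y, z (hyoid position).  The landmark pair for
# each measure is in ``airwaykit.morphometry.DEFAULT_PAIR_MAP``.
CRANIOFACIAL_MM = {
    "a": (7.09, 0.20, 8, 7.03, 0.19, 7),
    "b": (7.93, 0.17, 8, 7.33, 0.20, 7),
    "c": (3.82, 0.15, 8, 3.69, 0.28, 7),
    "d": (4.20, 0.06, 8, 3.78, 0.05, 7),
    "e": (5.98, 0.19, 8, 6.00, 0.16, 7),
    "f": (7.88, 0.19, 8, 7.53, 0.27, 7),
    "g": (7.41, 0.17, 8, 6.84, 0.07, 7),
    "h": (7.42, 0.19, 8, 6.79, 0.09, 7),
    "i": (3.40, 0.04, 8, 3.19, 0.09, 7),
    "j": (5.27, 0.14, 8, 4.74, 0.26, 7),
    "k": (3.75, 0.12, 8, 3.37, 0.21, 7),
    "l": (2.11, 0.05, 8, 1.92, 0.08, 7),
    "m": (2.66, 0.09, 8, 2.51, 0.05, 7),
    "n": (4.78, 0.11, 8, 4.66, 0.16, 7),
    "o": (5.10, 0.11, 8, 4.75, 0.15, 7),
    "p": (5.10, 0.14, 8, 4.66, 0.15, 7),
    "q": (6.86, 0.13, 8, 6.47, 0.18, 7),
    "r": (6.92, 0.12, 8, 6.53, 0.18, 7),
    "s": (8.57, 0.11, 8, 7.92, 0.19, 7),
    "t": (8.57, 0.19, 8, 7.96, 0.21, 7),
    "u": (3.93, 0.14, 8, 3.86, 0.17, 7),
    "v": (3.87, 0.12, 8, 3.85, 0.18, 7),
    "w": (9.46, 0.14, 8, 9.06, 0.25, 7),
    "x": (4.99, 0.12, 8, 4.70, 0.07, 7),
    "y": (4.18, 0.14, 8, 3.33, 0.19, 7),
    "z": (2.79, 0.12, 8, 2.79, 0.13, 7),
}

# Plethysmography parameters during quiet wakefulness.
RESPIRATORY = {
    "expiratory_time_ms": (254.05, 28.25, 8, 218.26, 33.70, 8),
    "inspiratory_time_ms": (80.61, 17.83, 8, 78.12, 8.03, 8),
}

# CFD-derived quantities at a constant inspiratory flow of 5.28 ml/s
# (the cohort mean of peak inspiratory flow).
CFD = {
    "vmax_nasal_m_s": (12.26, 4.28, 8, 14.76, 6.25, 8),
    "vmax_pharyngeal_m_s": (12.29, 1.16, 8, 17.63, 2.63, 8),
    "pmax_pa": (-689.0, 134.0, 8, -1085.0, 346.0, 8),
    "nasal_volume_mm3": (18.56, 3.22, 8, 14.49, 2.5, 8),
    "pharyngeal_volume_mm3": (5.13, 0.78, 8, 3.39, 0.80, 8),
    "pharyngeal_length_mm": (5.80, 0.23, 8, 5.53, 0.15, 8),
}

# Body characteristics.
BASELINE = {
    "weight_g": (22.23, 2.83, 8, 20.40, 3.27, 8),
    "age_days": (57.0, 12.0, 8, 58.0, 12.0, 8),
}

# Mean peak inspiratory flow used as the constant CFD flow rate (ml/s).
PEAK_INSPIRATORY_FLOW_ML_S = 5.28
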