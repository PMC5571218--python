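"""Published per-vessel parameter estimates for porcine LAD coronary arteries.

Three estimation variants were reported for the same five vessels:

* ``STATISTICAL_FIT`` — orientation/waviness statistics fixed at the
  population averages; only material parameters estimated;
* ``REFINED_FIT`` — geometric distribution parameters additionally
  refined per vessel within the measured statistical ranges;
* ``MEAN_VALUE_FIT`` — every distribution replaced by its mean
  (point-mass microstructure), estimating mean angles and straightening
  strains directly.

Each table maps a parameter name to its five per-sample estimates;
``*_AVERAGES`` carry the published "average ± SD" column as printed
(which occasionally differs from the recomputed sample mean in the last
printed digit).  Units: stiffnesses and stresses MPa, angles rad,
strains and ratios dimensionless.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STATISTICAL_FIT", "REFINED_FIT", "MEAN_VALUE_FIT",
    "STATISTICAL_FIT_AVERAGES", "REFINED_FIT_AVERAGES",
    "MEAN_VALUE_FIT_AVERAGES", "sample_mean",
]

STATISTICAL_FIT = {
    "k_IL":      (0.19, 0.05, 0.02, 0.23, 0.17),
    "k_E":       (0.25, 0.28, 0.13, 0.13, 0.26),
    "k_C":       (10.0, 48.2, 10.9, 100.0, 36.4),
    "M_C":       (5.96, 5.71, 6.00, 5.99, 4.06),
    "rho1":      (0.47, 0.45, 0.63, 0.20, 0.30),
    "rho2":      (1.22, 0.59, 0.03, 1.66, 0.90),
    "lam_max":   (1.44, 1.06, 1.39, 1.38, 1.36),
    "sigma_max": (0.10, 0.11, 0.07, 0.06, 0.12),
    "tau":       (0.14, 0.20, 0.45, 0.87, 0.13),
    "k_SMC":     (0.12, 0.00, 0.003, 0.02, 0.002),
    "R2_P_passive":  (0.80, 0.96, 0.95, 0.96, 0.96),
    "R2_F_passive":  (0.78, 0.77, 0.82, 0.72, 0.86),
    "R2_ro_passive": (0.91, 0.91, 0.96, 0.93, 0.94),
    "R2_P_full":  (0.83, 0.69, 0.99, 0.99, 0.83),
    "R2_F_full":  (0.71, 0.77, 0.72, 0.78, 0.86),
    "R2_ro_full": (0.90, 0.58, 0.85, 0.91, 0.91),
}

STATISTICAL_FIT_AVERAGES = {
    "k_IL": 0.13, "k_E": 0.21, "k_C": 41.1, "M_C": 5.54,
    "rho1": 0.41, "rho2": 0.88, "lam_max": 1.33, "sigma_max": 0.09,
    "tau": 0.36, "k_SMC": 0.03,
    "R2_P_passive": 0.93, "R2_F_passive": 0.79, "R2_ro_passive": 0.93,
    "R2_P_full": 0.87, "R2_F_full": 0.77, "R2_ro_full": 0.83,
}

REFINED_FIT = {
    "k_IL":      (0.15, 0.04, 0.04, 0.28, 0.39),
    "k_E":       (0.30, 0.28, 0.14, 0.28, 0.35),
    "k_C":       (11.8, 55.1, 10.9, 57.9, 11.8),
    "M_C":       (5.68, 5.65, 5.91, 5.58, 3.32),
    "e_02":      (0.39, 0.38, 0.37, 0.38, 0.25),
    "alpha1":    (8.30, 4.97, 4.90, 5.22, 6.97),
    "alpha2":    (71.9, 42.0, 47.7, 67.2, 71.0),
    "mu_E1":     (0.32, 0.20, 0.20, 0.24, 0.29),
    "sd_E1":     (0.26, 0.10, 0.14, 0.12, 0.24),
    "mu_E2":     (1.74, 1.97, 1.80, 1.96, 1.71),
    "sd_E2":     (0.56, 0.46, 0.26, 0.33, 0.30),
    "mu_C1":     (0.20, 0.37, 0.38, 0.38, 0.26),
    "sd_C1":     (0.30, 0.15, 0.27, 0.16, 0.27),
    "mu_C2":     (2.09, 2.08, 1.58, 1.61, 1.71),
    "sd_C2":     (0.22, 0.44, 0.28, 0.24, 0.47),
    "mu_M":      (0.29, 0.18, 0.28, 0.13, 0.26),
    "sd_M":      (0.30, 0.11, 0.13, 0.16, 0.27),
    "rho1":      (0.27, 0.30, 0.47, 0.25, 0.27),
    "rho2":      (1.04, 1.83, 1.66, 1.83, 0.79),
    "lam_max":   (1.45, 1.28, 1.48, 1.35, 1.16),
    "sigma_max": (0.08, 0.09, 0.08, 0.07, 0.11),
    "tau":       (0.32, 0.11, 0.15, 0.26, 0.30),
    "k_SMC":     (0.03, 0.00, 0.00, 0.03, 0.01),
    "mu_SMC":    (0.19, 0.27, 0.22, 0.25, 0.29),
    "sd_SMC":    (0.15, 0.29, 0.29, 0.12, 0.22),
    "R2_P_full":  (0.95, 0.85, 0.99, 0.99, 0.94),
    "R2_F_full":  (0.83, 0.83, 0.77, 0.93, 0.79),
    "R2_ro_full": (0.96, 0.93, 0.87, 0.95, 0.98),
}

REFINED_FIT_AVERAGES = {
    "k_IL": 0.18, "k_E": 0.27, "k_C": 29.5, "M_C": 5.23,
    "e_02": 0.35, "alpha1": 6.07, "alpha2": 60.0,
    "mu_E1": 0.25, "sd_E1": 0.17, "mu_E2": 1.84, "sd_E2": 0.38,
    "mu_C1": 0.32, "sd_C1": 0.23, "mu_C2": 1.81, "sd_C2": 0.33,
    "mu_M": 0.23, "sd_M": 0.19,
    "rho1": 0.31, "rho2": 1.43, "lam_max": 1.34, "sigma_max": 0.09,
    "tau": 0.23, "k_SMC": 0.01,
    "mu_SMC": 0.24, "sd_SMC": 0.21,
    "R2_P_full": 0.94, "R2_F_full": 0.83, "R2_ro_full": 0.94,
}

MEAN_VALUE_FIT = {
    "k_IL":      (0.25, 0.00, 0.03, 0.29, 0.22),
    "k_E":       (0.23, 0.28, 0.21, 0.21, 0.28),
    "k_C":       (10.5, 16.9, 10.7, 42.7, 36.1),
    "M_C":       (5.66, 5.66, 5.71, 5.31, 5.13),
    "e_01":      (0.23, 0.30, 0.29, 0.22, 0.24),
    "e_02":      (0.39, 0.21, 0.38, 0.36, 0.26),
    "mu_E1":     (0.23, 0.31, 0.36, 0.23, 0.20),
    "mu_E2":     (1.70, 1.62, 1.81, 1.63, 1.90),
    "mu_C1":     (0.38, 0.30, 0.33, 0.40, 0.32),
    "mu_C2":     (1.76, 1.85, 1.74, 1.70, 1.77),
    "mu_M":      (0.27, 0.21, 0.26, 0.15, 0.19),
    "rho1":      (0.48, 0.36, 0.53, 0.27, 0.24),
    "rho2":      (1.80, 1.57, 1.73, 1.47, 1.27),
    "lam_max":   (1.48, 1.22, 1.48, 1.47, 1.48),
    "sigma_max": (0.08, 0.10, 0.08, 0.08, 0.12),
    "tau":       (0.13, 0.14, 0.24, 0.17, 0.38),
    "k_SMC":     (0.01, 0.00, 0.00, 0.03, 0.01),
    "mu_SMC":    (0.26, 0.23, 0.27, 0.20, 0.12),
    "R2_P_full":  (0.93, 0.90, 0.86, 0.99, 0.99),
    "R2_F_full":  (0.84, 0.63, 0.70, 0.96, 0.85),
    "R2_ro_full": (0.96, 0.86, 0.79, 0.96, 0.89),
}

MEAN_VALUE_FIT_AVERAGES = {
    "k_IL": 0.16, "k_E": 0.24, "k_C": 23.4, "M_C": 5.50,
    "e_01": 0.26, "e_02": 0.32,
    "mu_E1": 0.27, "mu_E2": 1.73, "mu_C1": 0.36, "mu_C2": 1.76, "mu_M": 0.22,
    "rho1": 0.38, "rho2": 1.57, "lam_max": 1.43, "sigma_max": 0.09,
    "tau": 0.21, "k_SMC": 0.01, "mu_SMC": 0.22,
    "R2_P_full": 0.93, "R2_F_full": 0.80, "R2_ro_full": 0.89,
}


def sample_mean(table: dict, name: str) -> float:
    """Mean of the five per-sample estimates of ``name``."""
    return float(np.mean(table[name]))
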