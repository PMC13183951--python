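"""Published summary statistics from a population-cohort genetic-nurture study.

These are inputs, not results: printed descriptive summaries and effect sizes
from the source cohort study, used to benchmark the pipeline's arithmetic
(direct-genetic-transmission contrasts, FDR adjustment, standardized mean
differences, Wald-difference power) and to calibrate the synthetic cohort's
generative effect sizes.
"""

import pandas as pd

# Joint transmitted / non-transmitted model, standardized coefficients (SE) or OR.
JOINT_EFFECTS = {
    "smoking_initiation": {"family": "binomial", "or_t": 1.853, "or_nt": 0.989},
    "cpd": {"family": "gaussian", "beta_t": 0.202, "se_t": 0.013, "beta_nt": 0.037, "se_nt": 0.013},
    "pack_years": {"family": "gaussian", "beta_t": 0.136, "se_t": 0.011, "beta_nt": 0.028, "se_nt": 0.011},
    "alcohol_g_day": {"family": "gaussian", "beta_t": 0.124, "se_t": 0.007, "beta_nt": 0.016, "se_nt": 0.008},
    "cannabis_initiation": {"family": "binomial", "or_t": 1.274, "or_nt": 1.033},
}

# Unadjusted p-values of the five non-transmitted tests, and their published
# FDR-adjusted counterparts (Benjamini-Hochberg over the five outcomes).
NT_PVALUES = {
    "smoking_initiation": 0.612,
    "cpd": 0.004,
    "pack_years": 0.014,
    "alcohol_g_day": 0.034,
    "cannabis_initiation": 0.328,
}
NT_PVALUES_FDR = {
    "smoking_initiation": 0.612,
    "cpd": 0.020,
    "pack_years": 0.035,
    "alcohol_g_day": 0.057,
    "cannabis_initiation": 0.410,
}

# Published direct-genetic-transmission column (beta_T - beta_NT) and the
# nurture/DGT ratios quoted for the two smoking-quantity outcomes.
DGT_PUBLISHED = {"cpd": 0.165, "pack_years": 0.108, "alcohol_g_day": 0.108}
NURTURE_RATIO_PUBLISHED = {"cpd": 22.4, "pack_years": 25.9}

# Parent-of-origin model for smoking quantity: standardized beta (cluster-robust SE).
POE_EFFECTS = {
    "cpd": {
        "maternal_t": (0.124, 0.012),
        "maternal_nt": (0.039, 0.015),
        "paternal_t": (0.155, 0.013),
        "paternal_nt": (0.036, 0.019),
        "wald_t": {"chi2": 3.35, "p": 0.07},
    },
    "pack_years": {
        "maternal_t": (0.082, 0.011),
        "maternal_nt": (0.027, 0.013),
        "paternal_t": (0.107, 0.011),
        "paternal_nt": (0.034, 0.017),
        "wald_t": {"chi2": 2.49, "p": 0.12},
    },
}

# Power scenario for the maternal-paternal transmitted difference (smoking
# quantity): lower confidence bound of the difference with per-coefficient SEs.
POWER_SCENARIO_CPD = {"delta_beta": 0.067, "se_maternal": 0.012, "se_paternal": 0.013}

# Longitudinal PGS x age interactions on current smoking quantity.
LONGITUDINAL_INTERACTIONS = {
    "t_by_age": (-0.004, 0.001),
    "nt_by_age": (-0.0004, 0.001),
}

# Standardized indirect (mediation) effects through parental smoking quantity.
MEDIATION_EFFECTS_CPD = {
    "maternal_t": 0.026,
    "maternal_nt": 0.029,
    "paternal_t": 0.008,
    "paternal_nt": 0.009,
}

# Descriptive characteristics of the genotyped family subsamples:
# single-genotyped-parent pairs vs complete trios.  Continuous rows carry
# (n, mean, sd); binary rows carry (n, count).
COHORT_DESCRIPTIVES = pd.DataFrame(
    [
        {"characteristic": "age", "kind": "continuous",
         "n_pair": 13417, "mean_pair": 31.86, "sd_pair": 8.70,
         "n_trio": 2454, "mean_trio": 30.59, "sd_trio": 8.02},
        {"characteristic": "female", "kind": "binary",
         "n_pair": 13417, "count_pair": 8376, "n_trio": 2454, "count_trio": 1451},
        {"characteristic": "smoking_initiation", "kind": "binary",
         "n_pair": 13403, "count_pair": 5620, "n_trio": 2450, "count_trio": 940},
        {"characteristic": "cpd", "kind": "continuous",
         "n_pair": 5134, "mean_pair": 10.34, "sd_pair": 6.06,
         "n_trio": 838, "mean_trio": 9.59, "sd_trio": 5.57},
        {"characteristic": "pack_years", "kind": "continuous",
         "n_pair": 5382, "mean_pair": 7.19, "sd_pair": 6.85,
         "n_trio": 894, "mean_trio": 6.04, "sd_trio": 5.88},
        {"characteristic": "alcohol_g_day", "kind": "continuous",
         "n_pair": 13411, "mean_pair": 6.73, "sd_pair": 8.47,
         "n_trio": 2452, "mean_trio": 6.81, "sd_trio": 8.41},
        {"characteristic": "cannabis_initiation", "kind": "binary",
         "n_pair": 7608, "count_pair": 1710, "n_trio": 1489, "count_trio": 359},
    ]
)

SMD_RANGE_PUBLISHED = (0.07, 0.18)
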