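"""Parent-of-origin effects: do maternal and paternal scores act differently?

Splits the transmitted and non-transmitted scores by parent and fits the
four-score path model with full-information maximum likelihood over the
missing scores of ungenotyped parents (pairs), family-clustered robust
standard errors, and a Wald test of maternal-paternal equality.  Monte Carlo
power for the equality test is evaluated at the observed difference and its
confidence bounds.
"""

import numpy as np

from hapnurture.pipeline import frame_from_true_scores
from hapnurture.power import power_grid_from_fit, power_wald_difference
from hapnurture.sem import fit_poe, wald_equality
from hapnurture.sim import GenerativeParams, simulate_scores

params = GenerativeParams(n_families=4000, delta_maternal=0.124, delta_paternal=0.155,
                          nurture_maternal=0.039, nurture_paternal=0.036, seed=5)
pheno, scores, info = simulate_scores(params)
frame = frame_from_true_scores(pheno, scores, waves=1)
# pairs: the non-genotyped parent's non-transmitted score is missing
rng = np.random.default_rng(5)
fams = frame.family_id.unique()
is_pair = rng.random(fams.size) > params.fraction_trios
mask_father = rng.random(fams.size) < params.maternal_bias
frame.loc[frame.family_id.map(dict(zip(fams, is_pair & mask_father))).astype(bool),
          "pgs_nt_paternal_z"] = np.nan
frame.loc[frame.family_id.map(dict(zip(fams, is_pair & ~mask_father))).astype(bool),
          "pgs_nt_maternal_z"] = np.nan

fit = fit_poe(frame, "cpd")
print(fit.ci.round(4))
chi2, df, p = wald_equality(fit, [("maternal_t", "paternal_t")])
print(f"Wald equality of transmitted effects: chi2 = {chi2:.2f} (df {df}), p = {p:.3f}")

row = power_wald_difference(0.067, 0.012, 0.013, n_reps=1000, seed=6)
print(f"power at a difference of 0.067 (SEs 0.012/0.013): {100 * row.power:.1f}% "
      f"(analytic {100 * row.analytic_power:.1f}%)")
grid = power_grid_from_fit(fit, n_reps=1000, seed=7)
print(grid[["constraint", "point", "delta_beta", "power"]].round(3).to_string(index=False))
print("(moderate power at observed differences, high power at the CI bounds, "
      "mirrors how equality tests should be interpreted at this sample size)")
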