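"""Estimate genetic nurture and direct genetic transmission.

Runs the full chain on a simulated cohort — transmission inference, polygenic
scoring, imputation of missing non-transmitted scores, standardization — then
fits the joint PGS_T/PGS_NT mixed model with a family random intercept.  The
non-transmitted coefficient measures genetic nurture; beta_T - beta_NT is the
direct-genetic-transmission (DGT) effect.
"""

from hapnurture import GenerativeParams, simulate_cohort
from hapnurture.nurture import dgt, fdr_adjust, fit_joint_tn, nurture_ratio
from hapnurture.pipeline import score_cohort

params = GenerativeParams(n_families=2000, n_markers=1250, n_chromosomes=2,
                          delta_direct=0.202, beta_nurture=0.037, seed=3)
cohort = simulate_cohort(params)
frame, tmap, table = score_cohort(cohort)

fit = fit_joint_tn(frame, "cpd")
print(f"beta_T  = {fit.beta_t:.3f} (SE {fit.se_t:.3f}, p {fit.p_t:.2g})  "
      "[generative truth 0.202]")
print(f"beta_NT = {fit.beta_nt:.3f} (SE {fit.se_nt:.3f}, p {fit.p_nt:.2g})  "
      "[generative truth 0.037]")
print(f"beta_DGT = beta_T - beta_NT = {dgt(fit):.3f}; "
      f"nurture/DGT ratio = {nurture_ratio(fit):.1f}%")
print("(beta_NT is the genetic-nurture effect: the influence of parental alleles "
      "the offspring did not inherit, acting through the rearing environment)")

fitb = fit_joint_tn(frame, "smoking_initiation", family="binomial")
print(f"smoking initiation: OR_T = {fitb.or_t:.3f}, OR_NT = {fitb.or_nt:.3f} "
      "(mixed logistic, family random intercept)")

print("BH-FDR of {0.612, 0.004, 0.014, 0.034, 0.328}:",
      [round(x, 3) for x in fdr_adjust([0.612, 0.004, 0.014, 0.034, 0.328])])
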