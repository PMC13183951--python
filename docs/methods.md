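# Methods

This note documents the models, algorithms and numerical choices behind
`hapnurture`, what the synthetic cohort does and does not emulate, and the
design decisions taken where the methodology left room.

## 1. The synthetic family cohort (`sim`)

**Genomes.** Founder couples carry independent biallelic markers with minor
allele frequencies drawn from Uniform(`maf_range`, default 0.05–0.5) and
haplotypes drawn independently per marker, so founders are in Hardy–Weinberg
and linkage equilibrium. The genetic map is uniform: each chromosome's length
in centimorgans is `100 × crossover_rate`, so crossovers per meiosis are
Poisson(`crossover_rate`) with breakpoints uniform on the map (no crossover
interference — a Haldane model). Offspring haplotype 0 is the maternal gamete
and haplotype 1 the paternal gamete; `TransmissionTruth` records the source
haplotype of every offspring allele, which is the oracle for validating the
transmission algorithm.

*Deliberately absent:* linkage disequilibrium, mutation, selection,
demography, multi-allelic sites, sex chromosomes, crossover interference.
Tile matching and score decomposition do not depend on LD (real-data LD is
the phasing software's concern, upstream of this package), so passing tests
here validate the transmission and modeling logic, not robustness to LD or
array artifacts.

**Family structure.** Each family has one offspring plus a second with
probability `sibling_rate` (default 0.2, giving ≈1.2 offspring per family,
matching the persons-per-family ratio of large population family cohorts).
`mask_parents` turns all but `fraction_trios` (default 3267/19233 ≈ 0.17) of
families into single-genotyped-parent pairs; the mother remains genotyped
with probability `maternal_bias` (default 0.7 — cohorts typically genotype
more mothers than fathers; the exact ratio is a free parameter, not an
estimate). Masked parents' haplotypes are blanked in the observable data
while the truth retains them.

**Phase errors.** `inject_phase_errors` applies switch errors: independently
per marker with probability `phase_error_rate`, the two haplotypes swap from
that marker onward. Genotype dosages are invariant by construction; only
haplotype identity degrades, which is exactly the error mode of statistical
phasing.

**Phenotypes.** All effect sizes are on the standardized scale. With
per-parent standardized scores `z_mT, z_mNT, z_pT, z_pNT` (z-scored true
haplotype scores), the offspring linear predictor at baseline is

```
eta = δ_m z_mT + δ_p z_pT + ν_m z_mNT + ν_p z_pNT + b_m P_m + b_p P_p
      + sex_main · male + age_main · (age − 33)
```

where `P_m = a_m z_m + √(1−a_m²) ε_m` is the mother's phenotype (`z_m` her
own full-genotype standardized score) and mate-pair noise correlation is set
so that corr(P_m, P_p) = `am_corr` — *phenotypic* assortment without
genotypic assortment, matching the empirical observation that maternal and
paternal polygenic scores are uncorrelated. Per-parent defaults are
`δ_m = δ_p = delta_direct/√2` and `ν = beta_nurture/√2`, so the combined
standardized scores `(z_mT+z_pT)/√2` and `(z_mNT+z_pNT)/√2` carry
coefficients `delta_direct` (default 0.202) and `beta_nurture` (default
0.037) — the calibration truths for recovery studies. Mediation loadings
`a_·`, `b_·` default to 0 so the direct coefficients are also marginal;
mediation scenarios set, e.g., `a_m = 0.4, b_m = 0.092`, making the maternal
transmitted indirect effect `(a_m/√2)·b_m = 0.026`. The residual SD defaults
to the value completing unit outcome variance at baseline, so standardized
analysis coefficients estimate the generative ones directly.

Outcomes: continuous traits are affine transforms of `eta + u_family + e`
(family intercept SD 0.2); smoking and cannabis initiation are liability
thresholds at the standard-normal quantiles of prevalences 0.414 and 0.227;
pack-years = max(CPD, 0) × years smoked / 20 with years ~ U(5, 25);
current smoking quantity is generated per wave (mean ages 33.0 / 38.9 / 44.8,
baseline age SD 8.5) with age-varying coefficients
`δ(age) = δ + age_slope_T · (age − 33)` (default −0.004/year) and
`ν(age) = ν + age_slope_NT · (age − 33)` (default 0), person intercept SD
0.3, person age-slope SD 0.02, and former smokers (rate 0.05) coded 0 at all
waves. Two known departures from strict realism are intentional: continuous
outcomes are not truncated at zero (a small negative tail is tolerated so the
linear generative model is exact and recovery studies are unbiased), and
binary traits are generated by liability threshold but analyzed by mixed
logistic regression — a mild, conventional model mismatch.

`simulate_scores` is a score-level shortcut for replicate studies: each
parent's two haplotype scores are iid standard normal; an offspring's
transmitted score is their mean plus independent N(0, ½) meiotic noise, and
the non-transmitted score is the mean minus the same noise. This reproduces
the second moments of real transmission exactly (unit variances, T–NT
independence, sibling correlation ½, T + NT = parent's score) at a fraction
of the cost of the genotype pipeline.

## 2. Transmission inference (`transmission`)

Markers are cut into tiles of 150 adjacent markers per chromosome (trailing
remainders merge into the last tile; chromosomes shorter than one tile become
a single tile with a warning). For each offspring haplotype and tile, the
Hamming distance to each available parental haplotype is computed over
non-missing markers, with the denominator reduced accordingly. Tiles whose
best distance exceeds τ (default 0.1, i.e. 10% of informative markers) are
unresolved; exact ties are broken by continuity with the previous tile's
label, else unresolved. τ = 0.1 sits between the distance of the correct
haplotype under realistic phase noise (≈0) and the distance of a wrong
haplotype (≈ mean heterozygosity, ~0.35), so it separates "noisy match" from
"wrong parent".

Resolution proceeds in four steps:

1. **Parent vote.** Each offspring haplotype is assigned to the parent with
   the smaller genome-wide mismatch total. In trios, both haplotypes voting
   for the same parent is a conflict: the offspring is excluded with a
   diagnostic. In pairs, the haplotype nearer the genotyped parent is claimed
   and the other belongs to the missing parent by elimination — its
   transmitted alleles are still observed (they are the offspring's own), but
   its non-transmitted alleles are missing by construction.
2. **Within-parent labels.** Restricted to the assigned parent's two
   haplotypes, per-tile labels are re-derived with the same τ/tie rules.
3. **Painting and breakpoint refinement.** Unresolved runs flanked by
   agreeing labels inherit the consensus (a single available flank, at
   chromosome ends, is used as is). Between *differing* resolved labels —
   adjacent, or separated by an unresolved run — the crossover breakpoint is
   placed at the marker minimizing cumulative mismatches to the left label
   before it plus the right label after it, over the spanning window. This
   window-spanning refinement is deliberate: leaving disagreeing-flank runs
   missing would drop ~150 markers per mid-tile crossover and cap concordance
   near 99.7%.
4. **Hidden-segment correction.** A pair of crossovers inside one tile leaves
   its label intact while an interior segment came from the other haplotype.
   An iterated maximum-subarray scan flips the contiguous segment whose flip
   removes the most mismatches, repeating until no flip gains at least
   `min_gain` (2) informative markers — the floor prevents chasing isolated
   phase-noise mismatches. With both refinements, simulated concordance of
   non-transmitted alleles against truth is ≈99.99% on 500 trios × 5,000
   markers (validation benchmark: 99.8%).

Transmitted and non-transmitted alleles are then read off the painted source:
at every resolved marker of a genotyped parent, transmitted + non-transmitted
equals the parent's genotype dosage (asserted exhaustively in tests).
Concordance against simulated truth is reported per allele, overall and per
parent role — the per-allele reading of the benchmark rate, since resolution
is per-marker.

## 3. Scoring (`scoring`)

A weight table (marker, effect allele, weight) is aligned to the variant map;
effect alleles must match ref or alt (else an error), weight rows for unknown
markers are dropped with a warning (or rejected with `unknown="error"`), and
zero overlap is an error. A haplotype's raw score is the weight sum over
carried effect alleles; markers missing in a haplotype are skipped — no mean
imputation — with the used-marker count reported for auditability.

The four per-parent scores and their sums form the score table. The missing
non-transmitted score of an ungenotyped parent is imputed with the mean of
all observed parental non-transmitted scores (per trait), on the raw scale
before standardization; a per-role (mothers-only/fathers-only) mean is
offered as an option. The pooled-mean reading is the only definition
available within a pair, where one cannot know which parent's distribution to
match; imputing before standardization keeps the imputed value at the batch
mean (≈0 after z-scoring), which is the behavior tests assert. Imputation is
used only for the combined-score mixed models; the parent-specific path
models leave missingness in place for FIML.

Standardization follows the array-batch recipe: per batch, each score column
is regressed on the supplied ancestry covariates (none, in simulation),
residuals are z-scored to mean 0 / SD 1. Batches with fewer than 3 members
fall back to pooled-cohort statistics with a warning; a residual variance of
zero (degenerate covariate) is an error, not a silent pass-through.

## 4. Nurture and transmission models (`nurture`)

**Joint model.** Continuous outcomes: linear mixed model with a family random
intercept, REML. The default solver is a closed-form profiled REML written
for this exact model (cluster covariances are rank-one corrections of the
identity, so the GLS normal equations reduce to per-cluster sums and REML is
a one-dimensional search in the variance ratio); statsmodels' MixedLM is
available as `engine="statsmodels"` and the two agree to ~1e-6 in tests. The
closed form exists because calibration studies fit thousands of replicates.
Binary outcomes: random-intercept logistic regression maximized over a
25-node Gauss–Hermite quadrature of the cluster integral (`glmm.py`).
Family clusters have one or two members, where fixed-node quadrature of this
smoothness is accurate; no adaptive recentering is needed. Separation is
flagged by diverging coefficients. Standardized coefficients come from
z-scoring the outcome and continuous predictors before fitting (binary
covariates untouched); binomial fits report odds ratios per score SD. Wald
p-values use a normal reference — conventional for cohorts of thousands of
families, where denominator-degrees-of-freedom corrections are negligible.

**β_DGT and the nurture ratio.** `dgt` returns β_T − β_NT for continuous
outcomes and refuses binary outcomes (the subtraction is not defined across
odds ratios). `nurture_ratio` reports β_NT / β_DGT as a percentage and
refuses a zero denominator.

**FDR.** Benjamini–Hochberg step-up over the five-outcome family;
`adjust_joint_fits` adjusts the transmitted and non-transmitted columns as
two separate five-test families, which reproduces the published adjusted
column for the non-transmitted tests.

**Longitudinal model.** Current smoking quantity across waves, age centered
at the baseline mean (33.0 years), fixed effects for PGS_T, PGS_NT, age,
sex, birth year, wave, and the two PGS × age interactions estimated in one
model (hence no multiplicity adjustment). Random structure: family intercept,
person intercept, person age-slope, mutually independent (the
intercept–slope covariance is constrained to zero). The solver is a batched
profiled REML over family clusters grouped by shape; it was verified against
R's lme4 during development (agreement ~1e-6 on all coefficients and
variance components) and is checked in the test suite against an independent
dense-matrix REML implementation and against pooled OLS in the zero-variance
limit. A single wave, or constant age, is rejected as inestimable.

**Pair-vs-trio contrasts.** Welch (unequal-variance) t-tests for continuous
characteristics, Pearson chi-square (no continuity correction) for binary
ones; SMD = |Δmean| / pooled SD (continuous) or |Δp| / √(p̄(1−p̄)) (binary).
All contrasts are computed from summary statistics only, so the same code
path serves simulated cohorts and published summary tables.

## 5. Path models with FIML (`sem`)

**FIML engine.** The modeled variables (outcome, scores, mediators,
covariates) are treated as jointly multivariate normal with free means and
covariances; the observed-data likelihood sums each record's marginal normal
over its observed entries, and the moments are maximized by EM, vectorized
over missingness patterns (a handful in practice: trio, mother-pair,
father-pair). With complete data this is the sample mean and ML covariance in
one step, so FIML reduces exactly to complete-case ML — a tested invariant.
Because the path models are recursive, coefficients are closed-form functions
of the fitted moments (partitioned-covariance regressions), standardized with
model-implied SDs. Binary covariates (sex) violate normality only in their
own marginal; the regression coefficients remain consistent (quasi-ML), and
inference uses robust covariances.

**Parent-of-origin model.** Outcome on the four parent-specific scores plus
age and sex. Standard errors are sandwich estimates clustered on family:
analytic per-record scores of the moment parameters, observed information by
numerical differentiation of the total score, family-summed outer products
as the meat, and a delta-method map onto the standardized coefficients.
`wald_equality` tests equality constraints with (Δβ)ᵀV⁻¹(Δβ) against a
chi-square; its size is verified by simulation (~5% under true equality).

**Mediation.** One joint model: each parental phenotype regressed on that
parent's own T and NT scores (paths a), the outcome regressed on all four
scores, both mediators and the covariates (paths c′ and b), covariances among
parental scores and phenotypes left free (assortative mating). Indirect
effects are a × b on the standardized scale, totals are *defined* as
c′ + a × b (the identity therefore holds within every bootstrap replicate,
and is asserted there). Inference is a clustered bootstrap resampling whole
families — the same dependence unit the mixed models adjust for — with 95%
percentile CIs (default 1,000 replications; significance = CI excluding
zero). Degenerate resamples (a single family) are discarded and logged.
The multi-group variant fits all paths freely per offspring-sex group,
bootstrapping within group, and contrasts maternal-vs-paternal mediation
within groups and same-parent mediation between groups.

## 6. Power (`power`)

Power for maternal-paternal coefficient differences is simulated at the
estimate level: the two coefficient estimates are drawn from a bivariate
normal with the stated SEs and correlation (default 0, justified by the null
maternal-paternal score correlation), and the two-sided Wald equality test is
applied per replicate. The analytic normal-theory power
Φ(|Δβ|/SE_Δ − z_{1−α/2}) + Φ(−|Δβ|/SE_Δ − z_{1−α/2}) is computed alongside
and agreement within Monte Carlo error is a tested invariant.
`power_grid_from_fit` evaluates the observed contrast and its 95% CI
endpoints from a fitted parent-of-origin model. A full-pipeline power mode
(regenerating cohorts and refitting) is reachable by composing
`simulate_scores`/`simulate_cohort` with `fit_poe` in a loop, as the test
suite does at reduced replication for the Wald size check.

## 7. Problem sizes and numerical settings

Test-suite and benchmark runs use: 500 trios × 5,000 markers for transmission
concordance; 200 replicates of 6,000 families (score-level) for coefficient
recovery and CI coverage; 500 replicates of 2,000 families for the
non-transmitted type-I error; 6,000 families × 3 waves for the longitudinal
pattern; 1,000 Monte Carlo replications for power. EM converges at a relative
parameter change of 1e-8 (1e-7 inside bootstraps, warm-started from the
point estimate); the profiled-REML searches use bounded scalar minimization
(random-intercept model) and Nelder–Mead over three log variance ratios
(longitudinal model). Numerical derivatives use central differences with
step 1e-5 × max(1, |θ|).

## 8. Known limitations

* No LD in simulated founders: concordance figures certify algorithm logic,
  not performance under real LD/array noise (real phasing quality is
  upstream).
* The FIML engine covers recursive path models among observed variables —
  sufficient here by design; no latent variables, no fit indices, no
  phenotypic-assortment correction beyond free covariances.
* The mixed logistic model uses fixed-node quadrature; for clusters much
  larger than sibships an adaptive rule would be preferable.
* Generated continuous outcomes admit small negative values (no
  zero-truncation); binary traits are liability-generated but logistic-
  analyzed.
* Cross-trait (multivariate GWAS) score construction is out of scope: weight
  tables are consumed as given, so any such analysis is a configuration, not
  code.
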