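"""Genetic nurture and direct transmission models.

The central model regresses an offspring outcome jointly on the combined
transmitted score (PGS_T) and the combined non-transmitted score (PGS_NT),
with sex and age as covariates and a family random intercept for sibling
relatedness.  The transmitted coefficient mixes direct inheritance with
genetic nurture; the non-transmitted coefficient captures nurture alone, so
the direct-genetic-transmission effect is the contrast beta_DGT = beta_T -
beta_NT.  Standardized coefficients are obtained by z-scoring the outcome and
the continuous predictors before fitting (binary covariates untouched);
binary outcomes use a random-intercept logistic model and report odds ratios.

The module also provides Benjamini-Hochberg adjustment over the five-outcome
test family, the longitudinal model with PGS x age interactions (person and
family intercepts plus an orthogonal person age-slope), and descriptive
pair-vs-trio contrasts (Welch t / Pearson chi-square with standardized mean
differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import fit_logit_ri


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _sex_male(values) -> np.ndarray:
    v = pd.Series(values)
    if v.dtype == object or str(v.dtype).startswith("category"):
        return (v == "male").to_numpy(dtype=float)
    return v.to_numpy(dtype=float)


@dataclass
class JointFit:
    """Joint transmitted/non-transmitted fit for one outcome."""

    outcome: str
    family: str  # gaussian | binomial
    beta_t: float
    se_t: float
    p_t: float
    beta_nt: float
    se_nt: float
    p_nt: float
    n: int
    n_families: int
    family_var: float
    converged: bool
    p_fdr_t: float = None
    p_fdr_nt: float = None
    extra: dict = field(default_factory=dict)

    @property
    def or_t(self) -> float:
        if self.family != "binomial":
            raise AttributeError("odds ratios are reported for binomial fits only")
        return float(np.exp(self.beta_t))

    @property
    def or_nt(self) -> float:
        if self.family != "binomial":
            raise AttributeError("odds ratios are reported for binomial fits only")
        return float(np.exp(self.beta_nt))

    @property
    def beta_dgt(self) -> float:
        return dgt(self)


def fit_joint_tn(data: pd.DataFrame, outcome: str, pgs_t: str = "pgs_t_z",
                 pgs_nt: str = "pgs_nt_z", covariates=("age", "sex"),
                 family_col: str = "family_id", family: str = "gaussian",
                 engine: str = "profile") -> JointFit:
    """Mixed model of an offspring outcome on PGS_T and PGS_NT entered jointly.

    Gaussian outcomes use a linear mixed model with a family random intercept
    fit by REML; binary outcomes use a random-intercept logistic model fit by
    Gauss-Hermite quadrature.  Coefficients are standardized (the outcome and
    continuous predictors are z-scored; for binomial fits the coefficients are
    log odds ratios per SD of the score).

    ``engine`` selects the gaussian solver: ``"profile"`` (closed-form profiled
    REML, exact for this model and fast enough for replicate studies) or
    ``"statsmodels"`` (MixedLM); the two agree to optimizer tolerance.
    """
    d = data.dropna(subset=[outcome, pgs_t, pgs_nt, family_col, *covariates]).copy()
    if d[family_col].nunique() < 2:
        raise ValueError("need at least two families")
    t = _z(d[pgs_t])
    nt = _z(d[pgs_nt])
    r = np.corrcoef(t, nt)[0, 1]
    if abs(r) > 0.9999:
        raise ValueError("transmitted and non-transmitted scores are perfectly collinear")

    cols = {"pgs_t": t, "pgs_nt": nt}
    for c in covariates:
        if c == "sex":
            cols["sex_male"] = _sex_male(d[c])
        else:
            v = d[c].to_numpy(dtype=float)
            cols[c] = _z(v) if np.unique(v).size > 2 else v
    X = pd.DataFrame(cols, index=d.index)
    X.insert(0, "const", 1.0)
    groups = d[family_col].to_numpy()

    if family == "gaussian":
        y = _z(d[outcome])
        if engine == "profile":
            from .lmm import fit_lmm_ri

            res = fit_lmm_ri(y, X.to_numpy(), groups, names=list(X.columns))
            fe = pd.Series(res.params, index=X.columns)
            bse = pd.Series(res.bse, index=X.columns)
            pv = pd.Series(res.pvalues, index=X.columns)
            fam_var = res.sigma_u2
            conv = True
        elif engine == "statsmodels":
            model = sm.MixedLM(y, X, groups=groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True)
            fe = res.fe_params
            bse = res.bse_fe
            pv = pd.Series(2 * stats.norm.sf(np.abs(fe / bse)), index=fe.index)
            fam_var = float(np.asarray(res.cov_re)[0, 0])
            conv = bool(res.converged)
        else:
            raise ValueError("engine must be 'profile' or 'statsmodels'")
        beta_t, se_t, p_t = float(fe["pgs_t"]), float(bse["pgs_t"]), float(pv["pgs_t"])
        beta_nt, se_nt, p_nt = float(fe["pgs_nt"]), float(bse["pgs_nt"]), float(pv["pgs_nt"])
        extra = {"result": res}
    elif family == "binomial":
        y = d[outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial outcome must be 0/1")
        res = fit_logit_ri(y, X.to_numpy(), groups, names=list(X.columns))
        k_t, k_nt = X.columns.get_loc("pgs_t"), X.columns.get_loc("pgs_nt")
        beta_t, se_t, p_t = float(res.params[k_t]), float(res.bse[k_t]), float(res.pvalues[k_t])
        beta_nt, se_nt, p_nt = float(res.params[k_nt]), float(res.bse[k_nt]), float(res.pvalues[k_nt])
        fam_var = float(res.sigma_u**2)
        conv = res.converged
        extra = {"result": res}
    else:
        raise ValueError("family must be 'gaussian' or 'binomial'")

    return JointFit(
        outcome=outcome,
        family=family,
        beta_t=beta_t,
        se_t=se_t,
        p_t=p_t,
        beta_nt=beta_nt,
        se_nt=se_nt,
        p_nt=p_nt,
        n=len(d),
        n_families=int(pd.Series(groups).nunique()),
        family_var=fam_var,
        converged=conv,
        extra=extra,
    )


def dgt(fit: JointFit) -> float:
    """Direct genetic transmission: beta_T - beta_NT (continuous outcomes only)."""
    if fit.family != "gaussian":
        raise ValueError("the DGT contrast is reported for continuous outcomes only")
    return fit.beta_t - fit.beta_nt


def nurture_ratio(fit: JointFit) -> float:
    """Genetic nurture as a percentage of direct genetic transmission."""
    d = dgt(fit)
    if abs(d) < 1e-10:
        raise ValueError("nurture ratio undefined: beta_DGT is zero")
    return 100.0 * fit.beta_nt / d


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_joint_fits(fits) -> list:
    """Apply BH-FDR across a family of joint fits, T and NT columns separately."""
    fits = list(fits)
    for attr, target in (("p_t", "p_fdr_t"), ("p_nt", "p_fdr_nt")):
        adj = fdr_adjust([getattr(f, attr) for f in fits])
        for f, a in zip(fits, adj):
            setattr(f, target, float(a))
    return fits


# ---------------------------------------------------------------------------
# longitudinal model


@dataclass
class LongitudinalFit:
    coefficients: pd.DataFrame  # index term; columns beta, se, p
    person_var: float
    family_var: float
    slope_var: float
    n_obs: int
    n_persons: int
    n_families: int
    converged: bool
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> tuple:
        row = self.coefficients.loc[name]
        return float(row["beta"]), float(row["se"]), float(row["p"])


def fit_longitudinal(data: pd.DataFrame, outcome: str = "current_cpd",
                     pgs_t: str = "pgs_t_z", pgs_nt: str = "pgs_nt_z",
                     person_col: str = "individual_id", family_col: str = "family_id",
                     age_col: str = "age", wave_col: str = "wave",
                     baseline_age: float = 33.0, engine: str = "profile") -> LongitudinalFit:
    """Linear mixed model of repeated outcomes with PGS x age interactions.

    Age is centered at the baseline mean so main PGS effects are the effects at
    baseline age and the interactions are per-year changes.  Random structure:
    family intercept, person intercept, and a person age-slope orthogonal to
    the intercept (independent variance components).  Covariates: sex, birth
    year, and measurement wave.  Both interactions sit in one model, so no
    multiplicity adjustment is applied to them.
    """
    need = [outcome, pgs_t, pgs_nt, person_col, family_col, age_col, wave_col, "sex", "birth_year"]
    d = data.dropna(subset=need).copy()
    if d[wave_col].nunique() < 2:
        raise ValueError("PGS x age interactions need at least two waves")
    if d[age_col].std() < 1e-9:
        raise ValueError("no variance in age: interaction design is singular")

    y = _z(d[outcome])
    t = _z(d[pgs_t])
    nt = _z(d[pgs_nt])
    age_c = d[age_col].to_numpy(dtype=float) - baseline_age
    X = pd.DataFrame(
        {
            "const": 1.0,
            "pgs_t": t,
            "pgs_nt": nt,
            "age": age_c,
            "sex_male": _sex_male(d["sex"]),
            "birth_year": _z(d["birth_year"]),
            "pgs_t_x_age": t * age_c,
            "pgs_nt_x_age": nt * age_c,
        },
        index=d.index,
    )
    for w in sorted(d[wave_col].unique())[1:]:
        X[f"wave_{w}"] = (d[wave_col] == w).astype(float)

    # sort by family so variance-component designs align with the groups
    order = np.argsort(d[family_col].to_numpy(), kind="stable")
    d = d.iloc[order]
    X = X.iloc[order]
    y = y[order]
    groups = d[family_col].to_numpy()
    persons = d[person_col].to_numpy()
    age_sorted = d[age_col].to_numpy(dtype=float) - baseline_age

    if engine != "profile":
        raise ValueError("only the 'profile' engine is available for the longitudinal model")
    from .lmm import fit_lmm_longitudinal

    res = fit_lmm_longitudinal(y, X.to_numpy(), groups, persons, age_sorted,
                               names=list(X.columns))
    coefs = pd.DataFrame({"beta": res.params, "se": res.bse, "p": res.pvalues},
                         index=X.columns)
    person_var, family_var, slope_var = res.person_var, res.family_var, res.slope_var
    converged = res.converged

    return LongitudinalFit(
        coefficients=coefs,
        person_var=float(person_var),
        family_var=float(family_var),
        slope_var=float(slope_var),
        n_obs=len(d),
        n_persons=int(pd.Series(persons).nunique()),
        n_families=int(pd.Series(groups).nunique()),
        converged=converged,
        extra={"result": res},
    )


# ---------------------------------------------------------------------------
# pair-vs-trio descriptive contrasts


def _welch_from_stats(m1, s1, n1, m2, s2, n2):
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    smd = abs(m1 - m2) / pooled if pooled > 0 else 0.0
    return float(t), float(p), float(smd)


def _chi2_from_counts(k1, n1, k2, n2):
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.min() < 0 or n1 == 0 or n2 == 0:
        raise ValueError("invalid 2x2 counts")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    p1, p2 = k1 / n1, k2 / n2
    pbar = (k1 + k2) / (n1 + n2)
    denom = np.sqrt(pbar * (1 - pbar))
    smd = abs(p1 - p2) / denom if denom > 0 else 0.0
    return float(chi2), float(p), float(smd)


def contrasts_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pair-vs-trio contrasts from printed summary statistics only.

    Expects the column layout of :data:`hapnurture.published.COHORT_DESCRIPTIVES`:
    continuous rows with (n, mean, sd) per group, binary rows with (n, count).
    """
    rows = []
    for _, r in summaries.iterrows():
        if r["kind"] == "continuous":
            stat, p, smd = _welch_from_stats(
                r["mean_pair"], r["sd_pair"], r["n_pair"],
                r["mean_trio"], r["sd_trio"], r["n_trio"],
            )
            test = "welch_t"
        else:
            stat, p, smd = _chi2_from_counts(
                int(r["count_pair"]), int(r["n_pair"]), int(r["count_trio"]), int(r["n_trio"])
            )
            test = "chi2"
        rows.append(
            {"characteristic": r["characteristic"], "test": test,
             "statistic": stat, "p": p, "smd": smd}
        )
    return pd.DataFrame(rows)


DEFAULT_CHARACTERISTICS = (
    ("age", "continuous"),
    ("female", "binary"),
    ("smoking_initiation", "binary"),
    ("cpd", "continuous"),
    ("pack_years", "continuous"),
    ("alcohol_g_day", "continuous"),
    ("cannabis_initiation", "binary"),
)


def subsample_contrasts(phenotypes: pd.DataFrame, pedigree: pd.DataFrame,
                        characteristics=DEFAULT_CHARACTERISTICS,
                        wave: int = 1) -> pd.DataFrame:
    """Compare offspring from pairs vs trios on baseline characteristics.

    Families with both parents genotyped are trios; with exactly one, pairs.
    Continuous characteristics use a Welch t-test, binary ones a Pearson
    chi-square, each with an absolute standardized mean difference.
    """
    parents = pedigree[pedigree["role"].isin(["mother", "father"])]
    n_geno = parents.groupby("family_id")["genotyped"].sum()
    group = n_geno.map({2: "trio", 1: "pair"})
    d = phenotypes[phenotypes["wave"] == wave].copy()
    d["subsample"] = d["family_id"].map(group)
    d = d.dropna(subset=["subsample"])
    if "female" in [c for c, _ in characteristics] and "female" not in d:
        d["female"] = (d["sex"] == "female").astype(int)

    summaries = []
    for name, kind in characteristics:
        a = d.loc[d["subsample"] == "pair", name].dropna()
        b = d.loc[d["subsample"] == "trio", name].dropna()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty subsample for characteristic {name!r}")
        if kind == "continuous":
            summaries.append(
                {"characteristic": name, "kind": kind,
                 "n_pair": len(a), "mean_pair": a.mean(), "sd_pair": a.std(ddof=1),
                 "n_trio": len(b), "mean_trio": b.mean(), "sd_trio": b.std(ddof=1)}
            )
        else:
            summaries.append(
                {"characteristic": name, "kind": kind,
                 "n_pair": len(a), "count_pair": int(a.sum()),
                 "n_trio": len(b), "count_trio": int(b.sum())}
            )
    return contrasts_from_summaries(pd.DataFrame(summaries))
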