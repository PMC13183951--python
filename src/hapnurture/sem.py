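"""Parent-of-origin path models and mediation through parental phenotypes.

Missing parental scores (pairs) are handled with full-information maximum
likelihood: the joint distribution of the modeled variables is taken to be
multivariate normal with free means and covariances, the likelihood is
accumulated pattern-wise over the observed entries of each record, and the
moments are maximized by EM.  Path coefficients are then exact functions of
the fitted moments (the models are recursive), standardized with the
model-implied standard deviations.  Binary covariates enter the joint model
as regressors; their own distribution is quasi-likelihood only, which leaves
the regression coefficients consistent and is covered by the robust
(sandwich) covariance, clustered on family, used for Wald inference in the
parent-of-origin model.  Mediation inference uses a clustered bootstrap that
resamples whole families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# FIML moments by EM


def _pattern_groups(mask: np.ndarray):
    """Group row indices by observed-variable pattern (mask True = observed)."""
    d = mask.shape[1]
    key = mask @ (1 << np.arange(d, dtype=np.int64))
    out = []
    for k in np.unique(key):
        rows = np.nonzero(key == k)[0]
        out.append((np.nonzero(mask[rows[0]])[0], rows))
    return out


def fiml_loglik(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Observed-data log-likelihood of the saturated MVN model."""
    total = 0.0
    for obs, rows in _pattern_groups(~np.isnan(X)):
        if obs.size == 0:
            continue
        S = Sigma[np.ix_(obs, obs)]
        r = X[np.ix_(rows, obs)] - mu[obs]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf
        sol = np.linalg.solve(S, r.T)
        quad = np.einsum("ij,ji->i", r, sol)
        total += -0.5 * rows.size * (obs.size * np.log(2 * np.pi) + logdet) - 0.5 * quad.sum()
    return float(total)


def fiml_mvn(X: np.ndarray, max_iter: int = 500, tol: float = 1e-8,
             start=None) -> tuple:
    """EM estimates of the MVN mean and covariance under arbitrary missingness.

    Returns ``(mu, Sigma, info)``.  With complete data this is the sample mean
    and (ML, divide-by-n) covariance in a single step.  Rows that are entirely
    missing are dropped.
    """
    X = np.asarray(X, dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n, d = X.shape
    if n < d + 1:
        raise ValueError("too few records for a full covariance")
    fully_missing_col = np.isnan(X).all(axis=0)
    if fully_missing_col.any():
        raise ValueError("a variable is entirely missing")

    mask = ~np.isnan(X)
    if mask.all():
        mu = X.mean(axis=0)
        Sigma = np.cov(X, rowvar=False, ddof=0)
        return mu, np.atleast_2d(Sigma), {"n_iter": 0, "converged": True, "n": n,
                                          "loglik": fiml_loglik(X, mu, np.atleast_2d(Sigma))}

    if start is not None:
        mu, Sigma = start[0].copy(), start[1].copy()
    else:
        mu = np.nanmean(X, axis=0)
        Xc = np.where(mask, X - mu, 0.0)
        counts = mask.T.astype(float) @ mask.astype(float)
        Sigma = (Xc.T @ Xc) / np.maximum(counts, 1.0)
        # guard against non-PSD pairwise start
        w, V = np.linalg.eigh(Sigma)
        Sigma = (V * np.clip(w, 1e-6 * max(w.max(), 1e-12), None)) @ V.T

    patterns = _pattern_groups(mask)
    prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S1 = np.zeros(d)
        S2 = np.zeros((d, d))
        for obs, rows in patterns:
            miss = np.setdiff1d(np.arange(d), obs, assume_unique=True)
            Xo = X[np.ix_(rows, obs)]
            if miss.size == 0:
                S1[obs] += Xo.sum(axis=0)
                S2[np.ix_(obs, obs)] += Xo.T @ Xo
                continue
            Soo = Sigma[np.ix_(obs, obs)]
            B = np.linalg.solve(Soo, Sigma[np.ix_(obs, miss)]).T  # (|miss|, |obs|)
            cm = mu[miss] + (Xo - mu[obs]) @ B.T
            cc = Sigma[np.ix_(miss, miss)] - B @ Sigma[np.ix_(obs, miss)]
            Xc = np.empty((rows.size, d))
            Xc[:, obs] = Xo
            Xc[:, miss] = cm
            S1 += Xc.sum(axis=0)
            S2 += Xc.T @ Xc
            S2[np.ix_(miss, miss)] += rows.size * cc
        mu = S1 / n
        Sigma = S2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        cur = np.concatenate([mu, Sigma.ravel()])
        if prev is not None and np.max(np.abs(cur - prev)) < tol * max(1.0, np.max(np.abs(cur))):
            converged = True
            break
        prev = cur
    return mu, Sigma, {"n_iter": it, "converged": converged, "n": n,
                       "loglik": fiml_loglik(X, mu, Sigma)}


# ---------------------------------------------------------------------------
# sandwich machinery for moment parameters


def _vech_indices(d: int):
    return np.tril_indices(d)


def _pack(mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    i, j = _vech_indices(mu.size)
    return np.concatenate([mu, Sigma[i, j]])


def _unpack(theta: np.ndarray, d: int):
    mu = theta[:d]
    S = np.zeros((d, d))
    i, j = _vech_indices(d)
    S[i, j] = theta[d:]
    S[j, i] = theta[d:]
    return mu, S


def _mvn_scores(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Per-record score of the observed-data MVN log-likelihood wrt (mu, vech Sigma)."""
    n, d = X.shape
    i_l, j_l = _vech_indices(d)
    p = d + i_l.size
    out = np.zeros((n, p))
    for obs, rows in _pattern_groups(~np.isnan(X)):
        if obs.size == 0:
            continue
        P = np.linalg.inv(Sigma[np.ix_(obs, obs)])
        r = X[np.ix_(rows, obs)] - mu[obs]
        rP = r @ P
        out[np.ix_(rows, obs)] = rP
        G = 0.5 * (rP[:, :, None] * rP[:, None, :] - P[None, :, :])
        # map the symmetric-derivative block into vech coordinates
        full = np.zeros((rows.size, d, d))
        full[np.ix_(np.arange(rows.size), obs, obs)] = G
        mult = np.where(i_l == j_l, 1.0, 2.0)
        out[rows, d:] = full[:, i_l, j_l] * mult
    return out


def _sandwich_cov(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray,
                  families: np.ndarray) -> np.ndarray:
    """Family-clustered sandwich covariance of the moment parameters."""
    d = mu.size
    theta = _pack(mu, Sigma)
    p = theta.size

    def total_score(th):
        m, S = _unpack(th, d)
        return _mvn_scores(X, m, S).sum(axis=0)

    J = np.zeros((p, p))
    for k in range(p):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (total_score(tp) - total_score(tm)) / (2 * h)
    H = -0.5 * (J + J.T)  # observed information, symmetrized

    scores = _mvn_scores(X, mu, Sigma)
    fam = pd.Series(families).astype("category").cat.codes.to_numpy()
    nfam = fam.max() + 1
    G = np.zeros((nfam, p))
    np.add.at(G, fam, scores)
    M = G.T @ G
    Hinv = np.linalg.pinv(H)
    V = Hinv @ M @ Hinv
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# parent-of-origin model


@dataclass
class PoeFit:
    """Regression of an outcome on the four parent-specific scores (FIML)."""

    outcome: str
    names: list  # the four score names in model order
    beta: np.ndarray  # standardized coefficients
    se: np.ndarray  # cluster-robust
    cov: np.ndarray  # robust covariance of the standardized coefficients
    beta_raw: np.ndarray
    covariate_beta: dict
    score_cov: pd.DataFrame  # model-implied covariance among the four scores
    mu: np.ndarray
    Sigma: np.ndarray
    n: int
    n_families: int
    loglik: float
    converged: bool

    @property
    def ci(self) -> pd.DataFrame:
        lo = self.beta - 1.96 * self.se
        hi = self.beta + 1.96 * self.se
        p = 2 * stats.norm.sf(np.abs(self.beta / self.se))
        return pd.DataFrame({"beta": self.beta, "se": self.se, "lo": lo, "hi": hi, "p": p},
                            index=self.names)


def _regression_from_moments(Sigma: np.ndarray, y: int, xs) -> np.ndarray:
    xs = np.asarray(xs)
    return np.linalg.solve(Sigma[np.ix_(xs, xs)], Sigma[xs, y])


POE_SCORE_NAMES = ["maternal_t", "maternal_nt", "paternal_t", "paternal_nt"]


def fit_poe(data: pd.DataFrame, outcome: str,
            scores=("pgs_t_maternal_z", "pgs_nt_maternal_z", "pgs_t_paternal_z", "pgs_nt_paternal_z"),
            covariates=("age", "sex"), family_col: str = "family_id",
            robust: bool = True) -> PoeFit:
    """Joint FIML regression of an offspring outcome on four parental scores.

    Records missing one parent's non-transmitted score (pairs) contribute
    through their observed entries; standard errors are sandwich estimates
    clustered on family.  Coefficients are standardized with the model-implied
    standard deviations.
    """
    cols = [outcome, *scores]
    d = data.copy()
    cov_cols = []
    for c in covariates:
        if c == "sex":
            d["_sex_male"] = (d[c] == "male").astype(float) if d[c].dtype == object else d[c]
            cov_cols.append("_sex_male")
        else:
            cov_cols.append(c)
    d = d.dropna(subset=[family_col, *cov_cols])
    X = d[cols + cov_cols].to_numpy(dtype=float)
    for k, c in enumerate(cols):
        if np.isnan(X[:, k]).all():
            raise ValueError(f"column {c!r} is entirely missing")
    score_obs = ~np.isnan(X[:, 1:5])
    if (~score_obs.any(axis=1)).any():
        raise ValueError("records with no observed parental scores")

    mu, Sigma, info = fiml_mvn(X)
    nx = len(cols) + len(cov_cols)
    xs = np.arange(1, nx)
    beta_all = _regression_from_moments(Sigma, 0, xs)
    sd = np.sqrt(np.diag(Sigma))

    def std_beta(theta):
        m, S = _unpack(theta, nx)
        b = _regression_from_moments(S, 0, xs)
        s = np.sqrt(np.clip(np.diag(S), 1e-12, None))
        return b[:4] * s[1:5] / s[0]

    theta = _pack(mu, Sigma)
    beta_std = std_beta(theta)

    if robust:
        V_theta = _sandwich_cov(X, mu, Sigma, d[family_col].to_numpy())
        Jf = np.zeros((4, theta.size))
        for k in range(theta.size):
            h = 1e-5 * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            Jf[:, k] = (std_beta(tp) - std_beta(tm)) / (2 * h)
        V = Jf @ V_theta @ Jf.T
    else:
        V = np.full((4, 4), np.nan)

    score_cov = pd.DataFrame(Sigma[1:5, 1:5], index=POE_SCORE_NAMES, columns=POE_SCORE_NAMES)
    return PoeFit(
        outcome=outcome,
        names=POE_SCORE_NAMES,
        beta=beta_std,
        se=np.sqrt(np.clip(np.diag(V), 0, None)),
        cov=V,
        beta_raw=beta_all[:4],
        covariate_beta=dict(zip(cov_cols, beta_all[4:])),
        score_cov=score_cov,
        mu=mu,
        Sigma=Sigma,
        n=info["n"],
        n_families=int(d[family_col].nunique()),
        loglik=info["loglik"],
        converged=info["converged"],
    )


def wald_equality(fit: PoeFit, constraints=(("maternal_t", "paternal_t"),)) -> tuple:
    """Wald chi-square for equality of standardized coefficients.

    ``constraints`` is a sequence of (name_a, name_b) pairs tested jointly;
    returns ``(delta_chi2, df, p)`` using the cluster-robust covariance.
    """
    L = np.zeros((len(constraints), len(fit.names)))
    for r, (a, b) in enumerate(constraints):
        L[r, fit.names.index(a)] = 1.0
        L[r, fit.names.index(b)] = -1.0
    delta = L @ fit.beta
    V = L @ fit.cov @ L.T
    if np.linalg.matrix_rank(V) < L.shape[0]:
        raise ValueError("singular contrast covariance")
    chi2 = float(delta @ np.linalg.solve(V, delta))
    df = L.shape[0]
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# mediation through parental phenotypes


MEDIATION_PATHS = [
    ("maternal", "t"),
    ("maternal", "nt"),
    ("paternal", "t"),
    ("paternal", "nt"),
]


def _mediation_paths(Sigma: np.ndarray, n_cov: int) -> pd.DataFrame:
    """Standardized paths from the joint moments.

    Variable order: y, s_mt, s_mnt, s_pt, s_pnt, med_m, med_p, covariates.
    Each parental phenotype is regressed on that parent's own scores; the
    outcome equation conditions on all four scores, both mediators and the
    covariates.  Indirect = a x b; total = c' + indirect by definition.
    """
    sd = np.sqrt(np.clip(np.diag(Sigma), 1e-12, None))
    a_m = _regression_from_moments(Sigma, 5, [1, 2])
    a_p = _regression_from_moments(Sigma, 6, [3, 4])
    xs = list(range(1, 7 + n_cov))
    by = _regression_from_moments(Sigma, 0, xs)
    cprime = {(p, t): by[k] for k, (p, t) in enumerate(MEDIATION_PATHS)}
    b_m, b_p = by[4], by[5]

    rows = []
    score_idx = {("maternal", "t"): 1, ("maternal", "nt"): 2, ("paternal", "t"): 3, ("paternal", "nt"): 4}
    a_map = {("maternal", "t"): a_m[0], ("maternal", "nt"): a_m[1],
             ("paternal", "t"): a_p[0], ("paternal", "nt"): a_p[1]}
    med_idx = {"maternal": 5, "paternal": 6}
    b_map = {"maternal": b_m, "paternal": b_p}
    for parent, st in MEDIATION_PATHS:
        si = score_idx[(parent, st)]
        mi = med_idx[parent]
        a_std = a_map[(parent, st)] * sd[si] / sd[mi]
        b_std = b_map[parent] * sd[mi] / sd[0]
        c_std = cprime[(parent, st)] * sd[si] / sd[0]
        rows.append(
            {"parent": parent, "score": st, "a": a_std, "b": b_std, "cprime": c_std,
             "indirect": a_std * b_std, "total": c_std + a_std * b_std}
        )
    return pd.DataFrame(rows).set_index(["parent", "score"])


@dataclass
class MediationResult:
    paths: pd.DataFrame  # standardized a, b, c', indirect, total per (parent, score)
    ci: pd.DataFrame  # percentile bootstrap CIs and significance flags
    contrasts: pd.DataFrame  # maternal - paternal indirect, per score type
    mediator_cov: float  # model-implied covariance of the two parental phenotypes
    score_cov: pd.DataFrame
    n: int
    n_families: int
    n_boot: int
    seed: int
    boot: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    between: pd.DataFrame = None  # between-group contrasts (multi-group models)
    n_discarded: int = 0


def _prepare_mediation_matrix(data, outcome, scores, mediators, covariates, family_col):
    d = data.copy()
    cov_cols = []
    for c in covariates:
        if c == "sex":
            d["_sex_male"] = (d[c] == "male").astype(float) if d[c].dtype == object else d[c]
            cov_cols.append("_sex_male")
        else:
            cov_cols.append(c)
    d = d.dropna(subset=[family_col, *cov_cols])
    cols = [outcome, *scores, *mediators, *cov_cols]
    X = d[cols].to_numpy(dtype=float)
    return X, d[family_col].to_numpy(), len(cov_cols)


def _boot_paths(X, fams, n_cov, n_boot, rng, start):
    """Clustered bootstrap: resample whole families, refit, recompute paths."""
    labels, inv = np.unique(fams, return_inverse=True)
    members = [[] for _ in labels]
    for row, g in enumerate(inv):
        members[g].append(row)
    members = [np.array(m) for m in members]
    draws_ind = np.empty((n_boot, 4))
    draws_tot = np.empty((n_boot, 4))
    draws_c = np.empty((n_boot, 4))
    discarded = 0
    for b in range(n_boot):
        pick = rng.integers(0, len(labels), len(labels))
        if np.unique(pick).size < 2:
            draws_ind[b] = np.nan
            draws_tot[b] = np.nan
            draws_c[b] = np.nan
            discarded += 1
            continue
        idx = np.concatenate([members[g] for g in pick])
        _, Sigma_b, _ = fiml_mvn(X[idx], max_iter=200, tol=1e-7, start=start)
        p = _mediation_paths(Sigma_b, n_cov)
        draws_ind[b] = p["indirect"].to_numpy()
        draws_tot[b] = p["total"].to_numpy()
        draws_c[b] = p["cprime"].to_numpy()
    return draws_ind, draws_tot, draws_c, discarded


def fit_mediation(data: pd.DataFrame, outcome: str,
                  scores=("pgs_t_maternal_z", "pgs_nt_maternal_z", "pgs_t_paternal_z", "pgs_nt_paternal_z"),
                  mediators=("maternal_cpd", "paternal_cpd"),
                  covariates=("age", "sex"), family_col: str = "family_id",
                  n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Joint mediation model: parental scores -> parental phenotype -> offspring outcome.

    One path model estimates both parents' transmitted and non-transmitted
    mediation simultaneously, with free covariances among parental scores and
    phenotypes (assortative mating).  Indirect effects (a x b) and their
    maternal-vs-paternal contrasts get 95% percentile CIs from a clustered
    bootstrap that resamples families; significance = CI excluding zero.
    """
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replications gives unstable CIs")
    X, fams, n_cov = _prepare_mediation_matrix(data, outcome, scores, mediators, covariates, family_col)
    mu, Sigma, info = fiml_mvn(X)
    paths = _mediation_paths(Sigma, n_cov)

    rng = np.random.default_rng(seed)
    d_ind, d_tot, d_c, discarded = _boot_paths(X, fams, n_cov, n_boot, rng, (mu, Sigma))
    if discarded:
        warnings.warn(f"{discarded} degenerate bootstrap replicates discarded")

    def pct(a, axis=0):
        return np.nanpercentile(a, [2.5, 97.5], axis=axis)

    lo_i, hi_i = pct(d_ind)
    lo_t, hi_t = pct(d_tot)
    ci = paths.copy()
    ci["indirect_lo"], ci["indirect_hi"] = lo_i, hi_i
    ci["total_lo"], ci["total_hi"] = lo_t, hi_t
    ci["significant"] = (lo_i > 0) | (hi_i < 0)

    # maternal - paternal contrast of indirect effects per score type
    con_rows = []
    con_boot = {}
    for st, im, ip in (("t", 0, 2), ("nt", 1, 3)):
        est = paths.loc[("maternal", st), "indirect"] - paths.loc[("paternal", st), "indirect"]
        draws = d_ind[:, im] - d_ind[:, ip]
        lo, hi = np.nanpercentile(draws, [2.5, 97.5])
        con_rows.append({"score": st, "delta_indirect": est, "lo": lo, "hi": hi,
                         "significant": (lo > 0) | (hi < 0)})
        con_boot[st] = draws
    contrasts = pd.DataFrame(con_rows).set_index("score")

    return MediationResult(
        paths=paths,
        ci=ci,
        contrasts=contrasts,
        mediator_cov=float(Sigma[5, 6] - Sigma[5, 1:5] @ np.linalg.solve(Sigma[1:5, 1:5], Sigma[1:5, 6])),
        score_cov=pd.DataFrame(Sigma[1:5, 1:5], index=POE_SCORE_NAMES, columns=POE_SCORE_NAMES),
        n=info["n"],
        n_families=int(pd.Series(fams).nunique()),
        n_boot=n_boot,
        seed=seed,
        boot={"indirect": d_ind, "total": d_tot, "cprime": d_c, "contrast": con_boot},
        n_discarded=discarded,
    )


def multigroup_mediation(data: pd.DataFrame, outcome: str, group_col: str = "sex",
                         scores=("pgs_t_maternal_z", "pgs_nt_maternal_z", "pgs_t_paternal_z", "pgs_nt_paternal_z"),
                         mediators=("maternal_cpd", "paternal_cpd"),
                         covariates=("age",), family_col: str = "family_id",
                         n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Multi-group mediation with all paths free across groups (e.g. offspring sex).

    Produces per-group mediation results (within-group maternal-vs-paternal
    contrasts) and between-group contrasts of the same parent's indirect
    effect, with CIs from bootstraps run independently within each group.
    The grouping variable must not also appear among the covariates.
    """
    groups = {}
    levels = [g for g in pd.unique(data[group_col]) if pd.notna(g)]
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    child_seeds = np.random.SeedSequence(seed).spawn(len(levels))
    for g, ss in zip(levels, child_seeds):
        sub = data[data[group_col] == g]
        if sub[family_col].nunique() < 50:
            warnings.warn(f"group {g!r} has fewer than 50 families; contrasts will be underpowered")
        groups[g] = fit_mediation(
            sub, outcome, scores=scores, mediators=mediators, covariates=covariates,
            family_col=family_col, n_boot=n_boot, seed=int(ss.generate_state(1)[0] % (2**31)),
        )

    rows = []
    for k, (parent, st) in enumerate(MEDIATION_PATHS):
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                g1, g2 = levels[i], levels[j]
                est = (groups[g1].paths.loc[(parent, st), "indirect"]
                       - groups[g2].paths.loc[(parent, st), "indirect"])
                draws = groups[g1].boot["indirect"][:, k] - groups[g2].boot["indirect"][:, k]
                lo, hi = np.nanpercentile(draws, [2.5, 97.5])
                rows.append({"parent": parent, "score": st, "group_a": g1, "group_b": g2,
                             "delta_indirect": est, "lo": lo, "hi": hi,
                             "significant": (lo > 0) | (hi < 0)})
    between = pd.DataFrame(rows)

    ref = groups[levels[0]]
    return MediationResult(
        paths=pd.concat({g: r.paths for g, r in groups.items()}, names=[group_col]),
        ci=pd.concat({g: r.ci for g, r in groups.items()}, names=[group_col]),
        contrasts=pd.concat({g: r.contrasts for g, r in groups.items()}, names=[group_col]),
        mediator_cov=ref.mediator_cov,
        score_cov=ref.score_cov,
        n=sum(r.n for r in groups.values()),
        n_families=sum(r.n_families for r in groups.values()),
        n_boot=n_boot,
        seed=seed,
        groups=groups,
        between=between,
    )
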