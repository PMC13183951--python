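"""Profiled REML for the random-intercept linear mixed model.

For y = X b + u_g + e with a single cluster intercept, the GLS solution and
the REML criterion are closed-form given the variance ratio rho = sigma_u^2 /
sigma_e^2: cluster covariance inverses reduce to rank-one corrections of the
identity, so everything is computable from per-cluster sums.  Profiling b and
sigma_e^2 leaves a one-dimensional REML optimization in log rho.  This is the
same estimator statsmodels' MixedLM computes for this model (the two are
cross-checked in the test suite); the closed form is used where thousands of
fits are needed (replicate calibration studies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm


@dataclass
class LMMRIResult:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma_e2: float
    sigma_u2: float
    names: list
    n_obs: int
    n_groups: int
    reml: bool

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * norm.sf(np.abs(self.params / self.bse))


def fit_lmm_ri(y, X, groups, names=None, reml: bool = True) -> LMMRIResult:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    g = np.asarray(groups)
    order = np.argsort(g, kind="stable")
    y, X, g = y[order], X[order], g[order]
    starts = np.concatenate([[0], np.nonzero(g[1:] != g[:-1])[0] + 1])
    sizes = np.diff(np.append(starts, y.size)).astype(float)
    N, p = X.shape
    G = starts.size

    Sx = np.add.reduceat(X, starts, axis=0)  # (G, p) per-cluster sums
    Sy = np.add.reduceat(y, starts)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(rho):
        w = rho / (1.0 + sizes * rho)  # per-cluster rank-one weight
        A = XtX - (Sx * w[:, None]).T @ Sx  # X' Vtilde^-1 X
        c = Xty - (Sx * (w * Sy)[:, None]).sum(axis=0)
        q = yty - float(w @ (Sy * Sy))
        b = np.linalg.solve(A, c)
        rss = q - float(b @ c)
        return A, b, rss, w

    def crit(log_rho):
        rho = np.exp(log_rho)
        A, b, rss, _ = pieces(rho)
        dof = N - p if reml else N
        sigma2 = max(rss / dof, 1e-12)
        out = dof * np.log(sigma2) + np.sum(np.log1p(sizes * rho))
        if reml:
            sign, logdetA = np.linalg.slogdet(A)
            out += logdetA
        return 0.5 * out

    res = minimize_scalar(crit, bounds=(-12.0, 6.0), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(np.exp(res.x))
    # compare against the boundary (no cluster variance)
    if crit(np.log(1e-12)) < res.fun:
        rho = 0.0
    A, b, rss, _ = pieces(rho)
    dof = N - p if reml else N
    sigma2 = rss / dof
    cov = np.linalg.inv(A) * sigma2
    return LMMRIResult(
        params=b,
        bse=np.sqrt(np.diag(cov)),
        cov_params=cov,
        sigma_e2=float(sigma2),
        sigma_u2=float(rho * sigma2),
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        n_obs=int(N),
        n_groups=int(G),
        reml=reml,
    )


@dataclass
class LMMLongResult:
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma_e2: float
    family_var: float
    person_var: float
    slope_var: float
    names: list
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * norm.sf(np.abs(self.params / self.bse))


def fit_lmm_longitudinal(y, X, family, person, age_c, names=None) -> LMMLongResult:
    """Profiled REML for the three-component longitudinal model.

    Random structure: family intercept, person intercept, person age-slope,
    all mutually independent (the slope is orthogonal to the intercept).
    Clusters (families) are batched by identical shape so the per-cluster
    covariance algebra is vectorized; the residual variance is profiled out,
    leaving a 3-parameter REML optimization over the variance ratios.
    Cross-checked against statsmodels MixedLM in the test suite.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    fam = np.asarray(family)
    per = np.asarray(person)
    a = np.asarray(age_c, float)
    order = np.argsort(fam, kind="stable")
    y, X, fam, per, a = y[order], X[order], fam[order], per[order], a[order]
    starts = np.concatenate([[0], np.nonzero(fam[1:] != fam[:-1])[0] + 1])
    bounds = np.append(starts, y.size)
    N, p = X.shape
    G = starts.size

    # batch families by (n_obs, n_persons)
    batches = {}
    for k in range(G):
        s, e = bounds[k], bounds[k + 1]
        pid, inv = np.unique(per[s:e], return_inverse=True)
        key = (e - s, pid.size)
        D = np.zeros((e - s, pid.size))
        D[np.arange(e - s), inv] = 1.0
        batches.setdefault(key, []).append((slice(s, e), D))

    packed = []
    for (nobs, nper), items in batches.items():
        Xb = np.stack([X[sl] for sl, _ in items])
        yb = np.stack([y[sl] for sl, _ in items])
        Db = np.stack([D for _, D in items])
        Ab = np.stack([D * a[sl][:, None] for sl, D in items])
        J = np.ones((nobs, nobs))
        P = Db @ Db.transpose(0, 2, 1)
        S = Ab @ Ab.transpose(0, 2, 1)
        packed.append((Xb, yb, J, P, S, nobs))

    eye_cache = {nobs: np.eye(nobs) for *_, nobs in packed}

    def assemble(gam):
        gf, gp, gs = gam
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ytWy = 0.0
        logdet = 0.0
        for Xb, yb, J, P, S, nobs in packed:
            W = eye_cache[nobs][None] + gf * J[None] + gp * P + gs * S
            sign, ld = np.linalg.slogdet(W)
            if np.any(sign <= 0):
                return None
            logdet += ld.sum()
            Wi = np.linalg.inv(W)
            WiX = Wi @ Xb
            Wiy = np.einsum("gij,gj->gi", Wi, yb)
            XtWX += np.einsum("gip,giq->pq", Xb, WiX)
            XtWy += np.einsum("gip,gi->p", Xb, Wiy)
            ytWy += float(np.einsum("gi,gi->", yb, Wiy))
        return XtWX, XtWy, ytWy, logdet

    def crit(log_gam):
        out = assemble(np.exp(log_gam))
        if out is None:
            return 1e12
        XtWX, XtWy, ytWy, logdet = out
        b = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(b @ XtWy), 1e-12)
        sigma2 = rss / (N - p)
        _, ldA = np.linalg.slogdet(XtWX)
        return 0.5 * ((N - p) * np.log(sigma2) + logdet + ldA)

    x0 = np.log([0.1, 0.2, 1e-3])
    res = minimize(crit, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    gam = np.exp(res.x)
    XtWX, XtWy, ytWy, logdet = assemble(gam)
    b = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(b @ XtWy)
    sigma2 = rss / (N - p)
    cov = np.linalg.inv(XtWX) * sigma2
    return LMMLongResult(
        params=b,
        bse=np.sqrt(np.diag(cov)),
        cov_params=cov,
        sigma_e2=float(sigma2),
        family_var=float(gam[0] * sigma2),
        person_var=float(gam[1] * sigma2),
        slope_var=float(gam[2] * sigma2),
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        n_obs=int(N),
        n_groups=int(G),
        converged=bool(res.success),
    )
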