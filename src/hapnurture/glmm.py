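"""Random-intercept logistic regression by Gauss-Hermite quadrature.

Family clusters in parent-offspring cohorts are tiny (one or two siblings), so
the cluster-level integral over the random intercept is smooth and a fixed
Gauss-Hermite rule with a generous node count is accurate; no adaptive
recentering is needed at these cluster sizes.  The marginal log-likelihood is

    sum_g log  integral  prod_{i in g} p_i(b, u)  phi(u; 0, sigma^2) du,

maximized over (beta, log sigma) with BFGS; Wald standard errors come from the
numerical Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1


@dataclass
class LogitRIResult:
    params: np.ndarray  # fixed effects
    bse: np.ndarray
    sigma_u: float  # random-intercept SD
    llf: float
    converged: bool
    names: list
    cov_params: np.ndarray
    n_obs: int
    n_groups: int

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        z = self.params / self.bse
        return 2 * norm.sf(np.abs(z))


def _cluster_index(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    starts = np.concatenate([[0], np.nonzero(g[1:] != g[:-1])[0] + 1])
    return order, starts


def fit_logit_ri(y, X, groups, n_nodes: int = 25, names=None, start=None) -> LogitRIResult:
    """Mixed logistic regression with a cluster random intercept.

    Raises on apparent separation (diverging fixed effects).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    order, starts = _cluster_index(np.asarray(groups))
    ys, Xs = y[order], X[order]
    nodes, weights = hermgauss(n_nodes)
    log_w = np.log(weights / np.sqrt(np.pi))
    scaled = np.sqrt(2.0) * nodes
    p = X.shape[1]

    def nll(theta):
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        eta = Xs @ beta
        total = 0.0
        # per-observation log-likelihood at each node, summed within clusters
        per_node = np.empty((starts.size, n_nodes))
        sign = 2.0 * ys - 1.0
        for k in range(n_nodes):
            ll = log_expit(sign * (eta + sigma * scaled[k]))
            per_node[:, k] = np.add.reduceat(ll, starts)
        total = logsumexp(per_node + log_w[None, :], axis=1).sum()
        return -total

    if start is None:
        import statsmodels.api as sm

        try:
            init = sm.Logit(y, X).fit(disp=0, maxiter=100)
            b0 = init.params
        except Exception:
            b0 = np.zeros(p)
        start = np.concatenate([b0, [np.log(0.5)]])

    res = minimize(nll, start, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    beta = res.x[:p]
    if np.any(np.abs(beta) > 30):
        raise RuntimeError("apparent separation: fixed effects diverged during optimization")
    H = approx_hess1(res.x, nll)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    cov = cov_all[:p, :p]
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    return LogitRIResult(
        params=beta,
        bse=bse,
        sigma_u=float(np.exp(res.x[p])),
        llf=float(-res.fun),
        converged=bool(res.success or np.linalg.norm(res.jac) < 1e-2),
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        cov_params=cov,
        n_obs=int(y.size),
        n_groups=int(starts.size),
    )
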