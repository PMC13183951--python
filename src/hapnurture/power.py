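"""Monte Carlo power for maternal-vs-paternal coefficient differences.

The simulation is at the estimate level: per replicate the two coefficient
estimates are drawn from a bivariate normal centered on (0, delta_beta) with
the stated per-coefficient standard errors and correlation, and the two-sided
Wald test of equality is applied.  Power is the rejection fraction; the
analytic normal-theory power

    Phi(|d|/se_d - z) + Phi(-|d|/se_d - z),   se_d^2 = se_m^2 + se_p^2 - 2 r se_m se_p

serves as the closed-form cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm


def analytic_wald_power(delta_beta: float, se_maternal: float, se_paternal: float,
                        corr_estimates: float = 0.0, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided Wald equality test."""
    se_d = np.sqrt(se_maternal**2 + se_paternal**2 - 2 * corr_estimates * se_maternal * se_paternal)
    z = norm.ppf(1 - alpha / 2)
    ncp = abs(delta_beta) / se_d
    return float(norm.cdf(ncp - z) + norm.cdf(-ncp - z))


def power_wald_difference(delta_beta: float, se_maternal: float, se_paternal: float,
                          corr_estimates: float = 0.0, n_reps: int = 1000,
                          alpha: float = 0.05, seed: int = 0) -> pd.Series:
    """Monte Carlo power of the Wald test for a coefficient difference.

    Returns a Series with the estimated power, its Monte Carlo SE, and the
    analytic power for the same configuration.
    """
    if se_maternal <= 0 or se_paternal <= 0:
        raise ValueError("standard errors must be positive")
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    if abs(corr_estimates) >= 1:
        raise ValueError("|corr_estimates| must be < 1")

    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [se_maternal**2, corr_estimates * se_maternal * se_paternal],
            [corr_estimates * se_maternal * se_paternal, se_paternal**2],
        ]
    )
    draws = rng.multivariate_normal([0.0, delta_beta], cov, size=n_reps)
    diff = draws[:, 1] - draws[:, 0]
    se_d = np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    z = np.abs(diff) / se_d
    reject = z > norm.ppf(1 - alpha / 2)
    power = reject.mean()
    mc_se = np.sqrt(power * (1 - power) / n_reps)
    return pd.Series(
        {
            "delta_beta": delta_beta,
            "se_maternal": se_maternal,
            "se_paternal": se_paternal,
            "corr_estimates": corr_estimates,
            "n_reps": n_reps,
            "alpha": alpha,
            "power": float(power),
            "mc_se": float(mc_se),
            "analytic_power": analytic_wald_power(delta_beta, se_maternal, se_paternal,
                                                  corr_estimates, alpha),
        }
    )


def power_grid_from_fit(fit, constraints=(("maternal_t", "paternal_t"), ("maternal_nt", "paternal_nt")),
                        n_reps: int = 1000, alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Power at the observed coefficient difference and at its 95% CI endpoints.

    ``fit`` is a :class:`~hapnurture.sem.PoeFit`; per constraint the grid holds
    the observed maternal-paternal difference and the differences implied by
    the lower and upper confidence bounds of the contrast.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in constraints:
        ia, ib = fit.names.index(a), fit.names.index(b)
        d = fit.beta[ia] - fit.beta[ib]
        se_d = np.sqrt(fit.cov[ia, ia] + fit.cov[ib, ib] - 2 * fit.cov[ia, ib])
        if not np.isfinite(se_d):
            raise ValueError("fit lacks a robust covariance; cannot form CI endpoints")
        for label, delta in (("observed", d), ("ci_lower", d - 1.96 * se_d), ("ci_upper", d + 1.96 * se_d)):
            row = power_wald_difference(
                float(delta), float(fit.se[ia]), float(fit.se[ib]),
                n_reps=n_reps, alpha=alpha, seed=int(rng.integers(0, 2**31)),
            )
            row["constraint"] = f"{a}=={b}"
            row["point"] = label
            rows.append(row)
    return pd.DataFrame(rows)
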