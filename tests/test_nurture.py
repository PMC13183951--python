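"""Joint T/NT mixed models, DGT arithmetic, FDR, longitudinal model, contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from hapnurture import published
from hapnurture.nurture import (
    JointFit,
    adjust_joint_fits,
    contrasts_from_summaries,
    dgt,
    fdr_adjust,
    fit_joint_tn,
    fit_longitudinal,
    nurture_ratio,
    subsample_contrasts,
)
from hapnurture.pipeline import frame_from_true_scores
from hapnurture.sim import GenerativeParams, simulate_scores


def _frame(params):
    pheno, scores, info = simulate_scores(params)
    return frame_from_true_scores(pheno, scores, waves=1), info


def _gaussian_fit(beta_t, beta_nt, **kw):
    return JointFit(outcome="x", family=kw.pop("family", "gaussian"),
                    beta_t=beta_t, se_t=0.01, p_t=0.0, beta_nt=beta_nt, se_nt=0.01,
                    p_nt=0.0, n=100, n_families=100, family_var=0.0, converged=True, **kw)


class TestJointFit:
    def test_profile_engine_matches_statsmodels_mixedlm(self):
        d, _ = _frame(GenerativeParams(n_families=600, seed=51))
        a = fit_joint_tn(d, "cpd", engine="profile")
        b = fit_joint_tn(d, "cpd", engine="statsmodels")
        assert abs(a.beta_t - b.beta_t) < 1e-5
        assert abs(a.beta_nt - b.beta_nt) < 1e-5
        assert abs(a.se_t - b.se_t) < 1e-5
        assert abs(a.family_var - b.family_var) < 1e-3

    def test_zero_family_variance_matches_ols(self):
        d, _ = _frame(GenerativeParams(n_families=800, sigma_family=0.0, seed=53))
        fit = fit_joint_tn(d, "cpd")
        y = (d.cpd - d.cpd.mean()) / d.cpd.std()
        X = pd.DataFrame(
            {
                "const": 1.0,
                "pgs_t": (d.pgs_t_z - d.pgs_t_z.mean()) / d.pgs_t_z.std(),
                "pgs_nt": (d.pgs_nt_z - d.pgs_nt_z.mean()) / d.pgs_nt_z.std(),
                "age": (d.age - d.age.mean()) / d.age.std(),
                "sex_male": (d.sex == "male").astype(float),
            }
        )
        ols = sm.OLS(y, X).fit()
        assert abs(fit.beta_t - ols.params["pgs_t"]) < 1e-3
        assert abs(fit.beta_nt - ols.params["pgs_nt"]) < 1e-3

    def test_collinear_scores_rejected(self):
        d, _ = _frame(GenerativeParams(n_families=300, seed=55))
        d["pgs_nt_z"] = d["pgs_t_z"]
        with pytest.raises(ValueError, match="collinear"):
            fit_joint_tn(d, "cpd")

    def test_binomial_reports_odds_ratios(self):
        d, _ = _frame(GenerativeParams(n_families=1500, seed=57))
        fit = fit_joint_tn(d, "smoking_initiation", family="binomial")
        assert fit.family == "binomial"
        assert fit.or_t > 1.0  # positive transmitted effect on liability
        assert np.isclose(fit.or_t, np.exp(fit.beta_t))
        gfit = fit_joint_tn(d, "cpd")
        with pytest.raises(AttributeError):
            gfit.or_t

    def test_glmm_matches_plain_logit_when_no_cluster_variance(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.normal(size=n)
        eta = -0.3 + 0.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        d = pd.DataFrame({"y": y, "pgs_t_z": x, "pgs_nt_z": rng.normal(size=n),
                          "age": rng.normal(40, 8, n), "sex": "female",
                          "family_id": [f"f{i}" for i in range(n)]})
        d["sex"] = np.where(rng.random(n) < 0.5, "male", "female")
        fit = fit_joint_tn(d, "y", family="binomial")
        X = sm.add_constant(pd.DataFrame({
            "pgs_t": (d.pgs_t_z - d.pgs_t_z.mean()) / d.pgs_t_z.std(),
            "pgs_nt": (d.pgs_nt_z - d.pgs_nt_z.mean()) / d.pgs_nt_z.std(),
            "age": (d.age - d.age.mean()) / d.age.std(),
            "sex_male": (d.sex == "male").astype(float)}))
        logit = sm.Logit(y, X).fit(disp=0)
        assert abs(fit.beta_t - logit.params["pgs_t"]) < 0.02
        assert abs(fit.beta_nt - logit.params["pgs_nt"]) < 0.02


class TestDGTArithmetic:
    @pytest.mark.parametrize(
        "bt,bnt,expected",
        [(0.202, 0.037, 0.165), (0.136, 0.028, 0.108), (0.124, 0.016, 0.108), (0.1, 0.1, 0.0)],
    )
    def test_dgt_subtraction(self, bt, bnt, expected):
        assert np.isclose(dgt(_gaussian_fit(bt, bnt)), expected)

    def test_dgt_withheld_for_binary_outcomes(self):
        with pytest.raises(ValueError):
            dgt(_gaussian_fit(0.6, 0.0, family="binomial"))

    @pytest.mark.parametrize(
        "bt,bnt,expected",
        [(0.202, 0.037, 22.4), (0.136, 0.028, 25.9), (0.2, 0.0, 0.0)],
    )
    def test_nurture_ratio_percent(self, bt, bnt, expected):
        assert round(nurture_ratio(_gaussian_fit(bt, bnt)), 1) == expected

    def test_nurture_ratio_undefined_at_zero_dgt(self):
        with pytest.raises(ValueError):
            nurture_ratio(_gaussian_fit(0.05, 0.05))


class TestFDR:
    def test_published_five_test_family(self):
        p = [published.NT_PVALUES[k] for k in published.NT_PVALUES]
        adj = fdr_adjust(p)
        expected = [published.NT_PVALUES_FDR[k] for k in published.NT_PVALUES]
        assert np.allclose(np.round(adj, 3), expected)

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(fdr_adjust([0.2] * 4), 0.2)

    def test_single_test_unchanged(self):
        assert np.isclose(fdr_adjust([0.123])[0], 0.123)

    def test_monotone_and_order_preserving(self, rng):
        p = rng.random(25)
        adj = fdr_adjust(p)
        assert np.all(adj >= p)
        # permutation invariance up to reordering
        perm = rng.permutation(25)
        assert np.allclose(fdr_adjust(p[perm]), adj[perm])

    def test_matches_naive_step_up_oracle(self, rng):
        p = rng.random(11)
        order = np.argsort(p)
        m = p.size
        raw = p[order] * m / (np.arange(m) + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        assert np.allclose(fdr_adjust(p), oracle)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_adjust_joint_fits_families(self):
        fits = [_gaussian_fit(0.1, 0.01) for _ in range(3)]
        for f, (pt, pn) in zip(fits, [(0.001, 0.612), (0.002, 0.004), (0.5, 0.014)]):
            f.p_t, f.p_nt = pt, pn
        adjust_joint_fits(fits)
        assert all(f.p_fdr_nt >= f.p_nt for f in fits)
        assert all(f.p_fdr_t >= f.p_t for f in fits)


def _dense_reml_oracle(y, X, fam, per, age_c, gammas):
    """Independent dense REML deviance for the longitudinal model."""
    order = np.argsort(fam, kind="stable")
    y, X, fam, per, age_c = y[order], X[order], fam[order], per[order], age_c[order]
    starts = np.concatenate([[0], np.nonzero(fam[1:] != fam[:-1])[0] + 1])
    bnd = np.append(starts, y.size)
    N, p = X.shape
    gf, gp, gs = gammas
    logdet, XtVX, XtVy, ytVy = 0.0, np.zeros((p, p)), np.zeros(p), 0.0
    for k in range(starts.size):
        s, e = bnd[k], bnd[k + 1]
        pid, inv = np.unique(per[s:e], return_inverse=True)
        D = np.zeros((e - s, pid.size))
        D[np.arange(e - s), inv] = 1.0
        A = D * age_c[s:e, None]
        V = np.eye(e - s) + gf * np.ones((e - s, e - s)) + gp * D @ D.T + gs * A @ A.T
        logdet += np.linalg.slogdet(V)[1]
        Vi = np.linalg.inv(V)
        XtVX += X[s:e].T @ Vi @ X[s:e]
        XtVy += X[s:e].T @ Vi @ y[s:e]
        ytVy += y[s:e] @ Vi @ y[s:e]
    b = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - b @ XtVy
    sigma2 = rss / (N - p)
    return 0.5 * ((N - p) * np.log(sigma2) + logdet + np.linalg.slogdet(XtVX)[1]), b, sigma2


class TestLongitudinal:
    def test_solver_at_reml_optimum_of_dense_oracle(self):
        params = GenerativeParams(n_families=250, seed=61)
        pheno, scores, _ = simulate_scores(params)
        d = frame_from_true_scores(pheno, scores)
        fit = fit_longitudinal(d)
        res = fit.extra["result"]
        g = np.array([fit.family_var, fit.person_var, fit.slope_var]) / res.sigma_e2
        y = res  # solver result
        # rebuild the design exactly as the solver saw it
        from hapnurture.nurture import _sex_male, _z

        dd = d.copy()
        yv = _z(dd.current_cpd)
        t, nt = _z(dd.pgs_t_z), _z(dd.pgs_nt_z)
        ac = dd.age.to_numpy() - 33.0
        X = pd.DataFrame({"const": 1.0, "pgs_t": t, "pgs_nt": nt, "age": ac,
                          "sex_male": _sex_male(dd.sex), "birth_year": _z(dd.birth_year),
                          "pgs_t_x_age": t * ac, "pgs_nt_x_age": nt * ac})
        for w in (2, 3):
            X[f"wave_{w}"] = (dd.wave == w).astype(float)
        fam = dd.family_id.to_numpy()
        per = dd.individual_id.to_numpy()
        dev0, b0, _ = _dense_reml_oracle(yv, X.to_numpy(), fam, per, ac, g)
        assert np.allclose(b0, fit.coefficients.beta.to_numpy(), atol=1e-5)
        # solver's solution is a local optimum of the independent oracle
        for scale in (0.7, 1.4):
            dev1, _, _ = _dense_reml_oracle(yv, X.to_numpy(), fam, per, ac,
                                            np.maximum(g, 1e-8) * scale)
            assert dev1 >= dev0 - 1e-6

    def test_zero_variance_limit_matches_pooled_ols(self):
        params = GenerativeParams(n_families=400, sigma_family=0.0, sigma_person=0.0,
                                  sigma_age_slope=0.0, former_smoker_rate=0.0, seed=63)
        pheno, scores, _ = simulate_scores(params)
        d = frame_from_true_scores(pheno, scores)
        fit = fit_longitudinal(d)
        from hapnurture.nurture import _sex_male, _z

        yv = _z(d.current_cpd)
        t, nt = _z(d.pgs_t_z), _z(d.pgs_nt_z)
        ac = d.age.to_numpy() - 33.0
        X = pd.DataFrame({"const": 1.0, "pgs_t": t, "pgs_nt": nt, "age": ac,
                          "sex_male": _sex_male(d.sex), "birth_year": _z(d.birth_year),
                          "pgs_t_x_age": t * ac, "pgs_nt_x_age": nt * ac})
        for w in (2, 3):
            X[f"wave_{w}"] = (d.wave == w).astype(float)
        ols = sm.OLS(yv, X).fit()
        diff = np.abs(fit.coefficients.beta.to_numpy() - ols.params.to_numpy())
        assert diff.max() < 1e-3

    def test_single_wave_rejected(self):
        params = GenerativeParams(n_families=200, seed=65)
        pheno, scores, _ = simulate_scores(params)
        d = frame_from_true_scores(pheno, scores, waves=1)
        with pytest.raises(ValueError, match="two waves"):
            fit_longitudinal(d)

    def test_constant_age_rejected(self):
        params = GenerativeParams(n_families=200, seed=67)
        pheno, scores, _ = simulate_scores(params)
        d = frame_from_true_scores(pheno, scores)
        d["age"] = 33.0
        with pytest.raises(ValueError, match="variance in age"):
            fit_longitudinal(d)

    def test_age_varying_transmitted_effect_recovered(self):
        params = GenerativeParams(n_families=3000, age_slope_T=-0.02,
                                  age_slope_NT=0.0, seed=69)
        pheno, scores, _ = simulate_scores(params)
        d = frame_from_true_scores(pheno, scores)
        fit = fit_longitudinal(d)
        bt, se_t, p_t = fit.term("pgs_t_x_age")
        bn, se_n, p_n = fit.term("pgs_nt_x_age")
        assert bt < 0 and p_t < 0.01
        assert abs(bn) < 2.5 * se_n
        assert min(fit.person_var, fit.family_var, fit.slope_var) >= 0


class TestContrasts:
    def test_identical_groups_zero_smd(self):
        s = pd.DataFrame(
            [{"characteristic": "x", "kind": "continuous", "n_pair": 100, "mean_pair": 5.0,
              "sd_pair": 2.0, "n_trio": 80, "mean_trio": 5.0, "sd_trio": 2.0},
             {"characteristic": "b", "kind": "binary", "n_pair": 100, "count_pair": 40,
              "n_trio": 80, "count_trio": 32}]
        )
        out = contrasts_from_summaries(s)
        assert np.allclose(out.smd, 0.0)

    def test_published_pack_years_smd_below_bound(self):
        row = published.COHORT_DESCRIPTIVES.query("characteristic == 'pack_years'")
        out = contrasts_from_summaries(row)
        assert 0.0 < out.smd.iloc[0] <= 0.18

    def test_chi2_matches_closed_form_on_hand_table(self):
        s = pd.DataFrame([{"characteristic": "b", "kind": "binary",
                           "n_pair": 200, "count_pair": 90, "n_trio": 100, "count_trio": 30}])
        out = contrasts_from_summaries(s)
        # Pearson chi-square from cell counts, brute force
        obs = np.array([[90, 110], [30, 70]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert np.isclose(out.statistic.iloc[0], chi2)
        assert np.isclose(out.p.iloc[0], stats.chi2.sf(chi2, 1))

    def test_cohort_contrasts_from_simulated_pedigree(self, small_cohort):
        out = subsample_contrasts(small_cohort.phenotypes, small_cohort.pedigree)
        assert len(out) == 7
        assert (out.smd >= 0).all()
        # random masking: no systematic pair/trio differences at this scale
        assert out.smd.max() < 0.5

    def test_empty_subgroup_rejected(self, small_cohort):
        ped = small_cohort.pedigree.copy()
        ped.loc[ped.role.isin(["mother", "father"]), "genotyped"] = True  # no pairs
        with pytest.raises(ValueError):
            subsample_contrasts(small_cohort.phenotypes, ped)
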