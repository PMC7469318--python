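import numpy as np
import pytest
from scipy import stats

from informdrop import (LMMParams, SimConfig, dataset_from_records, fit_lmm,
                        lmm_loglik, marginal_moments, predict_mean,
                        simulate_complete, simulate_trial)
from informdrop.core_data import VisitSchedule
from informdrop.lmm import design_matrices


def params(beta=(60.0, 0.5, -0.13), G=((400.0, 0.0), (0.0, 0.25)), s2=225.0):
    return LMMParams(*beta, G=np.asarray(G), sigma2=s2)


class TestMoments:
    def test_identity_covariance_when_g_zero(self):
        p = params(G=np.zeros((2, 2)), s2=1.0)
        _, V = marginal_moments(p, 0, [0.0, 3.0, 12.0])
        np.testing.assert_allclose(V, np.eye(3))

    def test_mean_direct_substitution(self):
        p = params(beta=(50.0, 2.0, 0.0), s2=1.0)
        m, _ = marginal_moments(p, 1, [0.0, 1.0])
        np.testing.assert_allclose(m, [50.0, 52.0])

    def test_covariance_hand_computed(self):
        p = params(G=((4.0, 0.0), (0.0, 1.0)), s2=1.0)
        _, V = marginal_moments(p, 0, [0.0, 2.0])
        np.testing.assert_allclose(V, [[5.0, 4.0], [4.0, 9.0]], atol=1e-12)

    def test_predict_mean_identities(self):
        assert predict_mean(params(beta=(0, 0, 0)), 0, [1.0, 5.0]).max() == 0.0
        # slope cancellation: beta1 + beta2 = 0 in the experimental arm
        p = params(beta=(50.0, 1.0, -1.0))
        assert predict_mean(p, 1, [10.0])[0] == pytest.approx(50.0)
        p2 = params(beta=(47.0, 0.8, -0.3))
        t = np.array([0.0, 6.0, 36.0])
        diff = predict_mean(p2, 1, t) - predict_mean(p2, 0, t)
        np.testing.assert_allclose(diff, -0.3 * t, atol=1e-12)


class TestLoglik:
    def test_single_point_density(self):
        sched = VisitSchedule((0.0, 1.0))
        sc = np.array([60.0, np.nan])
        ds = dataset_from_records([("a", 0, sc), ("b", 0, sc)], sched)
        p = params(beta=(60.0, 0.0, 0.0), G=np.zeros((2, 2)), s2=1.0)
        ll = lmm_loglik(p, ds, "ML")
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)

    def test_matches_direct_mvn_density(self, mcar_dataset):
        p = params()
        ll = lmm_loglik(p, mcar_dataset, "ML")
        direct = 0.0
        t_all = mcar_dataset.schedule.times_array()
        for i in range(mcar_dataset.n_subjects):
            idx = np.flatnonzero(mcar_dataset.observed[i])
            m, V = marginal_moments(p, mcar_dataset.arm[i], t_all[idx])
            direct += stats.multivariate_normal.logpdf(
                mcar_dataset.scores[i, idx], m, V)
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_reml_variance_exceeds_ml(self):
        # small balanced layout with negligible subject heterogeneity: the
        # residual-variance estimators differ by the known N/(N-p) bias factor
        truth = LMMParams(60.0, 0.5, -0.13, G=np.diag([1e-6, 1e-8]),
                          sigma2=225.0)
        trial = simulate_complete(SimConfig(n_per_arm=4, lmm=truth, seed=9))
        f_ml = fit_lmm(trial.dataset, method="ML")
        f_reml = fit_lmm(trial.dataset, method="REML")
        assert f_reml.params.sigma2 > f_ml.params.sigma2

    def test_non_psd_G_rejected(self):
        with pytest.raises(ValueError):
            LMMParams(0, 0, 0, G=np.array([[1.0, 2.0], [2.0, 1.0]]), sigma2=1.0)


class TestFit:
    def test_noise_free_interpolation(self, schedule):
        t = schedule.times_array()
        recs = [(f"s{i}", i % 2, 50.0 + 2.0 * t) for i in range(8)]
        ds = dataset_from_records(recs, schedule)
        fit = fit_lmm(ds, method="ML")
        np.testing.assert_allclose(fit.params.beta, [50.0, 2.0, 0.0], atol=1e-6)
        assert fit.params.sigma2 < 1e-6

    def test_fixed_effects_equal_gls_oracle(self, mcar_dataset):
        from informdrop import _marginal
        from informdrop.lmm import _problem
        fit = fit_lmm(mcar_dataset, method="REML")
        prob = _problem(mcar_dataset)
        _, G, s2 = _marginal.chol_from_theta(fit.theta)
        # independent GLS: accumulate X'V^-1X and X'V^-1y by hand
        t_all = mcar_dataset.schedule.times_array()
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for i in range(mcar_dataset.n_subjects):
            idx = np.flatnonzero(mcar_dataset.observed[i])
            X, Z = design_matrices(mcar_dataset.arm[i], t_all[idx])
            V = Z @ G @ Z.T + s2 * np.eye(idx.size)
            Vi = np.linalg.inv(V)
            A += X.T @ Vi @ X
            b += X.T @ Vi @ mcar_dataset.scores[i, idx]
        np.testing.assert_allclose(fit.params.beta, np.linalg.solve(A, b),
                                   atol=1e-8)

    def test_ols_equivalence_when_g_zero(self):
        from informdrop import _marginal
        from informdrop.lmm import _problem
        sched = VisitSchedule((0.0, 1.0, 2.0, 3.0))
        rng = np.random.default_rng(9)
        t = sched.times_array()
        recs = []
        for i in range(40):
            arm = i % 2
            y = 50.0 - 0.4 * t + 0.2 * arm * t + rng.normal(0, 2.0, 4)
            recs.append((f"s{i}", arm, y))
        ds = dataset_from_records(recs, sched)
        X = np.vstack([design_matrices(ds.arm[i], t)[0] for i in range(40)])
        ols = np.linalg.lstsq(X, ds.scores.reshape(-1), rcond=None)[0]
        # exact identity at the G = 0 boundary of the parametrization
        prob = _problem(ds)
        theta0 = np.array([-10.0, 0.0, -10.0, np.log(4.0)])
        beta_gls, _ = prob.gls(theta0)
        np.testing.assert_allclose(beta_gls, ols, atol=1e-8)
        # the full fit on heterogeneity-free data lands next to OLS
        fit = fit_lmm(ds, method="ML")
        np.testing.assert_allclose(fit.params.beta, ols, atol=2e-3)

    def test_parameter_recovery_complete_data(self):
        truth = LMMParams(60.0, -0.5, 0.3, G=np.diag([100.0, 0.25]),
                          sigma2=25.0)
        est = []
        for rep in range(100):
            cfg = SimConfig(n_per_arm=100, lmm=truth, seed=1000 + rep)
            trial = simulate_complete(cfg)
            est.append(fit_lmm(trial.dataset, method="REML").params.beta)
        est = np.asarray(est)
        mc_se = est.std(axis=0, ddof=1) / 10.0
        np.testing.assert_array_less(
            np.abs(est.mean(axis=0) - [60.0, -0.5, 0.3]), 3.0 * mc_se)

    def test_ml_optimum_is_local_max(self, mcar_dataset):
        fit = fit_lmm(mcar_dataset, method="ML")
        ll = fit.loglik
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.normal(0, 0.05, 3)
            p = LMMParams(*(fit.params.beta + d), G=fit.params.G,
                          sigma2=fit.params.sigma2)
            assert lmm_loglik(p, mcar_dataset, "ML") <= ll + 1e-8

    def test_degenerate_designs_error(self, schedule):
        sc = np.full(8, np.nan)
        sc[0] = 50.0
        ds = dataset_from_records([("a", 0, sc), ("b", 1, sc)], schedule)
        with pytest.raises(ValueError, match="distinct times"):
            fit_lmm(ds)
        one = dataset_from_records([("a", 0, np.full(8, 50.0))], schedule)
        with pytest.raises(ValueError, match="two subjects"):
            fit_lmm(one)


def test_wald_z_matches_statsmodels(mcar_dataset):
    """Cross-validation against an independent mixed-model implementation."""
    import pandas as pd
    import statsmodels.formula.api as smf

    ds = mcar_dataset
    t_all = ds.schedule.times_array()
    rows = []
    for i in range(ds.n_subjects):
        for j in np.flatnonzero(ds.observed[i]):
            rows.append((i, ds.arm[i], t_all[j], ds.scores[i, j]))
    df = pd.DataFrame(rows, columns=["subj", "arm", "t", "y"])
    md = smf.mixedlm("y ~ t + t:arm", df, groups=df["subj"],
                     re_formula="~t").fit(reml=True)
    ours = fit_lmm(ds, method="REML")
    # point estimates agree with the independent fit
    ref_beta = md.params[["Intercept", "t", "t:arm"]].to_numpy()
    np.testing.assert_allclose(ours.params.beta, ref_beta, atol=1e-3)
    # Wald z against the reference variance components with the GLS
    # covariance convention (the one the trial software family reports)
    G_ref = md.cov_re.to_numpy()
    s2_ref = md.scale
    A = np.zeros((3, 3))
    for i in range(ds.n_subjects):
        idx = np.flatnonzero(ds.observed[i])
        X, Z = design_matrices(ds.arm[i], t_all[idx])
        V = Z @ G_ref @ Z.T + s2_ref * np.eye(idx.size)
        A += X.T @ np.linalg.solve(V, X)
    z_ref = ref_beta[1] / np.sqrt(np.linalg.inv(A)[1, 1])
    z_our = ours.params.beta1 / ours.se[1]
    assert z_our == pytest.approx(z_ref, rel=0.02)
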