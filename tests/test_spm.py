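import numpy as np
import pytest
from scipy import integrate

from informdrop import (DEFAULT_KNOTS, GHConfig, LMMParams, SimConfig,
                        SPMParams, cumulative_hazard, current_value,
                        dataset_from_records, dropout_hazard_ratio,
                        dropout_times, fit_lmm, fit_spm, hazard, lmm_loglik,
                        simulate_trial, spm_loglik)
from informdrop.spm import (fit_piecewise_exponential, interval_index,
                            piecewise_exponential_loglik,
                            pseudo_adaptive_config)


def lmm_params(**kw):
    base = dict(beta0=60.0, beta1=0.5, beta2=-0.13,
                G=np.array([[400.0, 2.0], [2.0, 0.25]]), sigma2=225.0)
    base.update(kw)
    return LMMParams(**base)


def spm_params(gamma=0.2, alpha=-0.02, xi=None, lmm=None):
    xi = np.asarray(xi if xi is not None
                    else [1.2, 1.0, 0.8, 0.5, 0.25, 0.15, 0.12])
    return SPMParams(lmm=lmm or lmm_params(), gamma=gamma, alpha=alpha, xi=xi)


class TestHazardPieces:
    def test_current_value_examples(self):
        p = lmm_params(beta0=50.0, beta1=1.0, beta2=0.0)
        assert current_value(p, (0.0, 0.0), 0, 4.0) == pytest.approx(54.0)
        # slope terms cancel: beta1 + beta2 + b1 = 0 in the experimental arm
        p2 = lmm_params(beta0=48.0, beta1=1.0, beta2=-0.4)
        vals = current_value(p2, (3.0, -0.6), 1, np.array([0.0, 10.0, 36.0]))
        np.testing.assert_allclose(vals, 51.0)

    def test_interval_indexing_left_closed(self):
        knots = DEFAULT_KNOTS
        assert interval_index(knots, 0.0) == 0
        assert interval_index(knots, 1.25) == 1
        assert interval_index(knots, 23.99) == 5
        assert interval_index(knots, 24.0) == 6
        assert interval_index(knots, 100.0) == 6

    def test_hazard_examples(self):
        p = spm_params(gamma=0.0, alpha=0.0)
        assert hazard(p, (0, 0), 1, 5.0) == pytest.approx(p.xi[3])  # t in [4, 6)
        # flat trajectory at 50 with alpha = 0.01 scales the level by e^0.5
        flat = lmm_params(beta0=50.0, beta1=0.0, beta2=0.0)
        p2 = spm_params(gamma=0.0, alpha=0.01, xi=[0.1] * 7, lmm=flat)
        assert hazard(p2, (0, 0), 0, 2.0) == pytest.approx(0.16487, abs=5e-6)
        # doubling exp(gamma) doubles the hazard at every time
        p3 = spm_params(gamma=0.3, alpha=0.013)
        p4 = spm_params(gamma=0.3 + np.log(2.0), alpha=0.013)
        for t in (0.5, 7.0, 30.0):
            assert hazard(p4, (1.0, 0.2), 1, t) == pytest.approx(
                2.0 * hazard(p3, (1.0, 0.2), 1, t))

    def test_cumulative_hazard_exponential_case(self):
        flat = lmm_params(beta0=0.0, beta1=0.0, beta2=0.0)
        p = SPMParams(lmm=flat, gamma=0.0, alpha=0.0, xi=[0.1, 0.1],
                      knots=(10.0,))
        assert cumulative_hazard(p, (0, 0), 0, 4.0) == pytest.approx(0.4)

    def test_cumulative_hazard_linear_trajectory(self):
        traj = lmm_params(beta0=40.0, beta1=5.0, beta2=0.0)
        p = SPMParams(lmm=traj, gamma=0.0, alpha=0.01, xi=[0.1, 0.1],
                      knots=(2.0,))
        assert cumulative_hazard(p, (0, 0), 0, 2.0) == pytest.approx(
            0.3138, abs=5e-5)

    def test_cumulative_hazard_equals_integrated_hazard(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            p = spm_params(gamma=rng.uniform(-0.5, 0.5),
                           alpha=rng.uniform(-0.05, 0.05),
                           xi=rng.uniform(0.02, 1.5, 7))
            b = rng.normal(0, [15.0, 0.4])
            arm = int(rng.integers(2))
            t = float(rng.uniform(0.5, 36.0))
            val = cumulative_hazard(p, b, arm, t)
            ref, _ = integrate.quad(lambda u: hazard(p, b, arm, u), 0, t,
                                    limit=400,
                                    points=[k for k in p.knots if k < t])
            assert val == pytest.approx(ref, abs=1e-8 * max(1.0, ref))
            # survival in (0, 1], non-increasing
            grid = np.linspace(0, 36, 20)
            surv = np.exp(-cumulative_hazard(p, b, arm, grid))
            assert (surv <= 1.0 + 1e-12).all()
            assert (np.diff(surv) <= 1e-12).all()


class TestDropoutTimes:
    def test_convention(self, make_monotone_dataset):
        ds = make_monotone_dataset({0: {1: 1, 3: 1, 8: 2}})
        dt = dropout_times(ds)
        np.testing.assert_allclose(sorted(dt.T), [0.0, 3.0, 36.0, 36.0])
        assert dt.event.sum() == 2


class TestLoglik:
    def test_decoupling_exact_form(self, mcar_dataset):
        """alpha = 0: joint likelihood separates into the trajectory ML
        likelihood and a piecewise-exponential survival likelihood."""
        rng = np.random.default_rng(9)
        dt = dropout_times(mcar_dataset)
        for _ in range(3):
            p = spm_params(gamma=rng.uniform(-0.5, 0.5), alpha=0.0,
                           xi=rng.uniform(0.05, 1.0, 7))
            pe = piecewise_exponential_loglik(p.xi, p.gamma, DEFAULT_KNOTS,
                                              dt.T, dt.event,
                                              mcar_dataset.arm)
            ref = lmm_loglik(p.lmm, mcar_dataset, "ML") + pe
            ll = spm_loglik(p, mcar_dataset, GHConfig(9), form="exact")
            assert ll == pytest.approx(ref, abs=1e-6)

    def test_decoupling_interval_form(self, mcar_dataset):
        """Same separation with the interval-censored dropout probability,
        against an independently coded piecewise-exponential survival
        function."""
        from informdrop.spm import _exposure_matrix
        ds = mcar_dataset
        p = spm_params(gamma=0.25, alpha=0.0,
                       xi=[0.4, 0.35, 0.3, 0.2, 0.1, 0.05, 0.04])

        def S(t_arr):
            E = _exposure_matrix(t_arr, DEFAULT_KNOTS)
            return np.exp(-(E @ p.xi) * np.exp(p.gamma * ds.arm))

        t_all = ds.schedule.times_array()
        D = ds.dropout_index
        dt = dropout_times(ds)
        T_next = t_all[np.minimum(D, 7)]
        probs = np.where(dt.event == 1, S(dt.T) - S(T_next), S(dt.T))
        ref = lmm_loglik(p.lmm, ds, "ML") + np.log(probs).sum()
        ll = spm_loglik(p, ds, GHConfig(9), form="interval")
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_g_to_zero_collapses_to_plugin(self, schedule):
        rng = np.random.default_rng(2)
        recs = []
        for i in range(10):
            d = int(rng.integers(2, 9))
            sc = np.full(8, np.nan)
            sc[:d] = rng.normal(60, 5, d)
            recs.append((f"s{i}", i % 2, sc))
        ds = dataset_from_records(recs, schedule)
        tiny = lmm_params(G=np.diag([1e-8, 1e-10]))
        p = spm_params(lmm=tiny, alpha=-0.01)
        ll = spm_loglik(p, ds, GHConfig(9))
        # reference: integrand at b = 0 (interval-censored dropout part)
        from informdrop.spm import _SPMContext
        ctx = _SPMContext(ds, GHConfig(1), None)
        ref = lmm_loglik(tiny, ds, "ML")
        t_all = schedule.times_array()
        for i in range(ds.n_subjects):
            lo = cumulative_hazard(p, (0, 0), ds.arm[i], ctx.T[i])
            if ctx.event[i]:
                hi = cumulative_hazard(p, (0, 0), ds.arm[i], ctx.T_next[i])
                ref += -lo + np.log(-np.expm1(-(hi - lo)))
            else:
                ref += -lo
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_node_refinement(self):
        cfg = SimConfig(n_per_arm=25, mechanism="mnar_spm", seed=31)
        ds = simulate_trial(cfg).dataset
        p = spm_params()
        l9 = spm_loglik(p, ds, GHConfig(9))
        l25 = spm_loglik(p, ds, GHConfig(25))
        assert abs(l9 - l25) < 1e-4

    def test_pseudo_adaptive_matches_adaptive_at_centering(self, mcar_dataset):
        pre = fit_lmm(mcar_dataset, method="REML")
        p = spm_params(lmm=pre.params, alpha=-0.01)
        ll_ad = spm_loglik(p, mcar_dataset, GHConfig(9))
        ll_fx = spm_loglik(p, mcar_dataset, pseudo_adaptive_config(mcar_dataset, 9))
        assert ll_fx == pytest.approx(ll_ad, abs=1e-8)


class TestFit:
    def test_no_events_reduces_to_lmm(self, schedule, caplog):
        import logging
        rng = np.random.default_rng(3)
        recs = [(f"s{i}", i % 2, rng.normal(60, 10, 8)) for i in range(20)]
        ds = dataset_from_records(recs, schedule)
        with caplog.at_level(logging.WARNING):
            fit = fit_spm(ds)
        ref = fit_lmm(ds, method="ML")
        np.testing.assert_allclose(fit.params.lmm.beta, ref.params.beta,
                                   atol=1e-8)
        assert fit.n_events == 0
        assert any("no dropout events" in r.message for r in caplog.records)

    def test_single_dataset_recovery(self):
        cfg = SimConfig(n_per_arm=125, mechanism="mnar_spm", seed=100)
        ds = simulate_trial(cfg).dataset
        fit = fit_spm(ds, quad=GHConfig(5))
        assert fit.converged and fit.hessian_ok
        assert abs(fit.params.alpha - (-0.02)) < 3 * fit.se_alpha
        assert (fit.params.xi > 0).all()

    def test_piecewise_exponential_profile_fit(self):
        rng = np.random.default_rng(12)
        n = 4000
        arm = np.repeat([0, 1], n // 2)
        lam = 0.12 * np.exp(0.4 * arm)
        T = rng.exponential(1.0 / lam)
        event = (T < 36.0).astype(int)
        T = np.minimum(T, 36.0)
        xi, g = fit_piecewise_exponential(T, event, arm)
        assert g == pytest.approx(0.4, abs=0.1)
        np.testing.assert_allclose(xi, 0.12, rtol=0.15)


class TestHazardRatio:
    def test_published_transforms(self):
        hr = dropout_hazard_ratio(-0.015, -10.0)
        assert round(hr, 2) == 1.16
        hr2, (lo, hi) = dropout_hazard_ratio(-0.015, -10.0,
                                             alpha_ci=(-0.03, 0.0))
        assert round(hi, 2) == 1.35
        assert lo == pytest.approx(1.0)

    def test_null_association(self):
        assert dropout_hazard_ratio(0.0, -25.0) == 1.0

    def test_ci_endpoints_sorted(self):
        _, (lo, hi) = dropout_hazard_ratio(0.02, 10.0, alpha_ci=(0.01, 0.03))
        assert lo < hi
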