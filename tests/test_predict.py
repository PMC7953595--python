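"""Predictions: closed-form targets, algebraic identities, contrasts, delta."""

import numpy as np
import pytest
from scipy import stats

import fpcrisk as fp
from fpcrisk.predict import _ci
from fpcrisk.quadrature import power_transformed_nodes
from tests.conftest import EXP_RATES


@pytest.fixture(scope="module")
def grid():
    return np.array([0.5, 1.0, 2.0, 5.0, 8.0, 10.0])


class TestClosedFormTargets:
    """Large-n fits to competing exponentials reproduce the closed forms."""

    def test_cif_csh_route(self, exp2_models_50k):
        res = fp.predict_cif_csh(exp2_models_50k, {}, [5.0], cause=1)
        truth = fp.exp_cif(EXP_RATES, 1, 5.0)
        assert abs(res.estimate[0] - truth) / truth < 0.01

    def test_lyl(self, exp2_models_50k):
        res = fp.predict_lyl(exp2_models_50k, {}, 10.0, cause=1)
        truth = fp.exp_lyl(EXP_RATES, 1, 10.0)
        assert abs(res.estimate[0] - truth) / truth < 0.01

    def test_rmst(self, exp2_models_50k):
        res = fp.predict_rmst(exp2_models_50k, {}, 10.0)
        truth = fp.exp_rmst(EXP_RATES, 10.0)
        assert abs(res.estimate[0] - truth) / truth < 0.01

    def test_constant_hazard_recovered(self, exp2_models_50k):
        res = fp.predict_csh(exp2_models_50k[0], {}, np.array([1.0, 3.0, 7.0]))
        assert np.all(np.abs(res.estimate - EXP_RATES[0]) / EXP_RATES[0] < 0.05)

    def test_weibull_hazard_shape(self, weibull_fit_20k):
        t = np.array([0.5, 1.0, 2.0, 4.0])
        res = fp.predict_csh(weibull_fit_20k, {"x": 0.0}, t)
        truth = 0.2 * 1.4 * t**0.4
        assert np.all(np.abs(res.estimate - truth) / truth < 0.05)


class TestIdentities:
    def test_survival_plus_cifs_is_one(self, exp2_models_50k, grid):
        S = fp.predict_survival(exp2_models_50k, {}, grid).estimate
        F = sum(
            fp.predict_cif_csh(exp2_models_50k, {}, grid, cause=k).estimate for k in (1, 2)
        )
        assert np.max(np.abs(S + F - 1.0)) < 1e-6

    def test_rmst_plus_lyl_is_horizon(self, exp2_models_50k):
        mu = fp.predict_rmst(exp2_models_50k, {}, 10.0).estimate[0]
        lyls = fp.predict_lyl(exp2_models_50k, {}, 10.0)
        assert abs(mu + sum(l.estimate[0] for l in lyls) - 10.0) < 1e-8

    def test_rmst_direct_route_agrees(self, exp2_models_50k):
        mu1 = fp.predict_rmst(exp2_models_50k, {}, 10.0).estimate[0]
        mu2 = fp.predict_rmst(exp2_models_50k, {}, 10.0, method="direct").estimate[0]
        assert abs(mu1 - mu2) < 1e-6

    def test_cumhaz_equals_exp_eta(self, exp2_models_50k):
        # integral of the predicted hazard reproduces H = exp(eta)
        m = exp2_models_50k[0]
        rule = fp.legendre_rule(30)
        for t in (2.0, 5.0, 10.0):
            u, w = power_transformed_nodes(t, rule, power=2)
            h = m.linear_predictor_dlnt(u, {}) / u * np.exp(m.linear_predictor(u, {}))
            H = np.exp(m.linear_predictor(np.array([t]), {}))[0]
            assert abs(w @ h - H) / H < 1e-6

    def test_cif_monotone_and_bounded(self, exp2_models_50k, grid):
        res = fp.predict_cif_csh(exp2_models_50k, {}, grid, cause=1)
        assert np.all(np.diff(res.estimate) > 0)
        assert np.all((res.estimate >= 0) & (res.estimate <= 1))

    def test_lyl_nondecreasing_and_bounded(self, exp2_models_50k):
        vals = [
            fp.predict_lyl(exp2_models_50k, {}, t, cause=1).estimate[0]
            for t in (1.0, 2.0, 5.0, 10.0)
        ]
        assert np.all(np.diff(vals) > 0)
        assert all(v <= t for v, t in zip(vals, (1.0, 2.0, 5.0, 10.0)))


@pytest.fixture(scope="module")
def sdh_fit():
    ds = fp.simulate_subdistribution(
        n=20_000, pi=0.3, beta=0.5, censoring_rate=0.2, admin_time=8.0, seed=31
    )
    return fp.fit(
        ds,
        fp.ModelSpec(
            scale="subdistribution", cause=1, baseline_df=3, covariates=("x",)
        ),
        expand_kwargs={"max_intervals": 60},
    )


class TestSubdistributionRoute:
    def test_cif_monotone_bounded(self, sdh_fit, grid):
        res = fp.predict_cif_sdh(sdh_fit, {"x": 0.0}, grid)
        assert np.all(np.diff(res.estimate) > 0)
        assert np.all((res.estimate > 0) & (res.estimate < 1))

    def test_cif_tracks_fine_gray_truth(self, sdh_fit):
        t = np.array([0.5, 1.0, 2.0, 4.0])
        truth = 1.0 - (1.0 - 0.3 * (1.0 - np.exp(-t)))
        res0 = fp.predict_cif_sdh(sdh_fit, {"x": 0.0}, t)
        assert np.max(np.abs(res0.estimate - (1 - (1 - 0.3 * (1 - np.exp(-t)))))) < 0.02
        res1 = fp.predict_cif_sdh(sdh_fit, {"x": 1.0}, t)
        truth1 = 1.0 - (1.0 - 0.3 * (1.0 - np.exp(-t))) ** np.exp(0.5)
        assert np.max(np.abs(res1.estimate - truth1)) < 0.02

    def test_k1_cif_equals_one_minus_survival(self, weibull_fit_20k):
        grid = np.array([1.0, 3.0, 6.0])
        F = fp.predict_cif_csh([weibull_fit_20k], {"x": 1.0}, grid, cause=1).estimate
        S = fp.predict_survival([weibull_fit_20k], {"x": 1.0}, grid).estimate
        assert np.max(np.abs(F - (1.0 - S))) < 1e-6


class TestContrasts:
    def test_self_contrast_null(self, exp2_models_50k):
        a = fp.predict_rmst(exp2_models_50k, {}, 10.0)
        b = fp.predict_rmst(exp2_models_50k, {}, 10.0)
        d = fp.contrast(a, b, "difference")
        assert d.estimate[0] == 0.0 and d.se[0] == 0.0
        r = fp.contrast(a, b, "ratio")
        assert r.estimate[0] == 1.0

    def test_antisymmetry(self, weibull_fit_20k):
        grid = [2.0, 5.0]
        a = fp.predict_cif_csh([weibull_fit_20k], {"x": 1.0}, grid, cause=1)
        b = fp.predict_cif_csh([weibull_fit_20k], {"x": 0.0}, grid, cause=1)
        d1 = fp.contrast(a, b)
        d2 = fp.contrast(b, a)
        assert np.allclose(d1.estimate, -d2.estimate)
        assert np.allclose(d1.se, d2.se)

    def test_exponential_strata_rmst_difference(self):
        # single cause, PH: lam(x) = 0.3 exp(0.5 x); closed-form RMST per arm
        spec_sim = fp.ScenarioSpec(
            n=40_000,
            baselines=(("exponential", {"rate": 0.3}),),
            betas=({"x": 0.5},),
            covariate_spec={"x": ("bernoulli", 0.5)},
            seed=77,
        )
        ds = fp.simulate_csh(spec_sim)
        m = fp.fit(
            ds, fp.ModelSpec(scale="cause_specific", cause=1, baseline_df=1, covariates=("x",))
        )
        a = fp.predict_rmst([m], {"x": 1.0}, 10.0)
        b = fp.predict_rmst([m], {"x": 0.0}, 10.0)
        d = fp.contrast(a, b)
        lam1, lam0 = 0.3 * np.exp(0.5), 0.3
        truth = fp.exp_rmst([lam1], 10.0) - fp.exp_rmst([lam0], 10.0)
        assert abs(d.estimate[0] - truth) < 3 * d.se[0] + 0.01

    def test_mismatched_measures_rejected(self, exp2_models_50k):
        a = fp.predict_rmst(exp2_models_50k, {}, 10.0)
        b = fp.predict_lyl(exp2_models_50k, {}, 10.0, cause=1)
        with pytest.raises(ValueError, match="matching measures"):
            fp.contrast(a, b)


class TestDeltaMethod:
    def test_single_parameter_identity(self, weibull_fit_20k):
        j = 1
        est, se, lci, uci = fp.delta_method(
            lambda th: th[j], [weibull_fit_20k], transform="identity"
        )
        assert se[0] == pytest.approx(np.sqrt(weibull_fit_20k.vcov[j, j]), rel=1e-6)

    def test_exp_parameter_log_transform(self, weibull_fit_20k):
        j = 2
        theta_j = weibull_fit_20k.params[j]
        sd = np.sqrt(weibull_fit_20k.vcov[j, j])
        est, se, lci, uci = fp.delta_method(
            lambda th: np.exp(th[j]), [weibull_fit_20k], transform="log"
        )
        z = stats.norm.ppf(0.975)
        assert lci[0] == pytest.approx(np.exp(theta_j - z * sd), rel=1e-4)
        assert uci[0] == pytest.approx(np.exp(theta_j + z * sd), rel=1e-4)

    def test_cloglog_interval_within_unit_range(self, exp2_models_50k):
        res = fp.predict_cif_csh(exp2_models_50k, {}, [5.0], cause=1)
        assert 0.0 < res.lci[0] < res.estimate[0] < res.uci[0] < 1.0

    def test_ci_transform_errors(self):
        with pytest.raises(ValueError, match="unknown transform"):
            _ci(np.array([0.5]), np.array([0.1]), "nope", 0.95)

    def test_invalid_times_rejected(self, weibull_fit_20k):
        with pytest.raises(ValueError, match="positive"):
            fp.predict_csh(weibull_fit_20k, {"x": 0.0}, [-1.0])
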