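"""Likelihood closed forms, parameter recovery, LR test and serialisation."""

import numpy as np
import pytest

import fpcrisk as fp
from fpcrisk.data import from_arrays
from fpcrisk.model import loglikelihood, prepare


def _exp_spec(**kw):
    base = dict(
        scale="cause_specific",
        cause=1,
        baseline_df=1,
        baseline_knots=(0.5, 3.0),
        orthogonalise=False,
    )
    base.update(kw)
    return fp.ModelSpec(**base)


class TestLoglikelihood:
    """With a df=1 basis, gamma = (log lam, 1) gives H(t) = lam t exactly."""

    def test_exponential_event(self):
        ds = from_arrays([2.0], [1], n_causes=1)
        md = prepare(ds, _exp_spec())
        lam = 0.4
        assert loglikelihood([np.log(lam), 1.0], md) == pytest.approx(
            np.log(lam) - lam * 2.0, abs=1e-12
        )

    def test_censored_contribution(self):
        ds = from_arrays([2.0], [0], n_causes=1)
        md = prepare(ds, _exp_spec())
        lam = 0.4
        assert loglikelihood([np.log(lam), 1.0], md) == pytest.approx(-lam * 2.0, abs=1e-12)

    def test_weight_doubles_contribution(self):
        frame = from_arrays([2.0], [1], n_causes=1).frame.assign(weight=2.0)
        ds = fp.SurvivalDataset(frame, n_causes=1)
        md = prepare(ds, _exp_spec())
        single = prepare(from_arrays([2.0], [1], n_causes=1), _exp_spec())
        th = [np.log(0.4), 1.0]
        assert loglikelihood(th, md) == pytest.approx(2.0 * loglikelihood(th, single))

    def test_delayed_entry_interval(self):
        # an interval (1, 2] censored row contributes H(1) - H(2)
        import pandas as pd

        frame = pd.DataFrame(
            {"id": [1], "tstart": [1.0], "tstop": [2.0], "event": [0], "weight": [1.0]}
        )
        ex = fp.ExpandedDataset(frame, cause=1, n_causes=1)
        md = prepare(ex, _exp_spec(scale="subdistribution"))
        lam = 0.4
        assert loglikelihood([np.log(lam), 1.0], md) == pytest.approx(lam * 1.0 - lam * 2.0)

    def test_weibull_shape(self):
        # gamma = (log lam, p) gives H = lam t^p, h = lam p t^(p-1)
        ds = from_arrays([2.0], [1], n_causes=1)
        md = prepare(ds, _exp_spec())
        lam, p, t = 0.3, 1.7, 2.0
        expected = np.log(lam * p * t ** (p - 1)) - lam * t**p
        assert loglikelihood([np.log(lam), p], md) == pytest.approx(expected, abs=1e-12)


class TestFit:
    def test_weibull_df1_linear_predictor_recovery(self, weibull_fit_20k):
        # df=1 model is exactly Weibull: eta(1 | x=0) = log lam at t=1
        eta1 = weibull_fit_20k.linear_predictor(np.array([1.0]), {"x": 0.0})[0]
        assert eta1 == pytest.approx(np.log(0.2), abs=0.06)

    def test_score_at_optimum_small(self, weibull_data_20k, weibull_fit_20k):
        md = prepare(weibull_data_20k, weibull_fit_20k.spec)
        ll, g = md.loglik_grad(weibull_fit_20k.params)
        assert np.max(np.abs(g)) < 1e-4 * (1.0 + abs(ll))

    def test_orthogonalised_and_raw_same_loglik(self, weibull_data_20k):
        spec_raw = fp.ModelSpec(
            scale="cause_specific", cause=1, baseline_df=1, covariates=("x",),
            orthogonalise=False,
        )
        spec_orth = fp.ModelSpec(
            scale="cause_specific", cause=1, baseline_df=1, covariates=("x",),
            orthogonalise=True,
        )
        m_raw = fp.fit(weibull_data_20k, spec_raw)
        m_orth = fp.fit(weibull_data_20k, spec_orth)
        assert abs(m_raw.loglik - m_orth.loglik) < 1e-6
        # raw coefficients recover (log lam, p, beta) within 3 SE
        se = np.sqrt(np.diag(m_raw.vcov))
        for name, truth in {"_cons": np.log(0.2), "_rcs1": 1.4, "x": 0.5}.items():
            j = m_raw.names.index(name)
            assert abs(m_raw.params[j] - truth) < 3 * se[j]

    def test_event_floor(self):
        ds = from_arrays([1.0, 2.0, 3.0], [1, 1, 0], n_causes=1)
        with pytest.raises(ValueError, match="at least 10"):
            fp.fit(ds, _exp_spec())

    def test_rank_deficiency_named(self, weibull_data_20k):
        frame = weibull_data_20k.frame.assign(x2=lambda d: d["x"])
        ds = fp.SurvivalDataset(frame, n_causes=1, covariates=("x", "x2"))
        spec = fp.ModelSpec(
            scale="cause_specific", cause=1, baseline_df=1, covariates=("x", "x2")
        )
        with pytest.raises(ValueError, match="collinear"):
            fp.fit(ds, spec)

    def test_tvc_model_recovers_time_dependent_loghr(self):
        # simulate beta(t) = b0 + b1 ln t via covariate-dependent Weibull shape
        spec_sim = fp.ScenarioSpec(
            n=50_000,
            baselines=(("weibull", {"rate": 0.3, "shape": 1.2}),),
            betas=({"x": 0.4},),
            tvc=({"x": 0.3},),
            covariate_spec={"x": ("bernoulli", 0.5)},
            admin_time=10.0,
            seed=99,
        )
        ds = fp.simulate_csh(spec_sim)
        spec = fp.ModelSpec(
            scale="cause_specific", cause=1, baseline_df=1, covariates=("x",),
            tvc={"x": 1}, orthogonalise=False,
        )
        m = fp.fit(ds, spec)
        se = np.sqrt(np.diag(m.vcov))
        # eta = g0 + g1 ln t + b0 x + b1 x ln t with truth (log .3, 1.2, .4, .3)
        for name, truth in {
            "_cons": np.log(0.3), "_rcs1": 1.2, "x": 0.4, "x_rcs1": 0.3
        }.items():
            j = m.names.index(name)
            assert abs(m.params[j] - truth) < 3 * se[j], (name, m.params[j])


class TestScaleEquivalence:
    def test_sdh_equals_csh_without_competing_events(self):
        spec_sim = fp.ScenarioSpec(
            n=4000,
            baselines=(("weibull", {"rate": 0.25, "shape": 0.9}),),
            censoring_rate=0.15,
            admin_time=10.0,
            seed=5,
        )
        ds = fp.simulate_csh(spec_sim)
        cs = fp.fit(ds, fp.ModelSpec(scale="cause_specific", cause=1, baseline_df=2))
        sd = fp.fit(ds, fp.ModelSpec(scale="subdistribution", cause=1, baseline_df=2))
        assert np.max(np.abs(cs.params - sd.params)) < 1e-5


class TestStackedFit:
    def test_stacked_matches_separate_fits(self):
        spec_sim = fp.ScenarioSpec(
            n=4000,
            baselines=(("exponential", {"rate": 0.2}), ("exponential", {"rate": 0.1})),
            betas=({"x": 0.4}, {"x": -0.2}),
            covariate_spec={"x": ("bernoulli", 0.5)},
            censoring_rate=0.05,
            admin_time=10.0,
            seed=11,
        )
        ds = fp.simulate_csh(spec_sim)
        specs = [
            fp.ModelSpec(scale="cause_specific", cause=k, baseline_df=2, covariates=("x",))
            for k in (1, 2)
        ]
        separate = [fp.fit(ds, s) for s in specs]
        stacked = fp.fit_stacked(ds, specs)
        for k in (1, 2):
            assert np.max(np.abs(stacked.extract(k).params - separate[k - 1].params)) < 1e-5
        assert stacked.loglik == pytest.approx(sum(m.loglik for m in separate), abs=1e-4)


class TestLRTest:
    def test_identical_models(self, weibull_fit_20k):
        stat, df, p = fp.lr_test(weibull_fit_20k, weibull_fit_20k)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_is_twice_loglik_difference(self, weibull_data_20k, weibull_fit_20k):
        reduced = fp.fit(
            weibull_data_20k, fp.ModelSpec(scale="cause_specific", cause=1, baseline_df=1)
        )
        stat, df, p = fp.lr_test(weibull_fit_20k, reduced)
        assert stat == pytest.approx(2 * (weibull_fit_20k.loglik - reduced.loglik))
        assert df == 1
        assert 0.0 <= p <= 1.0

    def test_non_nested_rejected(self, weibull_fit_20k, weibull_data_20k):
        reduced = fp.fit(
            weibull_data_20k, fp.ModelSpec(scale="cause_specific", cause=1, baseline_df=1)
        )
        with pytest.raises(ValueError):
            fp.lr_test(reduced, weibull_fit_20k)  # fewer params in "full"


class TestSerialisation:
    def test_round_trip(self, tmp_path, weibull_fit_20k):
        path = tmp_path / "model.json"
        weibull_fit_20k.save(path)
        back = fp.FittedModel.load(path)
        assert np.allclose(back.params, weibull_fit_20k.params)
        assert np.allclose(back.vcov, weibull_fit_20k.vcov)
        t = np.array([0.5, 2.0, 7.0])
        for x in ({"x": 0.0}, {"x": 1.0}):
            assert np.allclose(
                back.linear_predictor(t, x), weibull_fit_20k.linear_predictor(t, x)
            )
        # a second save is byte-identical (deterministic serialisation)
        path2 = tmp_path / "model2.json"
        back.save(path2)
        weibull_fit_20k.save(path)
        assert path.read_bytes() == path2.read_bytes()
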