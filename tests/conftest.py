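"""Shared fixtures: simulated datasets and fitted models reused across files.

All randomness is seeded; session scope avoids refitting the larger models
in every test module.
"""

import numpy as np
import pytest

import fpcrisk as fp

EXP_RATES = (0.2, 0.1)  # two competing exponential causes used throughout


@pytest.fixture(scope="session")
def exp2_data_50k():
    """n=50,000 from two exponential causes (0.2, 0.1), no censoring."""
    spec = fp.ScenarioSpec(
        n=50_000,
        baselines=(
            ("exponential", {"rate": EXP_RATES[0]}),
            ("exponential", {"rate": EXP_RATES[1]}),
        ),
        seed=20260924,
    )
    return fp.simulate_csh(spec)


@pytest.fixture(scope="session")
def exp2_models_50k(exp2_data_50k):
    """df=2 cause-specific fits to the large exponential dataset."""
    return [
        fp.fit(exp2_data_50k, fp.ModelSpec(scale="cause_specific", cause=k, baseline_df=2))
        for k in (1, 2)
    ]


@pytest.fixture(scope="session")
def weibull_data_20k():
    """n=20,000 Weibull (rate 0.2, shape 1.4) with a binary covariate, log-HR 0.5."""
    spec = fp.ScenarioSpec(
        n=20_000,
        baselines=(("weibull", {"rate": 0.2, "shape": 1.4}),),
        betas=({"x": 0.5},),
        covariate_spec={"x": ("bernoulli", 0.5)},
        censoring_rate=0.1,
        admin_time=10.0,
        seed=1234,
    )
    return fp.simulate_csh(spec)


@pytest.fixture(scope="session")
def weibull_fit_20k(weibull_data_20k):
    return fp.fit(
        weibull_data_20k,
        fp.ModelSpec(scale="cause_specific", cause=1, baseline_df=1, covariates=("x",)),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
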