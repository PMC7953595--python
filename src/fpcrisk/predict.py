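"""Post-estimation predictions with delta-method confidence intervals.

From fitted models this module predicts, for a covariate setting ``x``:

* the cause-specific cumulative incidence function ``F_k(t | x)`` -- directly
  as ``1 - exp(-exp(eta))`` from a subdistribution-scale model, or by
  Gauss-Legendre integration of ``S(u | x) h_k^cs(u | x)`` from the set of
  cause-specific models;
* the cause-specific hazard and all-cause survival;
* restricted mean survival time ``mu(t*) = t* - sum_k L_k(0, t*)``, the
  total restricted mean failure time, and the expected life-years lost due
  to each cause ``L_k(0, t*) = \\int_0^{t*} F_k(u | x) du``;
* differences and ratios of any of these between two covariate settings.

Standard errors propagate the parameter covariance through each functional
by the delta method with finite-difference gradients.  Confidence intervals
are computed on a transformed scale that respects range restrictions
(complementary log-log for probabilities, log for positive time quantities,
identity for differences, log for ratios) and back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import linalg, stats

from .model import FittedModel
from .quadrature import DEFAULT_NODES, QuadratureRule, legendre_rule

__all__ = [
    "PredictionResult",
    "ContrastResult",
    "predict_cif_sdh",
    "predict_csh",
    "predict_survival",
    "predict_cif_csh",
    "predict_lyl",
    "predict_rmst",
    "contrast",
    "delta_method",
]


def default_rule() -> QuadratureRule:
    return legendre_rule(DEFAULT_NODES)


# ---------------------------------------------------------------------------
# parameter stacking and delta machinery
# ---------------------------------------------------------------------------

def _as_models(models) -> list:
    if isinstance(models, FittedModel):
        return [models]
    models = list(models)
    if not models:
        raise ValueError("no models supplied")
    return models


def _stack_params(models: Sequence[FittedModel], robust: bool | None = None):
    theta = np.concatenate([m.params for m in models])
    blocks = [m.covariance(robust) for m in models]
    V = linalg.block_diag(*blocks)
    sizes = [m.params.size for m in models]
    offs = np.cumsum([0] + sizes)
    slices = [slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:])]
    return theta, V, slices


def _fd_jacobian(fn: Callable, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    f0 = np.atleast_1d(np.asarray(fn(theta), float))
    G = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        G[:, j] = (np.atleast_1d(fn(tp)) - np.atleast_1d(fn(tm))) / (2.0 * h)
    return G


def _ci(est: np.ndarray, se: np.ndarray, transform: str, level: float):
    z = stats.norm.ppf(0.5 + level / 2.0)
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "identity":
            return est - z * se, est + z * se
        if transform == "log":
            # exact for the monotone map theta -> exp(log theta +/- z se/theta)
            ratio = np.where(est > 0, np.exp(z * se / np.where(est > 0, est, 1.0)), np.nan)
            return est / ratio, est * ratio
        if transform == "cloglog":
            # for an incidence p in (0,1): v = log(-log(1 - p))
            p = np.clip(est, 1e-300, 1 - 1e-12)
            v = np.log(-np.log1p(-p))
            dv = se / ((1.0 - p) * (-np.log1p(-p)))
            lo = -np.expm1(-np.exp(v - z * dv))
            hi = -np.expm1(-np.exp(v + z * dv))
            return np.where(se > 0, lo, est), np.where(se > 0, hi, est)
        if transform == "cloglog_survival":
            s = np.clip(est, 1e-300, 1 - 1e-12)
            v = np.log(-np.log(s))
            dv = se / (s * (-np.log(s)))
            # v increasing means S decreasing: swap bounds
            lo = np.exp(-np.exp(v + z * dv))
            hi = np.exp(-np.exp(v - z * dv))
            return np.where(se > 0, lo, est), np.where(se > 0, hi, est)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class PredictionResult:
    """A prediction over a time grid (or at a horizon) with SE and CI."""

    measure: str
    cause: int | None
    times: np.ndarray
    x: Mapping[str, float]
    estimate: np.ndarray
    se: np.ndarray
    lci: np.ndarray
    uci: np.ndarray
    level: float
    transform: str
    gradient: np.ndarray = field(repr=False, default=None)
    param_cov: np.ndarray = field(repr=False, default=None)

    def to_frame(self, label: str | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "measure": self.measure,
                "cause": self.cause if self.cause is not None else pd.NA,
                "time": self.times,
                "estimate": self.estimate,
                "se": self.se,
                "lci": self.lci,
                "uci": self.uci,
            }
        )
        df["setting"] = label if label is not None else _format_setting(self.x)
        return df


@dataclass
class ContrastResult:
    """Difference or ratio between two covariate settings."""

    type: str
    measure: str
    cause: int | None
    times: np.ndarray
    x1: Mapping[str, float]
    x0: Mapping[str, float]
    estimate: np.ndarray
    se: np.ndarray
    lci: np.ndarray
    uci: np.ndarray
    level: float

    def to_frame(self, label: str | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "measure": f"{self.measure}_{self.type}",
                "cause": self.cause if self.cause is not None else pd.NA,
                "time": self.times,
                "estimate": self.estimate,
                "se": self.se,
                "lci": self.lci,
                "uci": self.uci,
            }
        )
        df["setting"] = label if label is not None else (
            f"{_format_setting(self.x1)} vs {_format_setting(self.x0)}"
        )
        return df


def _format_setting(x: Mapping[str, float]) -> str:
    return ", ".join(f"{k}={v:g}" for k, v in x.items()) or "(baseline)"


def _finish(measure, cause, times, x, fn, models, transform, level, robust=None):
    theta, V, _ = _stack_params(models, robust)
    est = np.atleast_1d(np.asarray(fn(theta), float))
    G = _fd_jacobian(fn, theta)
    var = np.einsum("ip,pq,iq->i", G, V, G)
    se = np.sqrt(np.clip(var, 0.0, None))
    lci, uci = _ci(est, se, transform, level)
    return PredictionResult(
        measure=measure,
        cause=cause,
        times=np.atleast_1d(np.asarray(times, float)),
        x=dict(x),
        estimate=est,
        se=se,
        lci=lci,
        uci=uci,
        level=level,
        transform=transform,
        gradient=G,
        param_cov=V,
    )


# ---------------------------------------------------------------------------
# design pre-computation helpers
# ---------------------------------------------------------------------------

def _design_at(model: FittedModel, u: np.ndarray, x: Mapping[str, float]):
    """Design and ln-t-derivative matrices of one model at times ``u``."""
    return model.design.matrices(np.log(u), {k: float(v) for k, v in x.items()})


def _check_times(times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("prediction times must be positive and finite")
    return times


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def predict_cif_sdh(
    model: FittedModel,
    x: Mapping[str, float],
    times,
    level: float = 0.95,
    robust: bool | None = None,
) -> PredictionResult:
    """CIF from a subdistribution-scale model: ``F_k = 1 - exp(-exp(eta))``."""
    if model.spec.scale != "subdistribution":
        raise ValueError("predict_cif_sdh requires a subdistribution-scale model")
    times = _check_times(times)
    A, _ = _design_at(model, times, x)

    def fn(theta):
        return -np.expm1(-np.exp(A @ theta))

    return _finish("cif", model.spec.cause, times, x, fn, [model], "cloglog", level, robust)


def predict_csh(
    model: FittedModel,
    x: Mapping[str, float],
    times,
    level: float = 0.95,
    robust: bool | None = None,
) -> PredictionResult:
    """Cause-specific hazard ``h_k(t|x) = (d eta/d t) exp(eta)``."""
    if model.spec.scale != "cause_specific":
        raise ValueError("predict_csh requires a cause-specific-scale model")
    if not model.valid:
        raise ValueError("model fit is flagged invalid (non-positive hazard); refusing to predict")
    times = _check_times(times)
    A, D = _design_at(model, times, x)

    def fn(theta):
        return (D @ theta) / times * np.exp(A @ theta)

    return _finish("csh", model.spec.cause, times, x, fn, [model], "log", level, robust)


def predict_survival(
    models,
    x: Mapping[str, float],
    times,
    level: float = 0.95,
    robust: bool | None = None,
) -> PredictionResult:
    """All-cause survival ``S(t|x) = exp(-sum_k exp(eta_k(t|x)))`` (CSH scale)."""
    models = _as_models(models)
    if any(m.spec.scale != "cause_specific" for m in models):
        raise ValueError("predict_survival requires cause-specific-scale models")
    times = _check_times(times)
    designs = [_design_at(m, times, x)[0] for m in models]
    _, _, slices = _stack_params(models)

    def fn(theta):
        cum = sum(np.exp(A @ theta[sl]) for A, sl in zip(designs, slices))
        return np.exp(-cum)

    return _finish("survival", None, times, x, fn, models, "cloglog_survival", level, robust)


def _require_all_causes(models: Sequence[FittedModel]) -> None:
    causes = sorted(m.spec.cause for m in models)
    K = max(m.spec.cause for m in models)
    if causes != list(range(1, K + 1)):
        raise ValueError(f"need one cause-specific model per cause 1..K, got causes {causes}")


def predict_cif_csh(
    models,
    x: Mapping[str, float],
    times,
    rule: QuadratureRule | None = None,
    cause: int | None = None,
    level: float = 0.95,
    robust: bool | None = None,
):
    """CIF via the cause-specific route: ``F_k(t) = \\int_0^t S(u) h_k(u) du``.

    ``models`` must contain one cause-specific model per cause 1..K.  If
    ``cause`` is None, a list of results (one per cause) is returned.
    """
    models = _as_models(models)
    if any(m.spec.scale != "cause_specific" for m in models):
        raise ValueError("predict_cif_csh requires cause-specific-scale models")
    _require_all_causes(models)
    rule = rule or default_rule()
    times = _check_times(times)
    T, m = times.size, rule.m
    q = 0.5 * (rule.nodes + 1.0)
    qw = q * rule.weights  # u = t q^2 substitution: \int_0^t g = t sum qw g(t q^2)
    U = times[:, None] * q[None, :] ** 2  # (T, m) interior nodes
    Uf = U.ravel()
    mats = [_design_at(mod, Uf, x) for mod in models]
    _, _, slices = _stack_params(models)

    def cif_fn(k_idx):
        Ak, Dk = mats[k_idx]

        def fn(theta):
            cum = sum(np.exp(A @ theta[sl]) for (A, _), sl in zip(mats, slices))
            S = np.exp(-cum)
            h = (Dk @ theta[slices[k_idx]]) / Uf * np.exp(Ak @ theta[slices[k_idx]])
            f = (S * h).reshape(T, m)
            return times * (f @ qw)

        return fn

    results = []
    for k_idx, mod in enumerate(models):
        if cause is not None and mod.spec.cause != cause:
            continue
        results.append(
            _finish("cif", mod.spec.cause, times, x, cif_fn(k_idx), models, "cloglog", level, robust)
        )
    return results[0] if cause is not None else results


def _lyl_fns_csh(models, x, t_star, rule):
    """Per-cause LYL functionals from CSH models, nested quadrature."""
    m = rule.m
    q = 0.5 * (rule.nodes + 1.0)
    qw = q * rule.weights
    u_out = t_star * q**2  # (m,)
    V = u_out[:, None] * q[None, :] ** 2  # (m, m) inner nodes
    Vf = V.ravel()
    mats = [_design_at(mod, Vf, x) for mod in models]
    _, _, slices = _stack_params(models)

    def make(k_idx):
        Ak, Dk = mats[k_idx]

        def fn(theta):
            cum = sum(np.exp(A @ theta[sl]) for (A, _), sl in zip(mats, slices))
            S = np.exp(-cum)
            h = (Dk @ theta[slices[k_idx]]) / Vf * np.exp(Ak @ theta[slices[k_idx]])
            f = (S * h).reshape(m, m)
            F_out = u_out * (f @ qw)  # F_k at outer nodes
            return np.array([t_star * (qw @ F_out)])

        return fn

    return make


def _lyl_fn_sdh(model, x, t_star, rule):
    q = 0.5 * (rule.nodes + 1.0)
    qw = q * rule.weights
    u_out = t_star * q**2
    A, _ = _design_at(model, u_out, x)

    def fn(theta):
        F = -np.expm1(-np.exp(A @ theta))
        return np.array([t_star * (qw @ F)])

    return fn


def predict_lyl(
    models,
    x: Mapping[str, float],
    t_star: float,
    rule: QuadratureRule | None = None,
    cause: int | None = None,
    level: float = 0.95,
    robust: bool | None = None,
):
    """Expected life-years lost ``L_k(0, t*) = \\int_0^{t*} F_k(u|x) du``.

    From a single subdistribution model the integral is a single quadrature
    of the model CIF; from the set of cause-specific models the CIF itself
    is a quadrature, evaluated afresh at each outer node (nested rule).
    If ``cause`` is None and several models are given, one result per cause
    is returned.
    """
    t_star = float(t_star)
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    rule = rule or default_rule()
    single_input = isinstance(models, FittedModel)
    models = _as_models(models)
    scales = {m.spec.scale for m in models}
    if scales == {"subdistribution"}:
        results = []
        for mod in models:
            if cause is not None and mod.spec.cause != cause:
                continue
            fn = _lyl_fn_sdh(mod, x, t_star, rule)
            results.append(
                _finish("lyl", mod.spec.cause, [t_star], x, fn, [mod], "log", level, robust)
            )
    elif scales == {"cause_specific"}:
        _require_all_causes(models)
        make = _lyl_fns_csh(models, x, t_star, rule)
        results = []
        for k_idx, mod in enumerate(models):
            if cause is not None and mod.spec.cause != cause:
                continue
            results.append(
                _finish("lyl", mod.spec.cause, [t_star], x, make(k_idx), models, "log", level, robust)
            )
    else:
        raise ValueError("models must share a single scale")
    if cause is not None:
        if not results:
            raise ValueError(f"no model for cause {cause}")
        return results[0]
    return results[0] if single_input else results


def predict_rmst(
    models,
    x: Mapping[str, float],
    t_star: float,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
    robust: bool | None = None,
    method: str = "lyl",
) -> PredictionResult:
    """Restricted mean survival time ``mu(t*) = t* - sum_k L_k(0, t*)``.

    ``method="lyl"`` (default) subtracts the summed per-cause life-years
    lost; ``method="direct"`` integrates the all-cause survival function
    directly (cause-specific models only).  The two routes agree to
    quadrature accuracy.
    """
    t_star = float(t_star)
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    rule = rule or default_rule()
    models = _as_models(models)
    scales = {m.spec.scale for m in models}

    if method == "direct":
        if scales != {"cause_specific"}:
            raise ValueError("direct RMST integration requires cause-specific models")
        q = 0.5 * (rule.nodes + 1.0)
        qw = q * rule.weights
        u_out = t_star * q**2
        designs = [_design_at(m, u_out, x)[0] for m in models]
        _, _, slices = _stack_params(models)

        def fn(theta):
            cum = sum(np.exp(A @ theta[sl]) for A, sl in zip(designs, slices))
            S = np.exp(-cum)
            return np.array([t_star * (qw @ S)])

        return _finish("rmst", None, [t_star], x, fn, models, "log", level, robust)

    # mu = t* - sum_k L_k with all models jointly.
    if scales == {"cause_specific"}:
        _require_all_causes(models)
        make = _lyl_fns_csh(models, x, t_star, rule)
        lyl_fns = [make(i) for i in range(len(models))]
    elif scales == {"subdistribution"}:
        _require_all_causes(models)
        q = 0.5 * (rule.nodes + 1.0)
        qw = q * rule.weights
        u_out = t_star * q**2
        designs = [_design_at(m, u_out, x)[0] for m in models]
        _, _, slices = _stack_params(models)

        def make_sdh(i):
            def fn_i(theta):
                F = -np.expm1(-np.exp(designs[i] @ theta[slices[i]]))
                return np.array([t_star * (qw @ F)])

            return fn_i

        lyl_fns = [make_sdh(i) for i in range(len(models))]
    else:
        raise ValueError("models must share a single scale")

    def fn(theta):
        return np.array([t_star - sum(f(theta)[0] for f in lyl_fns)])

    return _finish("rmst", None, [t_star], x, fn, models, "log", level, robust)


def predict_rmft(
    models,
    x: Mapping[str, float],
    t_star: float,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
    robust: bool | None = None,
) -> PredictionResult:
    """Total restricted mean failure time ``L(0,t*) = sum_k L_k(0,t*)``."""
    res = predict_rmst(models, x, t_star, rule=rule, level=level, robust=robust)
    t_star = float(t_star)
    est = t_star - res.estimate
    se = res.se
    lci, uci = _ci(est, se, "log", res.level)
    return PredictionResult(
        measure="rmft_total",
        cause=None,
        times=res.times,
        x=res.x,
        estimate=est,
        se=se,
        lci=lci,
        uci=uci,
        level=res.level,
        transform="log",
        gradient=None if res.gradient is None else -res.gradient,
        param_cov=res.param_cov,
    )


# ---------------------------------------------------------------------------
# contrasts and generic delta method
# ---------------------------------------------------------------------------

def contrast(a: PredictionResult, b: PredictionResult, type: str = "difference") -> ContrastResult:
    """Difference ``a - b`` or ratio ``a / b`` with joint delta-method SE.

    Both predictions must come from the same model set (identical parameter
    covariance), measure, cause and time grid.
    """
    if type not in ("difference", "ratio"):
        raise ValueError(f"contrast type must be 'difference' or 'ratio', got {type!r}")
    if a.measure != b.measure or a.cause != b.cause:
        raise ValueError("contrast requires matching measures and causes")
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("contrast requires matching time grids")
    if a.gradient is None or b.gradient is None:
        raise ValueError("predictions lack stored gradients; recompute with CIs enabled")
    if a.param_cov.shape != b.param_cov.shape or not np.allclose(a.param_cov, b.param_cov):
        raise ValueError("predictions come from different model sets")
    V = a.param_cov
    if type == "difference":
        est = a.estimate - b.estimate
        G = a.gradient - b.gradient
        var = np.einsum("ip,pq,iq->i", G, V, G)
        se = np.sqrt(np.clip(var, 0.0, None))
        lci, uci = _ci(est, se, "identity", a.level)
    else:
        if np.any(b.estimate <= 0):
            raise ValueError("ratio contrast requires a positive denominator")
        est = a.estimate / b.estimate
        # delta on the log scale, back-transformed
        Glog = a.gradient / a.estimate[:, None] - b.gradient / b.estimate[:, None]
        var = np.einsum("ip,pq,iq->i", Glog, V, Glog)
        se_log = np.sqrt(np.clip(var, 0.0, None))
        z = stats.norm.ppf(0.5 + a.level / 2.0)
        lci = est * np.exp(-z * se_log)
        uci = est * np.exp(z * se_log)
        se = est * se_log
    return ContrastResult(
        type=type,
        measure=a.measure,
        cause=a.cause,
        times=a.times,
        x1=a.x,
        x0=b.x,
        estimate=est,
        se=se,
        lci=lci,
        uci=uci,
        level=a.level,
    )


def delta_method(
    fn: Callable,
    models,
    transform: str = "identity",
    level: float = 0.95,
    robust: bool | None = None,
):
    """Delta-method SE and CI of an arbitrary functional of model parameters.

    ``fn`` maps the stacked parameter vector of ``models`` to a scalar or
    vector.  Returns ``(estimate, se, lci, uci)``.
    """
    models = _as_models(models)
    theta, V, _ = _stack_params(models, robust)
    if not np.all(np.isfinite(V)):
        raise ValueError("parameter covariance contains non-finite entries")
    eig = np.linalg.eigvalsh(0.5 * (V + V.T))
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("parameter covariance is not positive semi-definite")
    est = np.atleast_1d(np.asarray(fn(theta), float))
    G = _fd_jacobian(fn, theta)
    var = np.einsum("ip,pq,iq->i", G, V, G)
    se = np.sqrt(np.clip(var, 0.0, None))
    lci, uci = _ci(est, se, transform, level)
    return est, se, lci, uci
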