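"""Regression standardisation (G-formula) for marginal predictions.

Marginal estimates average individual-level model predictions over the
observed covariate distribution while an intervention covariate ``X`` is
fixed: for each individual ``i`` the prediction is computed at
``(X = x, Z = z_i)`` and the N predictions averaged,

    E(mu^stand | X = x, Z) = (1/N) sum_i mu_i.

With all exposures and confounders measured at baseline this is the
G-formula.  Variance treats the covariate distribution as fixed
(conditional-on-sample inference): the delta method is applied to the
averaged functional, i.e. with the averaged gradient.  Estimation of the
censoring weights is not accounted for.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalDataset
from .model import FittedModel
from .predict import (
    ContrastResult,
    PredictionResult,
    _as_models,
    _ci,
    _fd_jacobian,
    _require_all_causes,
    _stack_params,
    default_rule,
)
from .quadrature import QuadratureRule

__all__ = ["standardized_measure", "standardized_contrast"]


def _population_frame(population, models: Sequence[FittedModel]) -> pd.DataFrame:
    if isinstance(population, SurvivalDataset):
        df = population.frame
    elif isinstance(population, pd.DataFrame):
        df = population
    else:
        raise TypeError("population must be a SurvivalDataset or DataFrame")
    needed = sorted({c for m in models for c in m.spec.covariates})
    missing = [c for c in needed if c not in df]
    if missing:
        raise ValueError(f"population is missing covariate columns {missing}")
    if len(df) < 1:
        raise ValueError("population must contain at least one individual")
    return df[needed].reset_index(drop=True) if needed else df.iloc[:, :0].reset_index(drop=True)


class _Standardizer:
    """Precomputed designs for averaging individual predictions.

    Evaluation points are laid out per individual once at construction
    (chunked over individuals to bound memory); each call with a parameter
    vector is then a matrix product.
    """

    def __init__(
        self,
        models: Sequence[FittedModel],
        Z: pd.DataFrame,
        intervention: Mapping[str, float],
        eval_times: np.ndarray,
        need_deriv: bool,
        chunk: int,
    ):
        self.models = list(models)
        self.E = np.asarray(eval_times, float)  # flattened per-individual eval points
        self.n_eval = self.E.size
        N = len(Z)
        self.N = N
        Zi = Z.copy()
        for cov, val in intervention.items():
            Zi[cov] = float(val)
        self.chunks = []
        for lo in range(0, N, chunk):
            hi = min(lo + chunk, N)
            nb = hi - lo
            logt = np.log(np.tile(self.E, nb))
            mats = []
            for m in self.models:
                X = {
                    c: np.repeat(Zi[c].to_numpy(float)[lo:hi], self.n_eval)
                    if c in Zi
                    else np.zeros(nb * self.n_eval)
                    for c in m.spec.covariates
                }
                A, D = m.design.matrices(logt, X)
                mats.append((A, D if need_deriv else None))
            self.chunks.append((nb, mats))

    def eta(self, mats_idx: int, chunk_idx: int, theta_k: np.ndarray):
        nb, mats = self.chunks[chunk_idx]
        A, _ = mats[mats_idx]
        return (A @ theta_k).reshape(nb, self.n_eval)

    def eta_dlnt(self, mats_idx: int, chunk_idx: int, theta_k: np.ndarray):
        nb, mats = self.chunks[chunk_idx]
        _, D = mats[mats_idx]
        return (D @ theta_k).reshape(nb, self.n_eval)


def _collapse_population(Z: pd.DataFrame, w: np.ndarray | None):
    """Collapse duplicate covariate rows into weights (exact, saves work)."""
    if Z.shape[1] == 0:
        total = float(len(Z)) if w is None else float(np.sum(w))
        return Z.head(1), np.array([total])
    Zw = Z.copy()
    Zw["_w"] = 1.0 if w is None else np.asarray(w, float)
    grouped = Zw.groupby(list(Z.columns), dropna=False, sort=False, as_index=False)["_w"].sum()
    if len(grouped) == len(Z):
        return Z, w
    return grouped[list(Z.columns)], grouped["_w"].to_numpy()


def _mean_over(values: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return values.mean(axis=0)
    w = weights / weights.sum()
    return w @ values


def _build_functional(
    models: Sequence[FittedModel],
    Z: pd.DataFrame,
    intervention: Mapping[str, float],
    measure: str,
    cause: int | None,
    times: np.ndarray | None,
    t_star: float | None,
    rule: QuadratureRule,
    weights: np.ndarray | None,
    chunk: int,
):
    """Return ``(fn, out_times)`` with ``fn(theta) -> standardised estimates``."""
    scales = {m.spec.scale for m in models}
    if len(scales) != 1:
        raise ValueError("models must share a single scale")
    scale = scales.pop()
    _, _, slices = _stack_params(models)
    m = rule.m

    if measure == "cif":
        if times is None:
            raise ValueError("measure 'cif' requires a time grid")
        times = np.atleast_1d(np.asarray(times, float))
        if scale == "subdistribution":
            idx = _model_index(models, cause)
            st = _Standardizer(models, Z, intervention, times, False, chunk)

            def fn(theta):
                acc = []
                for ci in range(len(st.chunks)):
                    eta = st.eta(idx, ci, theta[slices[idx]])
                    acc.append(-np.expm1(-np.exp(eta)))
                return _mean_over(np.vstack(acc), weights)

            return fn, times
        # cause-specific route: F_k(t) by quadrature per time point
        _require_all_causes(models)
        idx = _model_index(models, cause)
        T = times.size
        q = 0.5 * (rule.nodes + 1.0)
        qw = q * rule.weights  # u = t q^2 substitution for [0, t] integrals
        U = (times[:, None] * q[None, :] ** 2).ravel()  # (T*m,)
        st = _Standardizer(models, Z, intervention, U, True, chunk)

        def fn(theta):
            acc = []
            for ci in range(len(st.chunks)):
                nb = st.chunks[ci][0]
                cum = sum(
                    np.exp(st.eta(j, ci, theta[slices[j]])) for j in range(len(models))
                )
                S = np.exp(-cum)
                h = st.eta_dlnt(idx, ci, theta[slices[idx]]) / U * np.exp(
                    st.eta(idx, ci, theta[slices[idx]])
                )
                f = (S * h).reshape(nb, T, m)
                acc.append(times * (f @ qw))
            return _mean_over(np.vstack(acc), weights)

        return fn, times

    if measure not in ("rmst", "rmft_total", "lyl"):
        raise ValueError(f"unknown standardised measure {measure!r}")
    if t_star is None or t_star <= 0:
        raise ValueError(f"measure {measure!r} requires a positive horizon t_star")
    t_star = float(t_star)
    q = 0.5 * (rule.nodes + 1.0)
    qw = q * rule.weights
    u_out = t_star * q**2

    if scale == "subdistribution":
        _require_all_causes(models)
        st = _Standardizer(models, Z, intervention, u_out, False, chunk)

        def lyl_chunk(ci, theta, j):
            F = -np.expm1(-np.exp(st.eta(j, ci, theta[slices[j]])))
            return t_star * (F @ qw)

        if measure == "lyl":
            idx = _model_index(models, cause)

            def fn(theta):
                acc = [lyl_chunk(ci, theta, idx) for ci in range(len(st.chunks))]
                return np.atleast_1d(_mean_over(np.concatenate(acc), weights))

        else:

            def fn(theta):
                acc = [
                    sum(lyl_chunk(ci, theta, j) for j in range(len(models)))
                    for ci in range(len(st.chunks))
                ]
                tot = np.atleast_1d(_mean_over(np.concatenate(acc), weights))
                return t_star - tot if measure == "rmst" else tot

        return fn, np.array([t_star])

    # cause-specific route: rmst is t* - sum_k lyl_k so that the partition
    # identity holds exactly; lyl needs F_k at the outer nodes, hence the
    # nested quadrature below
    V = (u_out[:, None] * q[None, :] ** 2).ravel()  # (m*m,)
    st = _Standardizer(models, Z, intervention, V, True, chunk)

    def lyl_chunk(ci, theta, j):
        nb = st.chunks[ci][0]
        cum = sum(np.exp(st.eta(jj, ci, theta[slices[jj]])) for jj in range(len(models)))
        S = np.exp(-cum)
        h = st.eta_dlnt(j, ci, theta[slices[j]]) / V * np.exp(st.eta(j, ci, theta[slices[j]]))
        f = (S * h).reshape(nb, m, m)
        F_out = u_out * (f @ qw)  # (nb, m)
        return t_star * (F_out @ qw)

    if measure == "lyl":
        idx = _model_index(models, cause)

        def fn(theta):
            acc = [lyl_chunk(ci, theta, idx) for ci in range(len(st.chunks))]
            return np.atleast_1d(_mean_over(np.concatenate(acc), weights))

    else:

        def fn(theta):
            acc = [
                sum(lyl_chunk(ci, theta, j) for j in range(len(models)))
                for ci in range(len(st.chunks))
            ]
            tot = np.atleast_1d(_mean_over(np.concatenate(acc), weights))
            return tot if measure == "rmft_total" else t_star - tot

    return fn, np.array([t_star])


def _model_index(models: Sequence[FittedModel], cause: int | None) -> int:
    if cause is None:
        if len(models) == 1:
            return 0
        raise ValueError("cause must be given when several models are supplied")
    for i, m in enumerate(models):
        if m.spec.cause == cause:
            return i
    raise ValueError(f"no model for cause {cause}")


_TRANSFORMS = {"cif": "cloglog", "rmst": "log", "rmft_total": "log", "lyl": "log"}


def standardized_measure(
    models,
    population,
    intervention: Mapping[str, float],
    measure: str,
    *,
    cause: int | None = None,
    times=None,
    t_star: float | None = None,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
    robust: bool | None = None,
    weights=None,
    chunk: int = 512,
) -> PredictionResult:
    """Regression-standardised (marginal) prediction.

    The intervention covariates are fixed to the given values for every
    individual in ``population`` (the analysis data by default; an external
    reference population with optional per-row ``weights`` is accepted) and
    the individual predictions averaged.
    """
    models = _as_models(models)
    rule = rule or default_rule()
    Z = _population_frame(population, models)
    for cov in intervention:
        if not any(cov in m.spec.covariates for m in models):
            raise ValueError(f"intervention covariate {cov!r} is not in any model")
    w = None if weights is None else np.asarray(weights, float)
    if w is not None and (w.size != len(Z) or np.any(w < 0) or w.sum() <= 0):
        raise ValueError("weights must be non-negative, one per individual, with positive sum")
    Z, w = _collapse_population(Z, w)
    fn, out_times = _build_functional(
        models, Z, intervention, measure, cause, times, t_star, rule, w, chunk
    )
    theta, Vp, _ = _stack_params(models, robust)
    est = np.atleast_1d(np.asarray(fn(theta), float))
    G = _fd_jacobian(fn, theta)
    var = np.einsum("ip,pq,iq->i", G, Vp, G)
    se = np.sqrt(np.clip(var, 0.0, None))
    lci, uci = _ci(est, se, _TRANSFORMS[measure], level)
    return PredictionResult(
        measure=measure,
        cause=cause,
        times=out_times,
        x=dict(intervention),
        estimate=est,
        se=se,
        lci=lci,
        uci=uci,
        level=level,
        transform=_TRANSFORMS[measure],
        gradient=G,
        param_cov=Vp,
    )


def standardized_contrast(
    models,
    population,
    x1: Mapping[str, float],
    x0: Mapping[str, float],
    measure: str,
    *,
    type: str = "difference",
    cause: int | None = None,
    times=None,
    t_star: float | None = None,
    rule: QuadratureRule | None = None,
    level: float = 0.95,
    robust: bool | None = None,
    weights=None,
    chunk: int = 512,
) -> ContrastResult:
    """Difference or ratio of standardised measures with joint delta SE."""
    if type not in ("difference", "ratio"):
        raise ValueError(f"contrast type must be 'difference' or 'ratio', got {type!r}")
    models = _as_models(models)
    rule = rule or default_rule()
    Z = _population_frame(population, models)
    w = None if weights is None else np.asarray(weights, float)
    Z, w = _collapse_population(Z, w)
    fn1, out_times = _build_functional(
        models, Z, x1, measure, cause, times, t_star, rule, w, chunk
    )
    fn0, _ = _build_functional(models, Z, x0, measure, cause, times, t_star, rule, w, chunk)
    theta, Vp, _ = _stack_params(models, robust)

    if type == "difference":
        def fn(th):
            return np.atleast_1d(fn1(th)) - np.atleast_1d(fn0(th))

        est = np.atleast_1d(fn(theta))
        G = _fd_jacobian(fn, theta)
        var = np.einsum("ip,pq,iq->i", G, Vp, G)
        se = np.sqrt(np.clip(var, 0.0, None))
        lci, uci = _ci(est, se, "identity", level)
    else:
        e1 = np.atleast_1d(fn1(theta))
        e0 = np.atleast_1d(fn0(theta))
        if np.any(e0 <= 0):
            raise ValueError("ratio contrast requires a positive denominator")

        def fn_log(th):
            return np.log(np.atleast_1d(fn1(th))) - np.log(np.atleast_1d(fn0(th)))

        est = e1 / e0
        G = _fd_jacobian(fn_log, theta)
        var = np.einsum("ip,pq,iq->i", G, Vp, G)
        se_log = np.sqrt(np.clip(var, 0.0, None))
        z = stats.norm.ppf(0.5 + level / 2.0)
        lci = est * np.exp(-z * se_log)
        uci = est * np.exp(z * se_log)
        se = est * se_log
    return ContrastResult(
        type=type,
        measure=measure,
        cause=cause,
        times=out_times,
        x1=dict(x1),
        x0=dict(x0),
        estimate=est,
        se=se,
        lci=lci,
        uci=uci,
        level=level,
    )
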