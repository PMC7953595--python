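"""Maximum-likelihood fitting of flexible parametric survival models.

The model places a restricted cubic spline of log time on the log
cumulative-hazard scale with a complementary log-log link:

    eta(t | x) = s(ln t; gamma, m0) + x beta' + sum_l s(ln t; alpha_l, m_l) x_l

On the cause-specific scale ``eta = log H_k^cs(t | x)``; on the
subdistribution scale (fitted to weighted, risk-set-expanded data)
``eta = log H_k^sd(t | x)`` so that ``F_k = 1 - exp(-exp(eta))``.
Time-dependent effects enter as covariate-by-spline interactions.

The log-likelihood over rows with intervals ``(tstart, tstop]``, event flags
``d`` and weights ``w`` is

    l = sum_i w_i [ d_i (log(d eta/d t |_{tstop_i}) + eta(tstop_i))
                    - exp(eta(tstop_i)) + 1{tstart_i > 0} exp(eta(tstart_i)) ]

with ``d eta/d t = s'(ln t)/t`` by the chain rule.  The hazard must be
positive at event times; during the search a smooth penalised surrogate for
``log`` keeps the objective finite, and a fit whose final hazard is not
positive at every event time is flagged invalid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import splines
from .data import ExpandedDataset, SurvivalDataset, expand_subdistribution

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "StackedFittedModel",
    "ConvergenceError",
    "fit",
    "fit_stacked",
    "loglikelihood",
    "prepare",
    "lr_test",
]

# Hazard-positivity barrier: below this slope the log is replaced by a
# quadratic surrogate so the search can recover from infeasible iterates.
_SLOPE_FLOOR = 1e-8
_ETA_CLIP = 60.0  # exp(60) ~ 1e26 dominates any likelihood; avoids overflow
_EVENT_FLOOR = 10


class ConvergenceError(RuntimeError):
    """Optimiser failed to reach a stationary point."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one flexible parametric (sub)hazard model.

    Parameters
    ----------
    scale : {"cause_specific", "subdistribution"}
        Link target: log cumulative cause-specific hazard, or log cumulative
        subdistribution hazard (fitted on weighted expanded data).
    cause : int
        Cause of interest (1..K).
    baseline_df : int
        Degrees of freedom of the baseline log-time spline (knots at equally
        spaced centiles of the uncensored cause-specific log event times).
    baseline_knots : sequence of float, optional
        Explicit baseline knots on the *time* scale (overrides ``baseline_df``).
    covariates : sequence of str
        Covariate columns entering linearly (spline-of-covariate terms are
        pre-computed columns, e.g. age splines).
    tvc : mapping str -> int
        Time-dependent effects: covariate name to spline df.  Knots default
        to centiles of the same uncensored log event times, sharing the
        boundary knots with the baseline.
    tvc_knots : mapping str -> sequence of float
        Explicit time-scale knots per time-dependent effect.
    intercept, baseline : bool
        Internal switches used by the stacked simultaneous fit, where the
        per-cause intercepts and baselines are carried by cause dummies.
    orthogonalise : bool
        Orthogonalise spline bases (default on, for conditioning); the
        projection is stored with the model so raw and orthogonalised
        parameterisations give identical fits.
    """

    scale: str
    cause: int = 1
    baseline_df: int = 2
    baseline_knots: tuple | None = None
    covariates: tuple = ()
    tvc: Mapping[str, int] = field(default_factory=dict)
    tvc_knots: Mapping[str, tuple] = field(default_factory=dict)
    intercept: bool = True
    baseline: bool = True
    orthogonalise: bool = True

    def __post_init__(self) -> None:
        if self.scale not in ("cause_specific", "subdistribution"):
            raise ValueError(f"unknown scale {self.scale!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "tvc", dict(self.tvc))
        object.__setattr__(
            self, "tvc_knots", {k: tuple(v) for k, v in dict(self.tvc_knots).items()}
        )
        if self.baseline_knots is not None:
            object.__setattr__(self, "baseline_knots", tuple(self.baseline_knots))
        unknown = set(self.tvc) - set(self.covariates)
        if unknown:
            raise ValueError(f"tvc covariates {sorted(unknown)} are not model covariates")
        for name, df in self.tvc.items():
            if int(df) < 1:
                raise ValueError(f"tvc df for {name!r} must be >= 1")


class Design:
    """Maps (log time, covariates) to the model design and its ln-t derivative."""

    def __init__(
        self,
        spec: ModelSpec,
        baseline_spec: splines.SplineBasisSpec | None,
        tvc_specs: Mapping[str, splines.SplineBasisSpec],
    ):
        self.spec = spec
        self.baseline_spec = baseline_spec
        self.tvc_specs = dict(tvc_specs)
        names: list[str] = []
        if spec.intercept:
            names.append("_cons")
        if baseline_spec is not None:
            names.extend(f"_rcs{j + 1}" for j in range(baseline_spec.ncol))
        names.extend(spec.covariates)
        for cov, sp in self.tvc_specs.items():
            names.extend(f"{cov}_rcs{j + 1}" for j in range(sp.ncol))
        self.names = names

    @property
    def n_params(self) -> int:
        return len(self.names)

    def matrices(self, log_t: np.ndarray, X: Mapping[str, np.ndarray]):
        """Return ``(A, D)`` with ``eta = A theta`` and ``d eta/d ln t = D theta``."""
        log_t = np.asarray(log_t, dtype=float)
        n = log_t.size
        cols, dcols = [], []
        if self.spec.intercept:
            cols.append(np.ones((n, 1)))
            dcols.append(np.zeros((n, 1)))
        if self.baseline_spec is not None:
            cols.append(splines.rcs_design(log_t, self.baseline_spec))
            dcols.append(splines.rcs_derivative(log_t, self.baseline_spec))
        for cov in self.spec.covariates:
            x = np.broadcast_to(np.asarray(X[cov], dtype=float), (n,))
            cols.append(x[:, None])
            dcols.append(np.zeros((n, 1)))
        for cov, sp in self.tvc_specs.items():
            x = np.broadcast_to(np.asarray(X[cov], dtype=float), (n,))
            cols.append(splines.rcs_design(log_t, sp) * x[:, None])
            dcols.append(splines.rcs_derivative(log_t, sp) * x[:, None])
        return np.hstack(cols), np.hstack(dcols)


@dataclass
class ModelData:
    """Prepared arrays for likelihood evaluation of one model."""

    design: Design
    A1: np.ndarray  # design at tstop
    D1: np.ndarray  # d/d ln t at tstop
    A0: np.ndarray  # design at tstart, rows with tstart > 0 only
    idx0: np.ndarray  # row indices for A0
    d: np.ndarray
    w: np.ndarray
    log_tstop: np.ndarray
    ids: np.ndarray
    tstart: np.ndarray = None

    @property
    def n_events(self) -> int:
        return int(np.sum(self.d > 0))

    def loglik_grad(self, theta: np.ndarray):
        """Penalised log-likelihood and analytic gradient."""
        theta = np.asarray(theta, dtype=float)
        eta1 = np.clip(self.A1 @ theta, -_ETA_CLIP, _ETA_CLIP)
        H1 = np.exp(eta1)
        ev = self.d > 0
        c = self.D1[ev] @ theta
        good = c > _SLOPE_FLOOR
        z = (c - _SLOPE_FLOOR) / _SLOPE_FLOOR
        logc = np.where(good, np.log(np.where(good, c, 1.0)), np.log(_SLOPE_FLOOR) + z - 0.5 * z**2)
        dlogc = np.where(good, 1.0 / np.where(good, c, 1.0), (1.0 - z) / _SLOPE_FLOOR)
        we = self.w[ev]
        ll = float(
            we @ (logc - self.log_tstop[ev] + eta1[ev]) - self.w @ H1
        )
        grad = (
            (we * dlogc) @ self.D1[ev]
            + we @ self.A1[ev]
            - (self.w * H1) @ self.A1
        )
        if self.idx0.size:
            eta0 = np.clip(self.A0 @ theta, -_ETA_CLIP, _ETA_CLIP)
            H0 = np.exp(eta0)
            w0 = self.w[self.idx0]
            ll += float(w0 @ H0)
            grad = grad + (w0 * H0) @ self.A0
        return ll, grad

    def hazard_positive(self, theta: np.ndarray) -> bool:
        c = self.D1[self.d > 0] @ np.asarray(theta, dtype=float)
        return bool(np.all(c > 0))

    def score_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Per-row score contributions (for clustered sandwich variance)."""
        theta = np.asarray(theta, dtype=float)
        eta1 = np.clip(self.A1 @ theta, -_ETA_CLIP, _ETA_CLIP)
        H1 = np.exp(eta1)
        S = -(self.w * H1)[:, None] * self.A1
        ev = self.d > 0
        c = self.D1[ev] @ theta
        S[ev] += self.w[ev, None] * (self.D1[ev] / c[:, None] + self.A1[ev])
        if self.idx0.size:
            eta0 = np.clip(self.A0 @ theta, -_ETA_CLIP, _ETA_CLIP)
            S[self.idx0] += (self.w[self.idx0] * np.exp(eta0))[:, None] * self.A0
        return S


def loglikelihood(params: Sequence[float], prepared: ModelData) -> float:
    """Weighted log-likelihood at ``params`` for a prepared design."""
    ll, _ = prepared.loglik_grad(np.asarray(params, dtype=float))
    return ll


def _rows_from_data(data, spec: ModelSpec):
    """Extract (tstart, tstop, d, w, covariate frame, ids) rows for a fit."""
    if isinstance(data, ExpandedDataset):
        if spec.scale != "subdistribution":
            raise ValueError("expanded data is for subdistribution-scale fits")
        if data.cause != spec.cause:
            raise ValueError(
                f"expanded data is for cause {data.cause}, spec asks for {spec.cause}"
            )
        f = data.frame
        return (
            f["tstart"].to_numpy(float),
            f["tstop"].to_numpy(float),
            f["event"].to_numpy(int),
            f["weight"].to_numpy(float),
            f,
            f["id"].to_numpy(),
        )
    if isinstance(data, SurvivalDataset):
        f = data.frame
        t = f["time"].to_numpy(float)
        d = (f["cause"].to_numpy(int) == spec.cause).astype(int)
        w = f["weight"].to_numpy(float) if "weight" in f else np.ones(t.size)
        return np.zeros(t.size), t, d, w, f, f["id"].to_numpy()
    raise TypeError(f"unsupported data type {type(data).__name__}")


def prepare(data, spec: ModelSpec) -> ModelData:
    """Build the design and prepared arrays for one model.

    Baseline (and time-dependent-effect) knots are placed on the uncensored
    cause-specific log event times; orthogonalisation projections are
    computed over all row stop-times and stored in the design.
    """
    tstart, tstop, d, w, frame, ids = _rows_from_data(data, spec)
    if np.any(tstop <= 0):
        raise ValueError("all stop times must be positive")
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    missing = [c for c in spec.covariates if c not in frame]
    if missing:
        raise ValueError(f"covariate columns {missing} not present in the data")
    log_stop = np.log(tstop)
    log_events = log_stop[d > 0]

    baseline_spec = None
    if spec.baseline:
        if spec.baseline_knots is not None:
            kv = splines.KnotVector(
                knots=tuple(np.log(np.asarray(spec.baseline_knots, float))), source="user"
            )
        else:
            kv = splines.make_knots(log_events, spec.baseline_df)
        baseline_spec = splines.build_spec(kv, log_stop, orthogonalise=spec.orthogonalise)
    tvc_specs = {}
    for cov, df_e in spec.tvc.items():
        if cov in spec.tvc_knots:
            kv = splines.KnotVector(
                knots=tuple(np.log(np.asarray(spec.tvc_knots[cov], float))), source="user"
            )
        else:
            kv = splines.make_knots(log_events, int(df_e))
        tvc_specs[cov] = splines.build_spec(kv, log_stop, orthogonalise=spec.orthogonalise)

    design = Design(spec, baseline_spec, tvc_specs)
    X = {c: frame[c].to_numpy(float) for c in spec.covariates}
    A1, D1 = design.matrices(log_stop, X)
    idx0 = np.flatnonzero(tstart > 0)
    if idx0.size:
        X0 = {c: frame[c].to_numpy(float)[idx0] for c in spec.covariates}
        A0, _ = design.matrices(np.log(tstart[idx0]), X0)
    else:
        A0 = np.empty((0, design.n_params))
    return ModelData(
        design=design,
        A1=A1,
        D1=D1,
        A0=A0,
        idx0=idx0,
        d=np.asarray(d, int),
        w=np.asarray(w, float),
        log_tstop=log_stop,
        ids=np.asarray(ids),
        tstart=np.asarray(tstart, float),
    )


def _check_rank(md: ModelData) -> None:
    r = np.abs(np.diag(np.linalg.qr(md.A1, mode="r")))
    tol = r.max() * max(md.A1.shape) * np.finfo(float).eps
    bad = [md.design.names[j] for j in np.flatnonzero(r < tol)]
    if bad:
        raise ValueError(f"design is rank deficient; collinear column(s): {bad}")


def _nelson_aalen(md: ModelData, max_points: int = 200):
    """Weighted Nelson-Aalen cumulative hazard at event times (for starts)."""
    ev = md.d > 0
    tau = np.unique(np.exp(md.log_tstop[ev]))
    tstop = np.exp(md.log_tstop)
    tstart = np.zeros_like(tstop)
    tstart[md.idx0] = md.tstart[md.idx0]
    # Risk set Y(tau) = sum w [tstart < tau <= tstop]
    stop_sorted = np.sort(tstop)
    w_stop_cum = np.concatenate([[0.0], np.cumsum(md.w[np.argsort(tstop, kind="stable")])])
    start_sorted = np.sort(tstart)
    w_start_cum = np.concatenate([[0.0], np.cumsum(md.w[np.argsort(tstart, kind="stable")])])
    lost = w_stop_cum[np.searchsorted(stop_sorted, tau, side="left")]
    entered = w_start_cum[np.searchsorted(start_sorted, tau, side="left")]
    Y = entered - lost
    dN = np.zeros(tau.size)
    np.add.at(dN, np.searchsorted(tau, tstop[ev]), md.w[ev])
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.cumsum(np.where(Y > 0, dN / Y, 0.0))
    keep = H > 0
    tau, H = tau[keep], H[keep]
    if tau.size > max_points:
        sel = np.unique(np.round(np.linspace(0, tau.size - 1, max_points)).astype(int))
        tau, H = tau[sel], H[sel]
    return tau, H


def _initial_values(md: ModelData) -> np.ndarray:
    """Start from a cloglog-of-Nelson-Aalen regression on the design."""
    theta0 = np.zeros(md.design.n_params)
    try:
        tau, H = _nelson_aalen(md)
        if tau.size >= 2:
            ev = md.d > 0
            # regress log H at each event row's stop time on that row's design
            y_row = np.interp(md.log_tstop[ev], np.log(tau), np.log(H))
            Arows = md.A1[ev]
            theta0, *_ = np.linalg.lstsq(Arows, y_row, rcond=None)
    except Exception:  # pragma: no cover - fall back to zeros
        logger.debug("Nelson-Aalen initialisation failed; starting from zeros")
    return theta0


def _numeric_hessian(md_grad, theta: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian of the log-likelihood."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        _, gp = md_grad(tp)
        tm = theta.copy()
        tm[j] -= h
        _, gm = md_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


@dataclass
class FittedModel:
    """A fitted flexible parametric (sub)hazard model."""

    spec: ModelSpec
    design: Design
    params: np.ndarray
    names: list
    vcov: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    valid: bool
    robust_vcov: np.ndarray | None = None
    convergence: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.params.size

    def covariance(self, robust: bool | None = None) -> np.ndarray:
        """Model-based or clustered-sandwich covariance.

        Defaults to the sandwich estimate when available (weighted
        subdistribution fits), else the inverse observed information.
        """
        if robust is None:
            robust = self.robust_vcov is not None
        if robust:
            if self.robust_vcov is None:
                raise ValueError("no robust covariance stored for this model")
            return self.robust_vcov
        return self.vcov

    def linear_predictor(self, times, x: Mapping[str, float], params=None) -> np.ndarray:
        """eta(t | x) on the model's scale (log cumulative (sub)hazard)."""
        times = np.asarray(times, dtype=float)
        if np.any(times <= 0):
            raise ValueError("times must be positive")
        A, _ = self.design.matrices(np.log(times), x)
        theta = self.params if params is None else np.asarray(params, float)
        return A @ theta

    def linear_predictor_dlnt(self, times, x: Mapping[str, float], params=None) -> np.ndarray:
        """d eta / d ln t at the requested times."""
        times = np.asarray(times, dtype=float)
        _, D = self.design.matrices(np.log(times), x)
        theta = self.params if params is None else np.asarray(params, float)
        return D @ theta

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        def spline_payload(sp: splines.SplineBasisSpec | None):
            if sp is None:
                return None
            return {
                "knots_time": list(np.exp(sp.knots.knots)),
                "source": sp.knots.source,
                "orthogonalise": sp.orthogonalise,
                "projection": None if sp.projection is None else sp.projection.tolist(),
            }

        spec = asdict(self.spec)
        spec["tvc"] = dict(self.spec.tvc)
        spec["tvc_knots"] = {k: list(v) for k, v in self.spec.tvc_knots.items()}
        from . import __version__

        return {
            "format": "fpcrisk-model-v1",
            "version": __version__,
            "spec": spec,
            "baseline_spline": spline_payload(self.design.baseline_spec),
            "tvc_splines": {k: spline_payload(v) for k, v in self.design.tvc_specs.items()},
            "names": list(self.names),
            "params": self.params.tolist(),
            "vcov": self.vcov.tolist(),
            "robust_vcov": None if self.robust_vcov is None else self.robust_vcov.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "valid": self.valid,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FittedModel":
        def spline_from(p):
            if p is None:
                return None
            kv = splines.KnotVector(
                knots=tuple(np.log(np.asarray(p["knots_time"], float))), source=p["source"]
            )
            proj = None if p["projection"] is None else np.asarray(p["projection"], float)
            return splines.SplineBasisSpec(
                knots=kv, orthogonalise=p["orthogonalise"], projection=proj
            )

        spec_d = dict(payload["spec"])
        spec = ModelSpec(
            scale=spec_d["scale"],
            cause=spec_d["cause"],
            baseline_df=spec_d["baseline_df"],
            baseline_knots=spec_d.get("baseline_knots"),
            covariates=tuple(spec_d.get("covariates", ())),
            tvc=dict(spec_d.get("tvc", {})),
            tvc_knots=dict(spec_d.get("tvc_knots", {})),
            intercept=spec_d.get("intercept", True),
            baseline=spec_d.get("baseline", True),
            orthogonalise=spec_d.get("orthogonalise", True),
        )
        design = Design(
            spec,
            spline_from(payload["baseline_spline"]),
            {k: spline_from(v) for k, v in payload["tvc_splines"].items()},
        )
        robust = payload.get("robust_vcov")
        return cls(
            spec=spec,
            design=design,
            params=np.asarray(payload["params"], float),
            names=list(payload["names"]),
            vcov=np.asarray(payload["vcov"], float),
            robust_vcov=None if robust is None else np.asarray(robust, float),
            loglik=float(payload["loglik"]),
            n=int(payload["n"]),
            n_events=int(payload["n_events"]),
            converged=bool(payload["converged"]),
            valid=bool(payload["valid"]),
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _optimise(md: ModelData, init: np.ndarray):
    def neg(theta):
        ll, g = md.loglik_grad(theta)
        return -ll, -g

    res = optimize.minimize(neg, init, jac=True, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-7})
    ll, g = md.loglik_grad(res.x)
    tol = 1e-4 * (1.0 + abs(ll))
    if np.max(np.abs(g)) > tol or not md.hazard_positive(res.x):
        # Nelder-Mead restart, then quasi-Newton polish.
        res_nm = optimize.minimize(lambda th: -md.loglik_grad(th)[0], res.x,
                                   method="Nelder-Mead",
                                   options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(neg, res_nm.x, jac=True, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-7})
        ll, g = md.loglik_grad(res.x)
    converged = bool(np.max(np.abs(g)) <= tol)
    return res.x, ll, g, converged


def fit(
    data,
    spec: ModelSpec,
    *,
    robust: bool | None = None,
    init: Sequence[float] | None = None,
    event_floor: int = _EVENT_FLOOR,
    expand_kwargs: Mapping | None = None,
) -> FittedModel:
    """Fit one flexible parametric model by maximum likelihood.

    ``data`` is a :class:`SurvivalDataset` (cause-specific scale, or
    subdistribution scale -- expanded internally with Kaplan-Meier censoring
    weights) or an :class:`ExpandedDataset` prepared by the caller.  The
    covariance is the inverse observed information (finite-difference
    Hessian); for weighted subdistribution fits a cluster-robust sandwich
    covariance (clustered on subject id) is additionally stored and used by
    default, since the censoring weights are estimated.
    """
    if spec.scale == "subdistribution" and isinstance(data, SurvivalDataset):
        data = expand_subdistribution(data, spec.cause, **dict(expand_kwargs or {}))
    md = prepare(data, spec)
    if md.n_events < event_floor:
        raise ValueError(
            f"only {md.n_events} events of cause {spec.cause}; "
            f"at least {event_floor} required"
        )
    _check_rank(md)
    theta0 = np.asarray(init, float) if init is not None else _initial_values(md)
    theta, ll, g, converged = _optimise(md, theta0)
    if not converged:
        raise ConvergenceError(
            f"fit did not converge: max |score| = {np.max(np.abs(g)):.3g} "
            f"at loglik {ll:.6f} (params {theta.round(4).tolist()})"
        )
    valid = md.hazard_positive(theta)
    if not valid:
        logger.warning("fitted hazard is not positive at all event times; fit flagged invalid")
    H = _numeric_hessian(md.loglik_grad, theta)
    vcov = _safe_inverse(-H)
    want_robust = robust if robust is not None else (spec.scale == "subdistribution")
    robust_vcov = None
    if want_robust:
        S = md.score_matrix(theta)
        G = pd.DataFrame(S).groupby(md.ids, sort=False).sum().to_numpy()
        meat = G.T @ G
        robust_vcov = vcov @ meat @ vcov
        robust_vcov = 0.5 * (robust_vcov + robust_vcov.T)
    return FittedModel(
        spec=spec,
        design=md.design,
        params=theta,
        names=list(md.design.names),
        vcov=vcov,
        robust_vcov=robust_vcov,
        loglik=ll,
        n=int(np.unique(md.ids).size),
        n_events=md.n_events,
        converged=converged,
        valid=valid,
        convergence={"max_score": float(np.max(np.abs(g)))},
    )


def _safe_inverse(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    try:
        Minv = linalg.inv(M)
    except linalg.LinAlgError:
        Minv = linalg.pinvh(M)
    return 0.5 * (Minv + Minv.T)


@dataclass
class StackedFittedModel:
    """Simultaneous fit of all K causes on stacked/expanded data.

    Parameters are fully cause-specific (cause dummies carry the per-cause
    intercepts and baselines), so the joint likelihood separates and the
    coefficients coincide with separate per-cause fits.
    """

    models: list
    params: np.ndarray
    vcov: np.ndarray
    loglik: float
    slices: list

    def extract(self, cause: int) -> FittedModel:
        """Per-cause :class:`FittedModel` view (parameters and vcov block)."""
        return self.models[cause - 1]


def fit_stacked(
    data: SurvivalDataset,
    specs: Sequence[ModelSpec],
    *,
    robust: bool | None = None,
    expand_kwargs: Mapping | None = None,
) -> StackedFittedModel:
    """Fit models for all K causes simultaneously on restructured data.

    Each cause keeps its own baseline knots (placed on its own event times)
    and parameters; the data are stacked so a single likelihood is maximised
    over the concatenated parameter vector, mirroring the Lunn-McNeil /
    simultaneous-stpm2 route.
    """
    K = data.n_causes
    if len(specs) != K:
        raise ValueError(f"need one spec per cause: {K} specs, got {len(specs)}")
    mds = []
    for k, spec in enumerate(specs, start=1):
        if spec.cause != k:
            raise ValueError("specs must be ordered by cause 1..K")
        d_k = data
        if spec.scale == "subdistribution":
            d_k = expand_subdistribution(data, k, **dict(expand_kwargs or {}))
        mds.append(prepare(d_k, spec))
    offsets = np.cumsum([0] + [md.design.n_params for md in mds])
    slices = [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]

    def joint_loglik_grad(theta):
        ll = 0.0
        grads = []
        for md, sl in zip(mds, slices):
            l_k, g_k = md.loglik_grad(theta[sl])
            ll += l_k
            grads.append(g_k)
        return ll, np.concatenate(grads)

    init = np.concatenate([_initial_values(md) for md in mds])

    def neg(theta):
        ll, g = joint_loglik_grad(theta)
        return -ll, -g

    res = optimize.minimize(neg, init, jac=True, method="BFGS",
                            options={"maxiter": 1000, "gtol": 1e-7})
    theta = res.x
    ll, g = joint_loglik_grad(theta)
    tol = 1e-4 * (1.0 + abs(ll))
    if np.max(np.abs(g)) > tol:
        raise ConvergenceError(f"stacked fit did not converge: max |score| = {np.max(np.abs(g)):.3g}")
    Hess = _numeric_hessian(joint_loglik_grad, theta)
    vcov = _safe_inverse(-Hess)
    models = []
    for k, (md, sl, spec) in enumerate(zip(mds, slices, specs), start=1):
        th_k = theta[sl]
        ll_k, _ = md.loglik_grad(th_k)
        want_robust = robust if robust is not None else (spec.scale == "subdistribution")
        robust_vcov = None
        v_k = vcov[sl, sl]
        if want_robust:
            S = md.score_matrix(th_k)
            G = pd.DataFrame(S).groupby(md.ids, sort=False).sum().to_numpy()
            robust_vcov = v_k @ (G.T @ G) @ v_k
            robust_vcov = 0.5 * (robust_vcov + robust_vcov.T)
        models.append(
            FittedModel(
                spec=spec,
                design=md.design,
                params=th_k,
                names=list(md.design.names),
                vcov=v_k,
                robust_vcov=robust_vcov,
                loglik=ll_k,
                n=int(np.unique(md.ids).size),
                n_events=md.n_events,
                converged=True,
                valid=md.hazard_positive(th_k),
            )
        )
    return StackedFittedModel(models=models, params=theta, vcov=vcov, loglik=ll, slices=slices)


def lr_test(full: FittedModel, reduced: FittedModel):
    """Likelihood-ratio test of nested models fitted to the same data.

    Returns ``(statistic, df, p)`` with ``statistic = 2 (l_full - l_reduced)``
    and a chi-squared upper-tail p-value.
    """
    stat = 2.0 * (full.loglik - reduced.loglik)
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("the full model must have at least as many parameters as the reduced")
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): models are not nested or fits not converged"
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p
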