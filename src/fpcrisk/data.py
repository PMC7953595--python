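"""Subject-level competing-risks data: validation and restructuring.

A :class:`SurvivalDataset` holds one row per subject with follow-up time
``T > 0``, cause of death ``D`` (0 = censored, 1..K = causes) and named
covariates.  Two restructurings support model fitting:

* :func:`expand_subdistribution` -- the weighted-data (Geskus / Fine-Gray)
  route for models on the subdistribution-hazard scale.  Subjects failing
  from a competing cause remain in the cause-k risk set after their failure
  time, down-weighted by the ratio of censoring-survival probabilities
  ``G(t-) / G(T_i-)``.
* :func:`stack_causes` -- the Lunn-McNeil stacking for fitting all K
  cause-specific models simultaneously, with cause dummies and
  covariate-by-cause interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "SurvivalDataset",
    "ExpandedDataset",
    "StackedDataset",
    "load_and_validate",
    "apply_followup_window",
    "expand_subdistribution",
    "stack_causes",
    "collapse_stack",
    "censoring_survival_km",
]

RESERVED = ("id", "time", "cause", "tstart", "tstop", "event", "weight")


class ValidationError(ValueError):
    """Input data failed validation; ``errors`` lists one message per issue."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... and {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} validation error(s):\n  {preview}{more}")


@dataclass
class SurvivalDataset:
    """One row per subject: id, time, cause (0..K) and covariates."""

    frame: pd.DataFrame
    n_causes: int
    covariates: tuple = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        missing = [c for c in ("id", "time", "cause", *self.covariates) if c not in self.frame]
        if missing:
            raise ValueError(f"dataset frame is missing columns {missing}")

    @property
    def n(self) -> int:
        return len(self.frame)

    def event_counts(self) -> dict:
        """Number of subjects per cause code (0 = censored)."""
        counts = self.frame["cause"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in range(self.n_causes + 1)}

    def report(self) -> dict:
        """Validation/summary report: counts by cause and covariate summaries."""
        summaries = {}
        for cov in self.covariates:
            col = self.frame[cov]
            summaries[cov] = {
                "mean": float(col.mean()),
                "sd": float(col.std()),
                "min": float(col.min()),
                "max": float(col.max()),
            }
        return {
            "n": self.n,
            "n_causes": self.n_causes,
            "events_by_cause": self.event_counts(),
            "covariates": summaries,
        }


@dataclass
class ExpandedDataset:
    """Weighted risk-set expansion for one cause on the subdistribution scale.

    Rows carry an interval ``(tstart, tstop]``, an event flag for the cause
    of interest at ``tstop`` and a censoring weight in ``(0, 1]``.
    """

    frame: pd.DataFrame
    cause: int
    n_causes: int
    covariates: tuple = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)


@dataclass
class StackedDataset:
    """K rows per subject with cause dummies and covariate interactions."""

    frame: pd.DataFrame
    n_causes: int
    covariates: tuple = ()
    cause_dummies: tuple = ()
    interactions: Mapping[str, tuple] = field(default_factory=dict)


def _validate_frame(df: pd.DataFrame, covariates: Sequence[str], n_causes: int) -> list:
    errors = []
    t = pd.to_numeric(df["time"], errors="coerce")
    bad = df.loc[~np.isfinite(t) | (t <= 0), "id"]
    errors.extend(f"subject {i}: non-positive or non-finite time" for i in bad)
    d = pd.to_numeric(df["cause"], errors="coerce")
    bad = df.loc[~np.isfinite(d) | (d != d.round()) | (d < 0) | (d > n_causes), "id"]
    errors.extend(f"subject {i}: cause code outside 0..{n_causes}" for i in bad)
    for cov in covariates:
        x = pd.to_numeric(df[cov], errors="coerce")
        bad = df.loc[~np.isfinite(x), "id"]
        errors.extend(f"subject {i}: missing or non-numeric covariate {cov!r}" for i in bad)
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()[:5]
        errors.append(f"duplicated subject ids (e.g. {list(dups)})")
    return errors


def load_and_validate(
    path,
    schema: Mapping[str, object] | None = None,
    n_causes: int | None = None,
) -> SurvivalDataset:
    """Load a delimited text file into a validated :class:`SurvivalDataset`.

    ``schema`` maps the standard names to file columns, e.g.
    ``{"id": "patid", "time": "exit", "cause": "cod", "covariates": ["sex", "age"]}``.
    Column names equal to the standard names may be omitted.  ``n_causes``
    defaults to the largest cause code observed.

    Raises :class:`ValidationError` with one itemised message per offending
    row (non-positive times, unknown cause codes, missing covariates).
    """
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    covs = list(schema.pop("covariates", []))
    rename = {v: k for k, v in schema.items() if isinstance(v, str)}
    df = raw.rename(columns=rename)
    missing = [c for c in ("id", "time", "cause") if c not in df]
    if missing:
        raise ValidationError([f"required column {c!r} not found" for c in missing])
    if not covs:
        covs = [c for c in df.columns if c not in RESERVED]
    else:
        absent = [c for c in covs if c not in df]
        if absent:
            raise ValidationError([f"covariate column {c!r} not found" for c in absent])
    df = df[["id", "time", "cause", *covs]].copy()
    cause_codes = pd.to_numeric(df["cause"], errors="coerce")
    if n_causes is None:
        n_causes = int(np.nanmax(cause_codes)) if np.isfinite(np.nanmax(cause_codes)) else 1
        n_causes = max(n_causes, 1)
    errors = _validate_frame(df, covs, n_causes)
    if errors:
        raise ValidationError(errors)
    df["time"] = df["time"].astype(float)
    df["cause"] = df["cause"].astype(int)
    for cov in covs:
        df[cov] = df[cov].astype(float)
    return SurvivalDataset(frame=df.reset_index(drop=True), n_causes=n_causes, covariates=tuple(covs))


def from_arrays(
    time,
    cause,
    covariates: Mapping[str, Sequence[float]] | None = None,
    n_causes: int | None = None,
    ids=None,
) -> SurvivalDataset:
    """Build a validated dataset from in-memory arrays (used by the simulator)."""
    time = np.asarray(time, dtype=float)
    cause = np.asarray(cause, dtype=int)
    covariates = dict(covariates or {})
    if ids is None:
        ids = np.arange(1, time.size + 1)
    df = pd.DataFrame({"id": ids, "time": time, "cause": cause, **covariates})
    if n_causes is None:
        n_causes = max(int(cause.max()), 1)
    errors = _validate_frame(df, list(covariates), n_causes)
    if errors:
        raise ValidationError(errors)
    return SurvivalDataset(frame=df, n_causes=n_causes, covariates=tuple(covariates))


def apply_followup_window(data: SurvivalDataset, max_follow: float) -> SurvivalDataset:
    """Administratively censor follow-up at ``max_follow``.

    Subjects with ``T > max_follow`` are censored at the window; an event
    exactly at the boundary is retained as an event (censoring wins only
    strictly beyond the window).
    """
    max_follow = float(max_follow)
    if max_follow <= 0:
        raise ValueError("max_follow must be positive")
    df = data.frame.copy()
    over = df["time"] > max_follow
    df.loc[over, "time"] = max_follow
    df.loc[over, "cause"] = 0
    return SurvivalDataset(frame=df, n_causes=data.n_causes, covariates=data.covariates)


class _StepSurvival:
    """Right-continuous step survival curve with left-limit evaluation."""

    def __init__(self, jump_times: np.ndarray, surv_after: np.ndarray):
        self.jump_times = np.asarray(jump_times, dtype=float)
        self.surv_after = np.asarray(surv_after, dtype=float)

    def left(self, t) -> np.ndarray:
        """S(t-): the survival just before ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left")
        vals = np.concatenate([[1.0], self.surv_after])
        return vals[idx]

    def right(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        vals = np.concatenate([[1.0], self.surv_after])
        return vals[idx]


def censoring_survival_km(data: SurvivalDataset) -> _StepSurvival:
    """Kaplan-Meier estimate of the censoring survival ``G``.

    Censorings (``cause == 0``) are the events; deaths from any cause are
    treated as censored observations of the censoring time.  At tied times
    deaths precede censorings, so the risk set at a censoring time ``t`` is
    ``#{T_i >= t}``.
    """
    t = data.frame["time"].to_numpy(float)
    is_cens = data.frame["cause"].to_numpy(int) == 0
    times, d_cens = np.unique(t[is_cens], return_counts=True)
    if times.size == 0:
        return _StepSurvival(np.array([]), np.array([]))
    order = np.sort(t)
    n = t.size
    n_at_risk = n - np.searchsorted(order, times, side="left")
    surv = np.cumprod(1.0 - d_cens / n_at_risk)
    return _StepSurvival(times, surv)


def expand_subdistribution(
    data: SurvivalDataset,
    cause: int,
    censoring_model: str = "km",
    censoring_df: int = 3,
    censoring_covariates: Sequence[str] = (),
    max_intervals: int | None = None,
) -> ExpandedDataset:
    """Risk-set expansion with time-dependent censoring weights (Geskus).

    Subjects failing from a competing cause remain at risk of cause ``k``
    after their failure time ``T_i``; their follow-up is split at subsequent
    distinct cause-k event times, with the interval ending at ``t`` weighted
    by ``G(t-) / G(T_i-)`` where ``G`` is the censoring-survival estimate.
    All other subjects carry weight 1 on their own observation window.

    ``censoring_model`` is ``"km"`` (Kaplan-Meier, default) or ``"fpm"`` (a
    flexible parametric model of the censoring distribution with
    ``censoring_df`` baseline df and optional covariates, the parametric
    route).  ``max_intervals`` caps the number of split intervals per
    subject by thinning the split-time grid (weights are then piecewise
    approximations; useful for very large datasets).
    """
    k = int(cause)
    if not 1 <= k <= data.n_causes:
        raise ValueError(f"cause must be in 1..{data.n_causes}, got {k}")
    t = data.frame["time"].to_numpy(float)
    d = data.frame["cause"].to_numpy(int)
    if not np.any(d == k):
        raise ValueError(f"no events of cause {k} in the data")

    if censoring_model == "km":
        G = censoring_survival_km(data)

        def g_left(times, _row):
            return G.left(times)

    elif censoring_model == "fpm":
        from . import model as _model  # deferred: model depends on this module

        cens_data = SurvivalDataset(
            frame=data.frame.copy(), n_causes=data.n_causes, covariates=data.covariates
        )
        cens_frame = cens_data.frame
        # Recode: censoring is the event of interest; deaths censor it.
        cens_frame = cens_frame.assign(cause=np.where(d == 0, 1, 0))
        cens_data = SurvivalDataset(frame=cens_frame, n_causes=1, covariates=data.covariates)
        spec = _model.ModelSpec(
            scale="cause_specific",
            cause=1,
            baseline_df=int(censoring_df),
            covariates=tuple(censoring_covariates),
        )
        cens_fit = _model.fit(cens_data, spec)

        def g_left(times, row):
            # Parametric G is continuous: left limit equals the value.
            x = {c: float(row[c]) for c in censoring_covariates}
            eta = cens_fit.linear_predictor(np.asarray(times, float), x)
            return np.exp(-np.exp(eta))

    else:
        raise ValueError(f"unknown censoring_model {censoring_model!r}")

    event_times_k = np.unique(t[(d == k)])

    # Every subject contributes their own observation window at weight 1.
    own = data.frame[["id", *data.covariates]].copy()
    own.insert(1, "tstart", 0.0)
    own.insert(2, "tstop", t)
    own.insert(3, "event", (d == k).astype(int))
    own.insert(4, "weight", 1.0)
    pieces = [own]

    # Competing failures stay at risk through later cause-k event times.
    warned = False
    competing = data.frame[(d != 0) & (d != k)]
    acc = {c: [] for c in ("id", "tstart", "tstop", "weight", *data.covariates)}
    for idx_row in range(len(competing)):
        row = competing.iloc[idx_row]
        Ti = float(row["time"])
        splits = event_times_k[event_times_k > Ti]
        if splits.size == 0:
            continue
        if max_intervals is not None and splits.size > max_intervals:
            sel = np.unique(
                np.round(np.linspace(0, splits.size - 1, max_intervals)).astype(int)
            )
            splits = splits[sel]
        g_ti = float(np.atleast_1d(g_left([Ti], row))[0])
        g_t = np.atleast_1d(g_left(splits, row)).astype(float)
        w = np.ones_like(g_t) if g_ti <= 0.0 else g_t / g_ti
        if np.any(w <= 0.0):
            if not warned:
                logger.warning(
                    "censoring survival reached 0 before the last cause-%d event time; "
                    "weights truncated at the last positive value",
                    k,
                )
                warned = True
            pos = w > 0.0
            w[~pos] = w[pos][-1] if np.any(pos) else 1.0
        # merge consecutive equal-weight intervals (weights only change at
        # censoring-distribution jumps, so this collapses most splits)
        keep = np.empty(w.size, dtype=bool)
        keep[0] = True
        np.not_equal(w[1:], w[:-1], out=keep[1:])
        starts = np.concatenate([[Ti], splits[:-1]])[keep]
        stops = np.append(splits[np.flatnonzero(keep)[1:] - 1], splits[-1])
        acc["id"].append(np.full(starts.size, row["id"]))
        acc["tstart"].append(starts)
        acc["tstop"].append(stops)
        acc["weight"].append(w[keep])
        for c in data.covariates:
            acc[c].append(np.full(starts.size, float(row[c])))
    if acc["id"]:
        extra = pd.DataFrame({c: np.concatenate(v) for c, v in acc.items()})
        extra["event"] = 0
        pieces.append(extra)
    frame = pd.concat(pieces, ignore_index=True)
    frame = frame.sort_values(["id", "tstart"], kind="stable").reset_index(drop=True)
    frame = frame[["id", "tstart", "tstop", "event", "weight", *data.covariates]]
    return ExpandedDataset(frame=frame, cause=k, n_causes=data.n_causes, covariates=data.covariates)


def stack_causes(data: SurvivalDataset) -> StackedDataset:
    """Lunn-McNeil stacking: K rows per subject with cause-specific dummies.

    Each covariate ``x`` generates interaction columns ``x_cause1 ..
    x_causeK`` equal to ``x`` on the matching cause row and 0 elsewhere.
    The event flag is 1 only on the row matching the subject's cause.
    """
    K = data.n_causes
    if K < 2:
        raise ValueError("stacking requires K >= 2 causes")
    pieces = []
    dummies = tuple(f"_cause{k}" for k in range(1, K + 1))
    interactions = {cov: tuple(f"{cov}_cause{k}" for k in range(1, K + 1)) for cov in data.covariates}
    for k in range(1, K + 1):
        piece = data.frame[["id", "time", "cause", *data.covariates]].copy()
        piece["at_risk_cause"] = k
        piece["event"] = (piece["cause"] == k).astype(int)
        for kk, name in enumerate(dummies, start=1):
            piece[name] = float(kk == k)
        for cov in data.covariates:
            for kk in range(1, K + 1):
                piece[f"{cov}_cause{kk}"] = piece[cov] * float(kk == k)
        pieces.append(piece)
    frame = (
        pd.concat(pieces, ignore_index=True)
        .sort_values(["id", "at_risk_cause"], kind="stable")
        .reset_index(drop=True)
    )
    return StackedDataset(
        frame=frame,
        n_causes=K,
        covariates=data.covariates,
        cause_dummies=dummies,
        interactions=interactions,
    )


def collapse_stack(stacked: StackedDataset) -> SurvivalDataset:
    """Invert :func:`stack_causes`, recovering the subject-level dataset."""
    df = stacked.frame
    first = df.groupby("id", sort=False).first().reset_index()
    events = df[df["event"] == 1].set_index("id")["at_risk_cause"]
    first["cause"] = first["id"].map(events).fillna(0).astype(int)
    out = first[["id", "time", "cause", *stacked.covariates]]
    return SurvivalDataset(frame=out, n_causes=stacked.n_causes, covariates=stacked.covariates)
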