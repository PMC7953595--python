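"""Restricted cubic splines of log time.

The flexible parametric (Royston-Parmar) model places a restricted cubic
spline (RCS) in ``ln(t)`` on the log cumulative-hazard scale.  Given a
strictly increasing knot vector ``m_1 < ... < m_M`` on the log-time scale,
the basis has ``M - 1`` columns

    z_1 = ln(t)
    z_j = (ln t - m_j)_+^3 - phi_j (ln t - m_1)_+^3 - (1 - phi_j)(ln t - m_M)_+^3

for ``j = 2, ..., M - 1`` with ``phi_j = (m_M - m_j) / (m_M - m_1)``, so the
spline is linear beyond the boundary knots.  Knots default to equally spaced
centiles of the uncensored log event times, with boundary knots at the 0th
and 100th centiles.

Basis columns can optionally be orthogonalised (Gram-Schmidt against the
intercept, zero mean, unit scale) for numerical conditioning; the projection
matrix is fixed at construction and re-applied verbatim at new evaluation
times so that fitted models are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KnotVector",
    "SplineBasisSpec",
    "DegenerateKnotsError",
    "make_knots",
    "build_spec",
    "rcs_design",
    "rcs_derivative",
]


class DegenerateKnotsError(ValueError):
    """Raised when the requested knots collapse (too few distinct times)."""


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knots on the log-time scale.

    ``source`` records whether the knots were derived from data centiles or
    supplied by the user (relevant for serialisation / audit).
    """

    knots: tuple
    source: str = "centile"

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 2:
            raise ValueError(f"a knot vector needs at least 2 knots, got {len(knots)}")
        if not all(np.isfinite(knots)):
            raise ValueError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise DegenerateKnotsError(f"knots must be strictly increasing, got {knots}")
        if self.source not in ("centile", "user"):
            raise ValueError(f"unknown knot source {self.source!r}")

    @property
    def M(self) -> int:
        return len(self.knots)

    @property
    def df(self) -> int:
        """Degrees of freedom of the associated basis (``M - 1``)."""
        return len(self.knots) - 1


@dataclass(frozen=True)
class SplineBasisSpec:
    """A knot vector plus (optional) stored orthogonalisation projection.

    When ``orthogonalise`` is set the raw basis ``[1, z_1, ..., z_{M-1}]`` is
    multiplied by the stored ``(M x M)`` projection matrix and the intercept
    column dropped, yielding mean-zero, unit-scale columns orthogonal to the
    intercept over the construction sample.  The same projection is applied
    at any new evaluation times.
    """

    knots: KnotVector
    orthogonalise: bool = False
    projection: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.projection is not None:
            proj = np.asarray(self.projection, dtype=float)
            p = self.knots.M
            if proj.shape != (p, p):
                raise ValueError(
                    f"projection must be {p}x{p} for {p - 1} basis columns, got {proj.shape}"
                )
            if not np.all(np.isfinite(proj)) or abs(np.linalg.det(proj)) < 1e-300:
                raise ValueError("projection matrix must be finite and invertible")
            object.__setattr__(self, "projection", proj)
        if self.orthogonalise and self.projection is None:
            raise ValueError("orthogonalise=True requires a stored projection matrix")

    @property
    def ncol(self) -> int:
        return self.knots.df


def make_knots(
    event_log_times: Sequence[float],
    df: int,
    boundary: tuple[float, float] | None = None,
) -> KnotVector:
    """Place ``df + 1`` knots at equally spaced centiles of the log event times.

    Boundary knots sit at the 0th and 100th centiles (min and max) unless
    ``boundary`` overrides them.  Centiles use the inclusive
    linear-interpolation quantile definition (numpy ``method='linear'``);
    this convention is fixed for format stability.
    """
    df = int(df)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    x = np.asarray(event_log_times, dtype=float)
    if x.size == 0:
        raise ValueError("no event times supplied for knot placement")
    if not np.all(np.isfinite(x)):
        raise ValueError("event log-times must be finite")
    if np.unique(x).size < df + 1:
        raise DegenerateKnotsError(
            f"need at least {df + 1} distinct uncensored times for df={df}, "
            f"got {np.unique(x).size}"
        )
    centiles = np.linspace(0.0, 100.0, df + 1)
    knots = np.percentile(x, centiles, method="linear")
    if boundary is not None:
        lo, hi = float(boundary[0]), float(boundary[1])
        knots[0], knots[-1] = lo, hi
        interior = knots[1:-1]
        if interior.size and (np.any(interior <= lo) or np.any(interior >= hi)):
            raise DegenerateKnotsError(
                "interior knots fall outside the supplied boundary knots"
            )
    return KnotVector(knots=tuple(knots), source="centile")


def _raw_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    m = np.asarray(knots, dtype=float)
    M = m.size
    out = np.empty((x.size, M - 1), dtype=float)
    out[:, 0] = x
    if M > 2:
        span = m[-1] - m[0]
        lo = np.maximum(x - m[0], 0.0) ** 3
        hi = np.maximum(x - m[-1], 0.0) ** 3
        for j in range(1, M - 1):
            phi = (m[-1] - m[j]) / span
            out[:, j] = np.maximum(x - m[j], 0.0) ** 3 - phi * lo - (1.0 - phi) * hi
    return out


def _raw_deriv(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    m = np.asarray(knots, dtype=float)
    M = m.size
    out = np.empty((x.size, M - 1), dtype=float)
    out[:, 0] = 1.0
    if M > 2:
        span = m[-1] - m[0]
        lo = np.maximum(x - m[0], 0.0) ** 2
        hi = np.maximum(x - m[-1], 0.0) ** 2
        for j in range(1, M - 1):
            phi = (m[-1] - m[j]) / span
            out[:, j] = 3.0 * (
                np.maximum(x - m[j], 0.0) ** 2 - phi * lo - (1.0 - phi) * hi
            )
    return out


def build_spec(
    knots: KnotVector,
    log_times: Sequence[float] | None = None,
    orthogonalise: bool = True,
) -> SplineBasisSpec:
    """Construct a basis spec, computing the projection from ``log_times``.

    The projection is the inverse R factor of a QR decomposition of
    ``[1, z_1, ..., z_{M-1}]`` over the construction sample, scaled so the
    transformed intercept column is identically one and the remaining
    columns have mean zero and unit scale.
    """
    if not orthogonalise:
        return SplineBasisSpec(knots=knots, orthogonalise=False, projection=None)
    if log_times is None:
        raise ValueError("orthogonalisation requires construction-time log_times")
    x = np.asarray(log_times, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_times must be finite")
    Z = _raw_basis(x, knots.knots)
    X = np.column_stack([np.ones(x.size), Z])
    _, R = np.linalg.qr(X)
    # Fix signs so the transform of the intercept column is +1.
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    R = R * sign[:, None]
    R = R / np.sqrt(x.size)
    if np.min(np.abs(np.diag(R))) < 1e-12 * np.max(np.abs(np.diag(R))):
        raise ValueError("basis columns are collinear over the construction sample")
    proj = np.linalg.inv(R)
    return SplineBasisSpec(knots=knots, orthogonalise=True, projection=proj)


def rcs_design(log_times: Sequence[float], spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the RCS basis columns ``z_1 .. z_{M-1}`` at ``log_times``.

    The intercept is *not* included; model code carries it separately.  With
    orthogonalisation the stored projection is applied and the (constant)
    transformed intercept column dropped.
    """
    x = np.asarray(log_times, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_times must be finite")
    Z = _raw_basis(x, spec.knots.knots)
    if spec.orthogonalise:
        X = np.column_stack([np.ones(x.size), Z])
        Z = (X @ spec.projection)[:, 1:]
    return Z


def rcs_derivative(log_times: Sequence[float], spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate ``d z_j / d ln t`` at ``log_times`` (projection applied)."""
    x = np.asarray(log_times, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_times must be finite")
    dZ = _raw_deriv(x, spec.knots.knots)
    if spec.orthogonalise:
        # The transform is linear, so the derivative transforms the same way
        # with a zero column in place of the intercept.
        X = np.column_stack([np.zeros(x.size), dZ])
        dZ = (X @ spec.projection)[:, 1:]
    return dZ
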