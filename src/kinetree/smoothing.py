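"""Derivative estimation for concentration time series.

Rate estimation by gradient matching needs the time derivative of every
metabolite's concentration curve.  Two estimators are provided:

* forward finite differences on the measurement grid, and
* penalized B-splines (P-splines): a B-spline least-squares fit with a
  difference penalty on the coefficients controlling smoothness, whose
  first derivative is evaluated analytically anywhere in the window.

The P-spline basis is cubic with knots at the data points; with fewer
than four observations the degree drops to the largest the data support.
The penalty weight can be fixed or chosen by leave-one-out
cross-validation, which is deterministic given the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "TimeSeriesData",
    "DerivativeEstimate",
    "PSpline",
    "fit_pspline",
    "finite_difference_derivatives",
    "derivatives_at",
]


@dataclass(frozen=True)
class TimeSeriesData:
    """Concentration matrix (nodes x times) on a strictly increasing grid."""

    times: np.ndarray
    X: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if X.shape != (len(self.labels), times.size):
            raise ValueError(
                f"X shape {X.shape} does not match "
                f"({len(self.labels)} labels, {times.size} times)"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("concentrations must be finite (no missing entries)")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_times(self) -> int:
        return self.times.size

    def row(self, label: str) -> np.ndarray:
        return self.X[self.labels.index(label)]

    def reordered(self, labels: Sequence[str]) -> "TimeSeriesData":
        """Rows rearranged to a given label order (e.g. a network's nodes)."""
        idx = [self.labels.index(l) for l in labels]
        return TimeSeriesData(self.times, self.X[idx], tuple(labels))


@dataclass(frozen=True)
class DerivativeEstimate:
    """Estimated dX/dt on an evaluation grid, with the smoothers that made it."""

    times: np.ndarray
    Xdot: np.ndarray
    labels: tuple[str, ...]
    method: Literal["finite_difference", "pspline", "exact"]
    smoothers: tuple["PSpline", ...] = field(default=(), repr=False)


def _greville_abscissae(knots: np.ndarray, degree: int) -> np.ndarray:
    """Greville sites: the knot averages at which each B-spline 'lives'."""
    if degree == 0:
        return 0.5 * (knots[:-1] + knots[1:])
    return np.array([
        knots[i + 1 : i + degree + 1].mean()
        for i in range(knots.size - degree - 1)
    ])


def _divided_difference_matrix(sites: np.ndarray, order: int) -> np.ndarray:
    """Divided-difference operator of the given order over irregular sites.

    Using divided rather than plain differences keeps polynomials up to
    ``order - 1`` in the penalty null space even when the knots (hence
    Greville sites) are non-uniform, so e.g. a second-order penalty shrinks
    exactly toward the straight-line fit.
    """
    D = np.eye(sites.size)
    x = sites.astype(float)
    for _ in range(order):
        step = x[1:] - x[:-1]
        D = (D[1:] - D[:-1]) / step[:, None]
        x = 0.5 * (x[1:] + x[:-1])
    # rescale to plain-difference magnitude so penalty weights keep their
    # classic meaning and huge weights stay numerically benign
    if sites.size > 1:
        hbar = float(np.mean(np.diff(sites)))
        D = D * hbar**order
    return D


class PSpline:
    """Penalized B-spline smoother for one scalar series.

    Minimizes ``||y - B c||^2 + penalty * ||D_d c||^2`` where ``B`` is the
    B-spline design matrix and ``D_d`` the d-th order divided-difference
    operator over the Greville sites (second order by default, so very
    large penalties shrink toward the straight-line fit).
    """

    def __init__(
        self,
        t: np.ndarray,
        y: np.ndarray,
        penalty: float | Literal["auto"] = "auto",
        degree: int = 3,
        diff_order: int = 2,
    ) -> None:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size != y.size or t.size < 2:
            raise ValueError("need matching t/y with at least two points")
        if isinstance(penalty, (int, float)) and penalty < 0:
            raise ValueError("penalty must be non-negative")
        m = t.size
        if m < degree + 1:
            degree = m - 1
            warnings.warn(
                f"only {m} points: reducing spline degree to {degree}",
                stacklevel=2,
            )
        self.degree = degree
        self.diff_order = min(diff_order, degree) if degree > 0 else 0
        # interior knots at the data points, trimmed not-a-knot style so the
        # basis has exactly m functions: an unpenalized fit interpolates with
        # a unique, boundary-stable solution
        trim = max((degree + 1) // 2, 1)
        interior = t[trim:-trim] if t.size > 2 * trim else t[1:-1][:0]
        self.knots = np.concatenate(
            [np.repeat(t[0], degree + 1), interior, np.repeat(t[-1], degree + 1)]
        )
        self._t, self._y = t, y
        design = BSpline.design_matrix(t, self.knots, degree).toarray()
        self._design = design
        ncoef = design.shape[1]
        self._D = _divided_difference_matrix(
            _greville_abscissae(self.knots, degree), self.diff_order
        ) if ncoef > self.diff_order else np.zeros((0, ncoef))
        if penalty == "auto":
            penalty = self._loocv_penalty()
        self.penalty = float(penalty)
        self.coefficients = self._solve(self.penalty)
        self._spline = BSpline(self.knots, self.coefficients, degree)
        self._dspline = self._spline.derivative() if degree >= 1 else None

    def _solve(self, lam: float) -> np.ndarray:
        B, D, y = self._design, self._D, self._y
        if lam == 0.0:
            # saturated basis: minimum-norm least squares interpolates
            return np.linalg.lstsq(B, y, rcond=None)[0]
        # augmented (QR-based) form stays accurate for extreme penalties
        # where the normal equations lose half the digits
        aug = np.vstack([B, np.sqrt(lam) * D])
        rhs = np.concatenate([y, np.zeros(D.shape[0])])
        return np.linalg.lstsq(aug, rhs, rcond=None)[0]

    def _loocv_penalty(self, grid: np.ndarray | None = None) -> float:
        """Leave-one-out CV over a log-spaced penalty grid (deterministic).

        Each held-out point is predicted from an explicit refit on the
        remaining points; the hat-matrix shortcut is avoided because it
        degenerates when a small penalty makes the fit interpolating.
        Boundary points are never held out -- predicting them is
        extrapolation, which would bias the selection toward
        over-smoothing.
        """
        if grid is None:
            grid = np.logspace(-4, 4, 17)
        B, D, y = self._design, self._D, self._y
        m = y.size
        P = lambda lam: lam * (D.T @ D)
        best_lam, best_score = grid[0], np.inf
        for lam in grid:
            pen = P(lam)
            score = 0.0
            ok = True
            for i in range(1, m - 1):
                mask = np.arange(m) != i
                Bi, yi = B[mask], y[mask]
                try:
                    c = np.linalg.solve(Bi.T @ Bi + pen, Bi.T @ yi)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                score += float((B[i] @ c - y[i]) ** 2)
            if ok and score < best_score:
                best_lam, best_score = lam, score
        return float(best_lam)

    def __call__(self, x) -> np.ndarray:
        return self._spline(np.asarray(x, dtype=float))

    def derivative(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._dspline is None:
            return np.zeros_like(x)
        return self._dspline(x)

    @property
    def fitted_values(self) -> np.ndarray:
        return self(self._t)


def fit_pspline(
    t: np.ndarray,
    y: np.ndarray,
    penalty: float | Literal["auto"] = "auto",
    degree: int = 3,
    diff_order: int = 2,
) -> PSpline:
    """Fit a P-spline to one series; see :class:`PSpline`."""
    return PSpline(t, y, penalty=penalty, degree=degree, diff_order=diff_order)


def finite_difference_derivatives(data: TimeSeriesData) -> DerivativeEstimate:
    """Forward differences (X_{j+1} - X_j) / dt, repeated at the last point.

    Exact for affine series; on non-equidistant grids each interval uses
    its own step.  The derivative at the final time reuses the last
    interval's slope so the estimate aligns with the measurement grid.
    """
    dt = np.diff(data.times)
    slopes = np.diff(data.X, axis=1) / dt
    Xdot = np.hstack([slopes, slopes[:, -1:]])
    return DerivativeEstimate(
        times=data.times, Xdot=Xdot, labels=data.labels, method="finite_difference"
    )


def derivatives_at(
    data: TimeSeriesData,
    method: Literal["finite_difference", "pspline"] = "pspline",
    penalty: float | Literal["auto"] = "auto",
    eval_times: np.ndarray | None = None,
) -> DerivativeEstimate:
    """Estimate dX/dt for all nodes at the measurement times (or a custom grid)."""
    if method == "finite_difference":
        if eval_times is not None:
            raise ValueError("finite differences evaluate on the measurement grid")
        return finite_difference_derivatives(data)
    if method != "pspline":
        raise ValueError(f"unknown derivative method {method!r}")
    times = data.times if eval_times is None else np.asarray(eval_times, float)
    if times.min() < data.times[0] or times.max() > data.times[-1]:
        raise ValueError("evaluation grid must lie inside the observation window")
    smoothers = tuple(
        PSpline(data.times, row, penalty=penalty) for row in data.X
    )
    Xdot = np.vstack([s.derivative(times) for s in smoothers])
    return DerivativeEstimate(
        times=times,
        Xdot=Xdot,
        labels=data.labels,
        method="pspline",
        smoothers=smoothers,
    )
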