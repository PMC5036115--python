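"""Identifiability and sensitivity diagnostics for fitted kinetic models.

Structural identifiability on tree networks follows from the pointwise
reformulation: the parameters solve an upper-triangular system, so they
are locally unique whenever all concentrations are nonzero.  Practical
identifiability is probed by profile likelihood: fix one parameter on a
grid, re-optimize all others, and flag the parameter as identifiable when
the profiled residual rises on both sides of the optimum.  Sloppiness is
quantified by the eigen-spectrum of the numerical Hessian of the residual
at the optimum; eigenvectors of near-zero eigenvalues point at poorly
determined parameter combinations -- typically those attached to nodes
whose concentrations are close to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .estimation import FitResult, _constrained_lsq
from .network import Network, find_undirected_cycle, validate_tree

__all__ = [
    "StructuralReport",
    "ProfileCurve",
    "SensitivitySpectrum",
    "structural_identifiability",
    "profile_likelihood",
    "sensitivity_spectrum",
]


@dataclass(frozen=True)
class StructuralReport:
    identifiable: bool
    reason: str
    triangular_order: tuple[str, ...] | None = None
    cycle: tuple[str, ...] | None = None


def structural_identifiability(network: Network) -> StructuralReport:
    """Certify local structural identifiability via the tree property.

    Trees admit an ordering in which the pointwise design matrix is upper
    triangular with nonzero diagonal, so the parameter map is locally
    injective; the certificate is that ordering.  Non-trees are flagged
    with an offending undirected cycle when one exists; unconstrained
    decay terms also void the certificate because the implicit sink edge
    breaks the node-per-parameter budget.
    """
    if network.decay_nodes:
        return StructuralReport(
            identifiable=False,
            reason=(
                "unconstrained decay on node(s) "
                f"{', '.join(network.decay_nodes)} breaks the tree structure"
            ),
        )
    is_tree, order = validate_tree(network)
    if is_tree:
        return StructuralReport(
            identifiable=True,
            reason="tree network: pointwise system is upper triangular",
            triangular_order=tuple(order),
        )
    cycle = find_undirected_cycle(network)
    return StructuralReport(
        identifiable=False,
        reason="not a tree; triangular embedding unavailable",
        cycle=tuple(cycle) if cycle else None,
    )


@dataclass
class ProfileCurve:
    parameter: str
    grid: np.ndarray
    residuals: np.ndarray
    optimum_value: float
    optimum_residual: float
    threshold: float
    identifiable: bool
    flat: bool
    point_status: list[bool] = field(default_factory=list)


def _default_grid(estimate: float, scale: float, n_points: int = 11) -> np.ndarray:
    """11 points spanning +/-50% (multiplicative) around the estimate;
    parameters at ~0 get a symmetric absolute span instead."""
    if abs(estimate) > 1e-8:
        return estimate * np.linspace(0.5, 1.5, n_points)
    return np.linspace(-0.5, 0.5, n_points) * max(scale, 1e-3)


def profile_likelihood(
    fit: FitResult,
    parameter: str,
    grid: np.ndarray | None = None,
    confidence: float = 0.95,
    absolute_floor: float = 1e-8,
    n_points: int = 11,
) -> ProfileCurve:
    """Profile the residual over one parameter, re-optimizing the rest.

    Gradient-matching fits (scheme 2) carry their quadratic objective, so
    each profile point is a reduced constrained least-squares solve and
    the profile is exact.  Other fits are profiled by re-running a
    Nelder-Mead search on their stored objective.

    A parameter is *identifiable* when the profiled residual rises past
    the likelihood-ratio threshold ``chi2(confidence, 1) * sigma^2`` on
    both sides of the optimum within the grid span, with ``sigma^2`` the
    residual variance at the optimum; otherwise the profile is flagged
    flat.  ``absolute_floor`` covers the noise-free case where the
    optimum residual (hence ``sigma^2``) is essentially zero.
    """
    if parameter not in fit.param_names:
        raise KeyError(f"unknown parameter {parameter!r}")
    p = fit.param_names.index(parameter)
    theta_hat = np.asarray(fit.theta, dtype=float)
    scale = float(np.median(np.abs(theta_hat))) or 1.0
    if grid is None:
        grid = _default_grid(theta_hat[p], scale, n_points)
    grid = np.asarray(grid, dtype=float)

    lsq = fit.diagnostics.get("lsq")
    residuals = np.empty(grid.size)
    status = []
    for i, v in enumerate(grid):
        try:
            if lsq is not None:
                residuals[i] = _profile_point_lsq(lsq, p, v)
            else:
                residuals[i] = _profile_point_generic(fit, p, v)
            status.append(True)
        except Exception:
            residuals[i] = np.nan
            status.append(False)

    if lsq is not None:
        M, y, _ = lsq
        opt_res = float(np.sum((M @ theta_hat - y) ** 2))
        n_obs = M.shape[0]
    else:
        opt_res = fit.residual
        n_obs = (fit.trajectories.size if fit.trajectories is not None
                 else theta_hat.size + 1)
    dof = max(n_obs - theta_hat.size, 1)
    sigma2 = opt_res / dof
    from scipy.stats import chi2

    threshold = max(float(chi2.ppf(confidence, 1)) * sigma2, absolute_floor)
    finite = np.isfinite(residuals)
    left = (grid < theta_hat[p]) & finite
    right = (grid > theta_hat[p]) & finite
    rise_left = np.nanmax(residuals[left]) - opt_res if left.any() else 0.0
    rise_right = np.nanmax(residuals[right]) - opt_res if right.any() else 0.0
    identifiable = bool(rise_left >= threshold and rise_right >= threshold)
    span = float(np.nanmax(residuals[finite]) - np.nanmin(residuals[finite])) if finite.any() else 0.0
    return ProfileCurve(
        parameter=parameter,
        grid=grid,
        residuals=residuals,
        optimum_value=float(theta_hat[p]),
        optimum_residual=opt_res,
        threshold=threshold,
        identifiable=identifiable,
        flat=bool(span < threshold),
        point_status=status,
    )


def _profile_point_lsq(lsq, p: int, value: float) -> float:
    """Exact profile point for a quadratic (gradient-matching) objective."""
    M, y, C = lsq
    keep = [j for j in range(M.shape[1]) if j != p]
    M_red = M[:, keep]
    y_red = y - M[:, p] * value
    C_red = C[:, keep]
    lb = -C[:, p] * value
    theta_red, _ = _constrained_lsq(M_red, y_red, C_red, lb=lb)
    return float(np.sum((M_red @ theta_red - y_red) ** 2))


def _profile_point_generic(fit: FitResult, p: int, value: float) -> float:
    if fit.objective is None:
        raise ValueError("fit carries no objective; cannot profile")
    theta_hat = np.asarray(fit.theta, dtype=float)
    keep = [j for j in range(theta_hat.size) if j != p]

    def reduced(th_red: np.ndarray) -> float:
        full = np.empty(theta_hat.size)
        full[keep] = th_red
        full[p] = value
        return fit.objective(full)

    res = minimize(reduced, theta_hat[keep], method="Nelder-Mead",
                   options={"maxiter": 200 * len(keep), "adaptive": True})
    return float(res.fun)


@dataclass
class SensitivitySpectrum:
    hessian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    param_names: list[str]

    @property
    def condition_span(self) -> float:
        """Orders of magnitude between largest and smallest |eigenvalue|."""
        ev = np.abs(self.eigenvalues)
        ev = ev[ev > 0]
        if ev.size < 2:
            return 0.0
        return float(np.log10(ev.max() / ev.min()))


def sensitivity_spectrum(
    fit: FitResult,
    rel_step: float = 1e-4,
    abs_floor: float = 1e-2,
) -> SensitivitySpectrum:
    """Eigen-decomposition of the numerical Hessian of the residual.

    Central differences with per-parameter step ``rel_step * max(|theta_i|,
    abs_floor)``.  The residual already sums the pointwise mismatch over
    measurement times, which equals the number of time points times the
    time-average of the pointwise sensitivity products; eigenstructure is
    unaffected by that constant.  The Hessian is symmetrized before the
    decomposition and eigenvalues are returned in descending order.
    """
    if fit.objective is None:
        raise ValueError("fit carries no objective; cannot differentiate")
    theta = np.asarray(fit.theta, dtype=float)
    P = theta.size
    h = rel_step * np.maximum(np.abs(theta), abs_floor)
    if np.any(h <= 0):
        raise FloatingPointError("step size underflow")
    f = fit.objective
    H = np.empty((P, P))
    f0 = f(theta)
    for i in range(P):
        ei = np.zeros(P)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, P):
            ej = np.zeros(P)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    order = np.argsort(vals)[::-1]
    return SensitivitySpectrum(
        hessian=H,
        eigenvalues=vals[order],
        eigenvectors=vecs[:, order],
        param_names=list(fit.param_names),
    )
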