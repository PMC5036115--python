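"""Catalytic-rate estimation: constant rates and three time-varying schemes.

All schemes estimate the influx ``b1`` and the per-edge catalytic rates of
the linear mass-balance model ``dX/dt = A(t) X + b`` from a concentration
matrix.  Time-varying rates are modeled as quadratics in time,
``k_ij(t) = alpha t^2 + beta t + gamma``.

Scheme 1 (pointwise solve, trees only)
    Fit P-splines per node, and at each time point solve the triangular
    linear system that the tree structure yields for ``(b1, k_ij)``
    exactly; then fit a quadratic through each rate's pointwise series.

Scheme 2 (gradient matching)
    Substitute the quadratic rate model into the mass-balance right-hand
    side and minimize the squared mismatch with estimated derivatives
    over all times simultaneously, subject to ``k_ij(t_k) >= 0``.  The
    objective is quadratic in the coefficients, so the unconstrained
    minimizer is a linear least-squares solve.

Scheme 3 (trajectory fitting)
    Integrate the ODE for candidate coefficients and minimize the summed
    distance between the model solution and the measurements with a
    multi-start Nelder-Mead simplex search.

Schemes 1 and 2 avoid repeated ODE integration and are therefore fast;
scheme 3 re-estimates the trajectories along with the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import LinearConstraint, lsq_linear, minimize

from .network import (
    Edge,
    Network,
    NetworkStructureError,
    RatePolynomial,
    RateSet,
    SingularConcentrationError,
    pointwise_design_matrix,
    tree_edge_order,
    validate_tree,
)
from .smoothing import DerivativeEstimate, TimeSeriesData, derivatives_at

__all__ = [
    "FitResult",
    "frobenius_norm",
    "model_trajectories",
    "estimate_constant_rates",
    "scheme1",
    "scheme2",
    "scheme3",
    "fit_scheme",
    "select_best_network",
    "pointwise_solve",
    "parameter_vector_names",
]


def frobenius_norm(M: np.ndarray) -> float:
    """Square root of the sum of squared entries."""
    M = np.asarray(M, dtype=float)
    return float(np.sqrt(np.sum(M * M)))


@dataclass
class FitResult:
    """Outcome of one rate-estimation run."""

    scheme: Literal["1", "2", "3", "constant"]
    network: Network
    rateset: RateSet
    param_names: list[str]
    theta: np.ndarray
    residual: float
    trajectories: np.ndarray | None = None
    times: np.ndarray | None = None
    pointwise: np.ndarray | None = None
    pointwise_times: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    objective: Callable[[np.ndarray], float] | None = field(default=None, repr=False)

    def rate_curves(self, times: np.ndarray) -> tuple[list[Edge], np.ndarray]:
        edges = canonical_edges(self.network)
        return edges, self.rateset.curves(edges, times)


def canonical_edges(network: Network) -> list[Edge]:
    """Tree-triangular edge order when available, declaration order otherwise."""
    is_tree, _ = validate_tree(network)
    return tree_edge_order(network) if is_tree else list(network.edges)


def parameter_vector_names(network: Network) -> list[str]:
    """Names of the quadratic-rate coefficient vector: b1 then per-edge coefficients."""
    names = ["b1"]
    for p, c in canonical_edges(network):
        names += [f"k_{p}_{c}.alpha", f"k_{p}_{c}.beta", f"k_{p}_{c}.gamma"]
    for d in network.decay_nodes:
        names += [f"kdecay_{d}.alpha", f"kdecay_{d}.beta", f"kdecay_{d}.gamma"]
    return names


def _theta_to_rateset(network: Network, theta: np.ndarray) -> RateSet:
    edges = canonical_edges(network)
    rates: dict[Edge, RatePolynomial] = {}
    for j, e in enumerate(edges):
        a, b, g = theta[1 + 3 * j : 4 + 3 * j]
        rates[e] = RatePolynomial(a, b, g)
    decay = {}
    off = 1 + 3 * len(edges)
    for i, d in enumerate(network.decay_nodes):
        a, b, g = theta[off + 3 * i : off + 3 * i + 3]
        decay[d] = RatePolynomial(a, b, g)
    return RateSet(rates=rates, b1=float(max(theta[0], 0.0)), decay=decay)


def _polynomial_system(network: Network, rateset: RateSet):
    """(A2, A1, A0, b) so that A(t) = A2 t^2 + A1 t + A0."""
    n = network.n_nodes
    idx = {node: i for i, node in enumerate(network.nodes)}
    mats = [np.zeros((n, n)) for _ in range(3)]  # alpha, beta, gamma layers

    def add(i: int, j: int, rate) -> None:
        coef = (
            rate.coefficients
            if isinstance(rate, RatePolynomial)
            else (0.0, 0.0, float(rate))
        )
        for layer, c in zip(mats, coef):
            if i != j:
                layer[i, j] += c
            layer[j, j] -= c

    for p, c in network.edges:
        add(idx[c], idx[p], rateset.rates[(p, c)])
    for d in network.decay_nodes:
        if d in rateset.decay:
            # pure outflow: only the diagonal loss term
            coef = rateset.decay[d]
            coefs = (
                coef.coefficients
                if isinstance(coef, RatePolynomial)
                else (0.0, 0.0, float(coef))
            )
            for layer, cc in zip(mats, coefs):
                layer[idx[d], idx[d]] -= cc
    b = np.zeros(n)
    b[idx[network.influx_node]] = rateset.b1
    return mats[0], mats[1], mats[2], b


def _rk4_trajectories(
    A2: np.ndarray,
    A1: np.ndarray,
    A0: np.ndarray,
    b: np.ndarray,
    x0: np.ndarray,
    times: np.ndarray,
    substeps: int = 3,
) -> np.ndarray:
    """Fixed-step RK4 for the time-varying linear system on the data grid.

    Cheap enough to sit inside simplex or Monte-Carlo loops; accuracy is
    O(h^4) in the substep h.
    """

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        return (A2 * t * t + A1 * t + A0) @ x + b

    out = np.empty((x0.size, times.size))
    out[:, 0] = x = np.asarray(x0, dtype=float).copy()
    for k in range(times.size - 1):
        t0, t1 = times[k], times[k + 1]
        h = (t1 - t0) / substeps
        t = t0
        for _ in range(substeps):
            k1 = rhs(t, x)
            k2 = rhs(t + h / 2, x + h / 2 * k1)
            k3 = rhs(t + h / 2, x + h / 2 * k2)
            k4 = rhs(t + h, x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[:, k + 1] = x
    return out


def model_trajectories(
    network: Network,
    rateset: RateSet,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fast: bool = False,
) -> np.ndarray:
    """Solve ``dX/dt = A(t) X + b`` at the requested times (nodes x times).

    ``fast=True`` switches from the adaptive Runge-Kutta integrator to a
    fixed-step RK4 suitable for inner optimization loops.
    """
    times = np.asarray(times, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    A2, A1, A0, b = _polynomial_system(network, rateset)
    if fast:
        return _rk4_trajectories(A2, A1, A0, b, x0, times)

    def rhs(t, x):
        return (A2 * t * t + A1 * t + A0) @ x + b

    sol = solve_ivp(
        rhs, (times[0], times[-1]), x0, t_eval=times, rtol=rtol, atol=atol,
        method="RK45",
    )
    if not sol.success:
        sol = solve_ivp(
            rhs, (times[0], times[-1]), x0, t_eval=times, rtol=rtol * 1e-2,
            atol=atol * 1e-2, method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y


def trajectory_objective(
    network: Network,
    rateset: RateSet,
    data: TimeSeriesData,
    norm: Literal["l2_squared", "l2"] = "l2_squared",
    fast: bool = True,
    x0: np.ndarray | None = None,
) -> float:
    """Summed (squared) Euclidean distance between model solution and data."""
    data = data.reordered(network.nodes)
    x0 = data.X[:, 0] if x0 is None else x0
    try:
        traj = model_trajectories(network, rateset, x0, data.times, fast=fast)
    except (RuntimeError, FloatingPointError, ValueError):
        return float("inf")
    if not np.all(np.isfinite(traj)):
        return float("inf")
    per_time = np.linalg.norm(traj - data.X, axis=0)
    return float(np.sum(per_time**2 if norm == "l2_squared" else per_time))


def estimate_constant_rates(
    network: Network,
    data: TimeSeriesData,
    deriv: DerivativeEstimate | None = None,
    allowed_edges: Sequence[Edge] | None = None,
) -> FitResult:
    """Constant-rate fit: minimize the Frobenius mismatch of derivatives.

    Solves ``argmin || Xdot - A_tilde Xtilde ||_F`` over the entries of
    the extended system matrix, with excluded edges pinned to zero and
    all rates (and ``b1``) constrained non-negative.  ``Xtilde`` is the
    data matrix with an appended row of ones.
    """
    data = data.reordered(network.nodes)
    if deriv is None:
        deriv = derivatives_at(data)
    edges = list(network.edges) if allowed_edges is None else list(allowed_edges)
    for e in edges:
        if e not in network.edges:
            raise ValueError(f"allowed edge {e} not in network")
    idx = {node: i for i, node in enumerate(network.nodes)}
    n, m = data.X.shape
    Xdot = deriv.Xdot
    P = len(edges) + 1  # one rate per allowed edge, then b1
    M = np.zeros((n * m, P))
    rows = lambda i: slice(i * m, (i + 1) * m)
    for j, (p, c) in enumerate(edges):
        M[rows(idx[c]), j] += data.X[idx[p]]
        M[rows(idx[p]), j] -= data.X[idx[p]]
    M[rows(idx[network.influx_node]), P - 1] = 1.0
    y = Xdot.reshape(-1)
    sol = lsq_linear(M, y, bounds=(0.0, np.inf))
    theta = sol.x
    rates = {e: float(theta[j]) for j, e in enumerate(edges)}
    rateset = RateSet(rates={**{e: 0.0 for e in network.edges}, **rates},
                      b1=float(theta[-1]))
    resid = frobenius_norm((M @ theta - y).reshape(n, m))
    traj = model_trajectories(network, rateset, data.X[:, 0], data.times)
    names = [f"k_{p}_{c}" for p, c in edges] + ["b1"]
    return FitResult(
        scheme="constant",
        network=network,
        rateset=rateset,
        param_names=names,
        theta=theta,
        residual=resid,
        trajectories=traj,
        times=data.times,
        diagnostics={"converged": bool(sol.status >= 0), "optimality": float(sol.optimality)},
    )


def pointwise_solve(
    network: Network, x: np.ndarray, xdot: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Solve ``B(X) theta = Xdot`` for ``theta = (b1, k_ij)`` at one time point.

    Exact (triangular) on trees.  ``x`` and ``xdot`` are in the network's
    declared node order; the returned vector follows the triangular
    parameter order.
    """
    from scipy.linalg import solve_triangular

    B, names, row_nodes = pointwise_design_matrix(network, x)
    perm = [network.index(nd) for nd in row_nodes]
    rhs = np.asarray(xdot, dtype=float)[perm]
    theta = solve_triangular(B, rhs, lower=False)
    return theta, names


def _general_pointwise_matrix(
    network: Network, x: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Pointwise system matrix for arbitrary networks (not necessarily square).

    Columns are ``b1`` followed by one rate per edge in canonical order;
    rows are the node equations in declared order.  On non-trees the
    parameter count exceeds the node count and the system is solved in
    the least-squares (minimum-norm) sense -- precisely the ambiguity
    that costs pointwise identifiability off trees.
    """
    idx = {node: i for i, node in enumerate(network.nodes)}
    edges = canonical_edges(network)
    G = np.zeros((network.n_nodes, 1 + len(edges)))
    G[idx[network.influx_node], 0] = 1.0
    for j, (p, c) in enumerate(edges):
        G[idx[c], 1 + j] += x[idx[p]]
        G[idx[p], 1 + j] -= x[idx[p]]
    names = ["b1"] + [f"k_{p}_{c}" for p, c in edges]
    return G, names


def _quadratic_polyfit(times: np.ndarray, series: np.ndarray, degree: int = 2):
    coefs = np.polyfit(times, series, deg=min(degree, times.size - 1))
    coefs = np.concatenate([np.zeros(3 - coefs.size), coefs])
    return RatePolynomial(*coefs)


def _project_nonnegative(rateset: RateSet, times: np.ndarray) -> RateSet:
    """Lift each rate polynomial's constant term so k(t_k) >= 0 at all t_k."""
    def lift(r):
        if not isinstance(r, RatePolynomial):
            return max(float(r), 0.0)
        worst = float(np.min(r(times)))
        if worst >= 0.0:
            return r
        return RatePolynomial(r.alpha, r.beta, r.gamma - worst)

    return RateSet(
        rates={e: lift(r) for e, r in rateset.rates.items()},
        b1=max(rateset.b1, 0.0),
        decay=dict(rateset.decay),  # decay terms stay unconstrained
    )


def scheme1(
    network: Network,
    data: TimeSeriesData,
    penalty: float | str = "auto",
    eval_times: np.ndarray | None = None,
    degree: int = 2,
    clip: Literal["zero", "none"] = "zero",
    deriv: DerivativeEstimate | None = None,
    allow_non_tree: bool = False,
) -> FitResult:
    """Pointwise triangular solve on a tree, then a quadratic fit per rate.

    P-splines smooth each node's series; at every evaluation time the
    smoothed concentrations and derivative estimates are substituted into
    the mass-balance equations, which on a tree form an upper-triangular
    system with the parameters as unknowns.  Negative pointwise values
    (possible under noise) are floored at zero before a degree-2
    polynomial is fitted through each rate's series; ``b1`` is estimated
    as the mean of its pointwise series.

    ``deriv`` may inject externally computed derivatives (e.g. exact ones
    from a simulator); it must then be evaluated on ``eval_times`` (or the
    measurement grid) and smoothed concentrations are replaced by the data.
    """
    is_tree, _ = validate_tree(network)
    if not is_tree and not allow_non_tree:
        raise NetworkStructureError(
            "scheme 1 requires a tree network (pass allow_non_tree=True to "
            "fall back to a pointwise least-squares solve)"
        )
    data = data.reordered(network.nodes)
    times = data.times if eval_times is None else np.asarray(eval_times, float)
    if deriv is None:
        est = derivatives_at(data, method="pspline", penalty=penalty,
                             eval_times=None if eval_times is None else times)
        Xdot = est.Xdot
        Xs = np.vstack([s(times) for s in est.smoothers])
    else:
        if deriv.Xdot.shape[1] != times.size:
            raise ValueError("injected derivatives must match the evaluation grid")
        Xdot = deriv.Xdot
        Xs = data.X

    edges = canonical_edges(network)
    P = 1 + len(edges)
    theta_t = np.full((P, times.size), np.nan)
    names = None
    masked = []
    for k in range(times.size):
        try:
            if is_tree:
                th, names = pointwise_solve(network, Xs[:, k], Xdot[:, k])
            else:
                G, names = _general_pointwise_matrix(network, Xs[:, k])
                th = np.linalg.lstsq(G, Xdot[:, k], rcond=None)[0]
        except SingularConcentrationError:
            masked.append(k)
            continue
        theta_t[:, k] = th
    if names is None:
        raise RuntimeError("all time points were singular; cannot estimate")
    if masked:
        warnings.warn(
            f"singular concentrations at {len(masked)} time point(s); masked",
            stacklevel=2,
        )
    ok = ~np.isin(np.arange(times.size), masked)
    raw = theta_t.copy()
    if clip == "zero":
        theta_t = np.maximum(theta_t, 0.0)

    rates = {}
    for j, e in enumerate(edges):
        rates[e] = _quadratic_polyfit(times[ok], theta_t[1 + j, ok], degree)
    b1 = float(np.mean(theta_t[0, ok]))
    rateset = _project_nonnegative(RateSet(rates=rates, b1=b1), data.times)
    traj = model_trajectories(network, rateset, data.X[:, 0], data.times)
    resid = float(np.sum(np.linalg.norm(traj - data.X, axis=0) ** 2))
    theta = np.array(
        [b1]
        + [c for e in edges for c in rates[e].coefficients]
    )
    return FitResult(
        scheme="1",
        network=network,
        rateset=rateset,
        param_names=parameter_vector_names(network),
        theta=theta,
        residual=resid,
        trajectories=traj,
        times=data.times,
        pointwise=raw,
        pointwise_times=times,
        diagnostics={"masked_time_points": masked, "pointwise_names": names},
    )


def _scheme2_design(
    network: Network, data: TimeSeriesData, Xdot: np.ndarray,
    X: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix, target, and non-negativity constraint rows for scheme 2.

    ``X`` lets the caller substitute smoothed concentrations for the raw
    data in the regressors (errors-in-variables mitigation under noise).
    """
    idx = {node: i for i, node in enumerate(network.nodes)}
    n, m = data.X.shape
    if X is None:
        X = data.X
    t = data.times
    tpow = np.stack([t**2, t, np.ones_like(t)], axis=1)  # m x 3
    edges = canonical_edges(network)
    D = len(network.decay_nodes)
    P = 1 + 3 * (len(edges) + D)
    M = np.zeros((n * m, P))
    rows = lambda i: slice(i * m, (i + 1) * m)
    M[rows(idx[network.influx_node]), 0] = 1.0
    for j, (p, c) in enumerate(edges):
        cols = slice(1 + 3 * j, 4 + 3 * j)
        contrib = X[idx[p], :, None] * tpow
        M[rows(idx[c]), cols] += contrib
        M[rows(idx[p]), cols] -= contrib
    off = 1 + 3 * len(edges)
    for i, dnode in enumerate(network.decay_nodes):
        cols = slice(off + 3 * i, off + 3 * i + 3)
        M[rows(idx[dnode]), cols] -= X[idx[dnode], :, None] * tpow
    y = Xdot.reshape(-1)
    # constraints: b1 >= 0 and every edge-rate polynomial >= 0 at every
    # t_k; decay terms are deliberately unconstrained -- an "unconstrained
    # decay" is exactly the modification that destroys identifiability
    C = np.zeros((1 + len(edges) * m, P))
    C[0, 0] = 1.0
    r = 1
    for j in range(len(edges)):
        cols = slice(1 + 3 * j, 4 + 3 * j)
        C[r : r + m, cols] = tpow
        r += m
    return M, y, C, parameter_vector_names(network)


def scheme2(
    network: Network,
    data: TimeSeriesData,
    deriv: DerivativeEstimate | None = None,
    penalty: float | str = "auto",
) -> FitResult:
    """Gradient matching with quadratic rate polynomials.

    The mass-balance right-hand side is linear in the polynomial
    coefficients, so the objective is a linear least-squares problem; the
    unconstrained solution is accepted when it already satisfies the
    non-negativity constraints, otherwise a quadratic program is solved.
    """
    data = data.reordered(network.nodes)
    Xs = None
    if deriv is None:
        deriv = derivatives_at(data, method="pspline", penalty=penalty)
        # when we fitted the smoothers ourselves, also use the smoothed
        # concentrations as regressors ("fix the concentrations first")
        Xs = np.vstack([s(data.times) for s in deriv.smoothers])
    if deriv.Xdot.shape != data.X.shape:
        raise ValueError("derivative estimate must align with the data grid")
    M, y, C, names = _scheme2_design(network, data, deriv.Xdot, X=Xs)
    theta, info = _constrained_lsq(M, y, C)
    rateset = _project_nonnegative(_theta_to_rateset(network, theta), data.times)
    traj = model_trajectories(network, rateset, data.X[:, 0], data.times)
    obj = float(np.sum((M @ theta - y) ** 2))

    def objective(th: np.ndarray) -> float:
        return float(np.sum((M @ th - y) ** 2))

    return FitResult(
        scheme="2",
        network=network,
        rateset=rateset,
        param_names=names,
        theta=theta,
        residual=obj,
        trajectories=traj,
        times=data.times,
        diagnostics={**info, "lsq": (M, y, C)},
        objective=objective,
    )


def _constrained_lsq(
    M: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    lb: np.ndarray | float = 0.0,
    tol: float = 1e-9,
) -> tuple[np.ndarray, dict]:
    """Least squares ``min ||M theta - y||`` subject to ``C theta >= lb``."""
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (C.shape[0],))
    theta0, *_ = np.linalg.lstsq(M, y, rcond=None)
    if np.all(C @ theta0 >= lb - tol):
        return theta0, {"converged": True, "constrained": False}
    H = M.T @ M

    def fun(th):
        r = M @ th - y
        return 0.5 * float(r @ r)

    def jac(th):
        return M.T @ (M @ th - y)

    res = minimize(
        fun,
        theta0,
        jac=jac,
        hess=lambda th: H,
        method="trust-constr",
        constraints=[LinearConstraint(C, lb, np.inf)],
        options={"maxiter": 500, "gtol": 1e-10, "xtol": 1e-12},
    )
    theta = res.x
    # exact KKT polish on the (estimated) active set: the interior-point
    # iterate stalls short of machine precision, which matters when profile
    # curves are compared against a tiny absolute floor
    active = C @ theta - lb < 1e-7
    if active.any():
        Ca = C[active]
        lba = lb[active]
        K = np.block([[H, Ca.T], [Ca, np.zeros((Ca.shape[0], Ca.shape[0]))]])
        rhs = np.concatenate([M.T @ y, lba])
        try:
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
            cand = sol[: H.shape[0]]
            if np.all(C @ cand >= lb - 1e-9) and fun(cand) <= fun(theta):
                theta = cand
        except np.linalg.LinAlgError:
            pass
    return theta, {"converged": bool(res.success), "constrained": True,
                   "iterations": int(res.niter)}


def scheme3(
    network: Network,
    data: TimeSeriesData,
    initial_guess: np.ndarray | FitResult | None = None,
    restarts: int = 5,
    seed: int | None = None,
    objective_norm: Literal["l2_squared", "l2"] = "l2_squared",
    maxiter: int | None = None,
    penalty_weight: float = 1e5,
    polish: bool = True,
) -> FitResult:
    """Trajectory fitting by multi-start Nelder-Mead simplex search.

    Each candidate coefficient vector is turned into rate curves, the ODE
    is integrated, and the summed (squared) per-time-point Euclidean
    distance to the measurements is minimized.  Non-negativity of the
    rates at the measurement times is enforced by a quadratic penalty.
    Starts: the caller's guess if given, a constant-rate warm start from
    the gradient-matching solution, and random log-uniform rate draws.
    """
    data = data.reordered(network.nodes)
    rng = np.random.default_rng(seed)
    names = parameter_vector_names(network)
    P = len(names)
    t = data.times
    x0 = data.X[:, 0]
    tpow = np.stack([t**2, t, np.ones_like(t)], axis=1)
    n_poly = (P - 1) // 3
    n_edge_poly = len(canonical_edges(network))

    def objective(theta: np.ndarray) -> float:
        try:
            traj = _fast_traj(theta)
        except FloatingPointError:
            return float("inf")
        if not np.all(np.isfinite(traj)):
            return float("inf")
        per_time = np.linalg.norm(traj - data.X, axis=0)
        val = float(np.sum(per_time**2 if objective_norm == "l2_squared" else per_time))
        viol = max(0.0, -theta[0]) ** 2
        for j in range(n_edge_poly):
            kvals = tpow @ theta[1 + 3 * j : 4 + 3 * j]
            viol += float(np.sum(np.minimum(kvals, 0.0) ** 2))
        return val + penalty_weight * viol

    def _fast_traj(theta: np.ndarray) -> np.ndarray:
        rs = _theta_to_rateset(network, theta)
        A2, A1, A0, b = _polynomial_system(network, rs)
        return _rk4_trajectories(A2, A1, A0, b, x0, t)

    starts: list[np.ndarray] = []
    if initial_guess is not None:
        if isinstance(initial_guess, FitResult):
            starts.append(np.asarray(initial_guess.theta, dtype=float))
        else:
            starts.append(np.asarray(initial_guess, dtype=float))
    # restarts from log-uniform random constant rates (curvature enters
    # through the simplex search itself)
    for _ in range(max(restarts, 1)):
        th = np.zeros(P)
        th[0] = rng.uniform(0.1, 2.0)
        for j in range(n_poly):
            th[3 + 3 * j] = np.exp(rng.uniform(np.log(0.05), np.log(2.0)))
        starts.append(th)

    best = None
    history = []
    nm_options = {
        "maxiter": maxiter if maxiter is not None else 150 * P,
        "xatol": 1e-8,
        "fatol": 1e-10,
        "adaptive": True,
    }
    with np.errstate(over="raise", invalid="raise"):
        for th0 in starts:
            f0 = objective(th0)
            res = minimize(objective, th0, method="Nelder-Mead", options=nm_options)
            history.append({"start_objective": f0, "final_objective": float(res.fun),
                            "iterations": int(res.nit)})
            if best is None or res.fun < best.fun:
                best = res
        if polish:
            # restart the simplex at the incumbent; a fresh simplex escapes
            # the shrunken one that Nelder-Mead tends to stall in
            res = minimize(objective, best.x, method="Nelder-Mead",
                           options=nm_options)
            if res.fun < best.fun:
                best = res
    theta = best.x
    rateset = _project_nonnegative(_theta_to_rateset(network, theta), t)
    traj = model_trajectories(network, rateset, x0, t)
    per_time = np.linalg.norm(traj - data.X, axis=0)
    resid = float(np.sum(per_time**2 if objective_norm == "l2_squared" else per_time))
    return FitResult(
        scheme="3",
        network=network,
        rateset=rateset,
        param_names=names,
        theta=theta,
        residual=resid,
        trajectories=traj,
        times=t,
        diagnostics={"restarts": history, "converged": bool(best.success)},
        objective=objective,
    )


def fit_scheme(
    scheme: Literal["1", "2", "3", "constant"],
    network: Network,
    data: TimeSeriesData,
    seed: int | None = None,
    **kwargs,
) -> FitResult:
    """Dispatch to one of the estimation schemes by label."""
    scheme = str(scheme)
    if scheme == "1":
        return scheme1(network, data, **kwargs)
    if scheme == "2":
        return scheme2(network, data, **kwargs)
    if scheme == "3":
        return scheme3(network, data, seed=seed, **kwargs)
    if scheme == "constant":
        return estimate_constant_rates(network, data, **kwargs)
    raise ValueError(f"unknown scheme {scheme!r}")


def select_best_network(
    candidates: Sequence[Network],
    data: TimeSeriesData,
    scheme: Literal["1", "2", "3", "constant"] = "2",
    seed: int | None = None,
    **kwargs,
) -> tuple[Network, list[FitResult]]:
    """Fit every candidate topology; return the one with the smallest
    trajectory residual (summed squared distance between the fitted model's
    solution and the measurements), along with all fits."""
    if not candidates:
        raise ValueError("need at least one candidate network")
    fits = []
    for net in candidates:
        fit = fit_scheme(scheme, net, data, seed=seed, **kwargs)
        fit.diagnostics["trajectory_residual"] = trajectory_objective(
            net, fit.rateset, data, fast=False
        )
        fits.append(fit)
    best_i = int(np.argmin([f.diagnostics["trajectory_residual"] for f in fits]))
    return candidates[best_i], fits
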