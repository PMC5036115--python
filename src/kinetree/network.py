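"""Directed metabolic networks and the linear mass-balance system matrices.

A metabolic network is a directed graph whose nodes are metabolites and
whose edge ``(i, j)`` carries the catalytic rate ``k_ij >= 0`` of the
conversion of metabolite ``i`` into ``j``.  With concentrations ``X_i(t)``
the mass-balance model is the linear ODE system

    dX_i/dt = -sum_j k_ij X_i + sum_j k_ji X_j + b_i,

where ``b_i`` is zero everywhere except at a single influx (root) node.
In matrix form ``dX/dt = A X + b`` with off-diagonal ``A_ij = k_ji`` and
diagonal ``A_ii = -sum_j k_ij``; every column of ``A`` sums to zero, which
is exactly conservation of mass.

When the graph is a *tree* (no undirected cycle, every non-root node with
exactly one incoming edge, all edges oriented away from the root), the
number of unknown parameters (one influx plus one rate per edge) equals
the number of nodes, and the system can be rewritten so that the unknowns
at a single time point solve an upper-triangular linear system.  That
reformulation -- the pointwise design matrix ``B`` -- is what makes
time-resolved rates uniquely estimable on trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "RatePolynomial",
    "RateSet",
    "SystemMatrix",
    "NetworkStructureError",
    "SingularConcentrationError",
    "validate_tree",
    "build_system_matrix",
    "pointwise_design_matrix",
    "parameter_names",
]


class NetworkStructureError(ValueError):
    """Raised when a graph violates a structural precondition (e.g. not a tree)."""


class SingularConcentrationError(ValueError):
    """Raised when a concentration needed as a divisor is (numerically) zero."""


Edge = tuple[str, str]


@dataclass(frozen=True)
class Network:
    """A directed metabolite network with a single influx (root) node.

    Parameters
    ----------
    nodes
        Ordered node identifiers; must be unique.
    edges
        Directed ``(parent, child)`` pairs; every endpoint must be a node.
    influx_node
        The node receiving the constant inflow ``b1``.
    decay_nodes
        Nodes with an additional unconstrained first-order outflow to an
        implicit external sink.  A decay term destroys both the tree
        property and, in short series, practical identifiability; it is
        supported so that this loss can be demonstrated.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    influx_node: str
    decay_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(str(n) for n in self.nodes))
        object.__setattr__(
            self, "edges", tuple((str(a), str(b)) for a, b in self.edges)
        )
        object.__setattr__(self, "decay_nodes", tuple(str(n) for n in self.decay_nodes))
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkStructureError("node identifiers must be unique")
        declared = set(self.nodes)
        for a, b in self.edges:
            if a not in declared or b not in declared:
                raise NetworkStructureError(f"edge ({a}, {b}) has undeclared endpoint")
            if a == b:
                raise NetworkStructureError(f"self-loop on node {a}")
        if self.influx_node not in declared:
            raise NetworkStructureError(f"influx node {self.influx_node!r} not declared")
        for n in self.decay_nodes:
            if n not in declared:
                raise NetworkStructureError(f"decay node {n!r} not declared")
        if len(set(self.edges)) != len(self.edges):
            raise NetworkStructureError("duplicate edges")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def children(self, node: str) -> list[str]:
        return [b for a, b in self.edges if a == node]

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]


@dataclass(frozen=True)
class RatePolynomial:
    """Quadratic time course of one catalytic rate: k(t) = alpha t^2 + beta t + gamma.

    Units: ``gamma`` in 1/time, ``beta`` in 1/time^2, ``alpha`` in 1/time^3.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.alpha * t**2 + self.beta * t + self.gamma

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


RateValue = Union[float, RatePolynomial]


@dataclass(frozen=True)
class RateSet:
    """Edge rates (constant or quadratic-in-time) plus the influx ``b1``.

    ``decay`` optionally maps decay-carrying nodes to their outflow rate.
    """

    rates: Mapping[Edge, RateValue]
    b1: float = 0.0
    decay: Mapping[str, RateValue] = field(default_factory=dict)

    def rate_at(self, edge: Edge, t: float | None = None) -> float:
        r = self.rates[edge]
        if isinstance(r, RatePolynomial):
            if t is None:
                raise ValueError("time-varying rate requires an evaluation time")
            return float(r(t))
        return float(r)

    def decay_at(self, node: str, t: float | None = None) -> float:
        r = self.decay[node]
        if isinstance(r, RatePolynomial):
            if t is None:
                raise ValueError("time-varying rate requires an evaluation time")
            return float(r(t))
        return float(r)

    def is_time_varying(self) -> bool:
        vals = list(self.rates.values()) + list(self.decay.values())
        return any(isinstance(r, RatePolynomial) for r in vals)

    def curves(self, edges: Sequence[Edge], times: np.ndarray) -> np.ndarray:
        """Rate curves evaluated on a grid, shape (n_edges, n_times)."""
        times = np.asarray(times, dtype=float)
        out = np.empty((len(edges), times.size))
        for i, e in enumerate(edges):
            r = self.rates[e]
            out[i] = r(times) if isinstance(r, RatePolynomial) else float(r)
        return out


@dataclass(frozen=True)
class SystemMatrix:
    """System matrices of ``dX/dt = A X + b``; ``A_tilde`` is ``[A | b]``."""

    A: np.ndarray
    b: np.ndarray
    A_tilde: np.ndarray
    nodes: tuple[str, ...]


def validate_tree(network: Network) -> tuple[bool, list[str] | None]:
    """Check the tree property and return a root-first (BFS) node order.

    A network is a tree when (i) it has no undirected cycle -- no closed
    chain of edges regardless of direction, (ii) every non-root node has
    exactly one incoming edge, and (iii) every edge is reachable from the
    influx node following edge directions.  Any decay term disqualifies
    the network, since the implicit sink edge closes the parameter budget
    that triangularity relies on.
    """
    if network.decay_nodes:
        return False, None
    g = network.to_digraph()
    root = network.influx_node
    if g.in_degree(root) != 0:
        return False, None
    for n in network.nodes:
        if n != root and g.in_degree(n) != 1:
            return False, None
    # in-degrees fixed above; an undirected cycle or unreachable component
    # now shows up as a node count mismatch in the BFS tree from the root
    order = bfs_order(network)
    if len(order) != network.n_nodes:
        return False, None
    if len(network.edges) != network.n_nodes - 1:
        return False, None
    return True, order


def bfs_order(network: Network) -> list[str]:
    """Breadth-first node order from the root, children in declaration order."""
    order = [network.influx_node]
    seen = {network.influx_node}
    queue = [network.influx_node]
    while queue:
        node = queue.pop(0)
        for child in network.children(node):
            if child not in seen:
                seen.add(child)
                order.append(child)
                queue.append(child)
    return order


def find_undirected_cycle(network: Network) -> list[str] | None:
    """Return one undirected cycle (node list) or None if the graph is acyclic."""
    g = network.to_digraph().to_undirected(as_view=False)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [a for a, _ in cyc]


def parameter_names(network: Network) -> list[str]:
    """Pointwise parameter order: ``b1`` first, then one rate per non-root node.

    On a tree each non-root node has a unique incoming edge, so ordering
    edges by the BFS position of their child makes the design matrix
    upper triangular.
    """
    is_tree, order = validate_tree(network)
    if not is_tree:
        raise NetworkStructureError("pointwise parameterization requires a tree")
    names = ["b1"]
    for node in order[1:]:
        (parent,) = network.parents(node)
        names.append(f"k_{parent}_{node}")
    return names


def tree_edge_order(network: Network) -> list[Edge]:
    """Edges ordered by BFS position of the child node (triangular order)."""
    is_tree, order = validate_tree(network)
    if not is_tree:
        raise NetworkStructureError("edge ordering requires a tree")
    return [(network.parents(n)[0], n) for n in order[1:]]


def build_system_matrix(
    network: Network, rates: RateSet, t: float | None = None
) -> SystemMatrix:
    """Assemble ``A``, ``b`` and the extended ``A_tilde = [A | b]``.

    Rows/columns follow the network's declared node order.  Time-varying
    rates are evaluated at ``t``.
    """
    n = network.n_nodes
    idx = {node: i for i, node in enumerate(network.nodes)}
    A = np.zeros((n, n))
    for a, b_ in network.edges:
        k = rates.rate_at((a, b_), t)
        if k < 0:
            raise ValueError(f"rate for edge ({a}, {b_}) is negative at t={t}: {k}")
        A[idx[b_], idx[a]] += k
        A[idx[a], idx[a]] -= k
    for node in network.decay_nodes:
        if node in rates.decay:
            # decay terms are deliberately unconstrained in sign
            A[idx[node], idx[node]] -= rates.decay_at(node, t)
    b = np.zeros(n)
    if rates.b1 < 0:
        raise ValueError("influx b1 must be non-negative")
    b[idx[network.influx_node]] = rates.b1
    A_tilde = np.hstack([A, b[:, None]])
    return SystemMatrix(A=A, b=b, A_tilde=A_tilde, nodes=network.nodes)


def pointwise_design_matrix(
    network: Network,
    x: np.ndarray | Mapping[str, float],
    rel_epsilon: float = 1e-9,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix ``B`` so that ``B @ (b1, k...) = dX/dt`` at one time point.

    Exchanging the roles of states and parameters in the mass-balance
    equations turns the concentrations at a single time into the
    coefficient matrix of a linear system for ``(b1, k_ij)``.  Rows are
    equations in BFS node order; columns are ``b1`` followed by the
    incoming edge of each non-root node in BFS order, which makes ``B``
    upper triangular with diagonal ``(1, X_parent, ...)`` so that
    ``det(B)`` is the product of parent concentrations over edges.

    Parameters
    ----------
    x
        Concentration vector in the network's declared node order, or a
        mapping node -> concentration.
    rel_epsilon
        Concentrations of magnitude below ``rel_epsilon * max|X|`` raise
        :class:`SingularConcentrationError`, because the solve divides by
        parent concentrations.

    Returns
    -------
    B, param_names, row_nodes
    """
    is_tree, order = validate_tree(network)
    if not is_tree:
        raise NetworkStructureError(
            "pointwise design matrix requires a tree network"
        )
    if isinstance(x, Mapping):
        xv = np.array([float(x[n]) for n in network.nodes])
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (network.n_nodes,):
            raise ValueError("concentration vector length mismatch")
    conc = {node: xv[network.index(node)] for node in network.nodes}
    # only parents' concentrations sit on the diagonal, but the contract
    # rejects any ~zero concentration so callers can mask the time point
    scale = np.max(np.abs(xv)) if xv.size else 0.0
    bad = [n for n in network.nodes if abs(conc[n]) < rel_epsilon * scale]
    if bad or scale == 0.0:
        raise SingularConcentrationError(
            f"near-zero concentrations at nodes {bad or list(network.nodes)}"
        )
    pos = {node: i for i, node in enumerate(order)}
    n = network.n_nodes
    B = np.zeros((n, n))
    B[0, 0] = 1.0  # influx enters the root equation with unit coefficient
    for node in order:
        i = pos[node]
        if node != network.influx_node:
            (parent,) = network.parents(node)
            B[i, i] = conc[parent]
        for child in network.children(node):
            # the outgoing rate k_{node,child} drains node and sits in the
            # child's parameter column, strictly above the diagonal
            B[i, pos[child]] = -conc[node]
    names = parameter_names(network)
    return B, names, list(order)
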