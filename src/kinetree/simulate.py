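"""Synthetic datasets for benchmarking the estimation schemes.

Generates random rooted tree (or cyclic) metabolite networks, quadratic
time-varying rates, clean trajectories from the mass-balance ODE, exact
derivatives from its right-hand side, and multiplicative uniform noise.
Defaults emulate the motivating data: a 7-node tree like the quercetin
glycosylation pathway, rates varying smoothly over the observation
window, and +/-10% relative noise.  Two grid presets are provided: a
20-point grid on [0, 10] for method benchmarking, and a 5-point
"seedling" grid on days 5-9 matching the sampling of the tomato series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import model_trajectories, _polynomial_system
from .network import Network, RatePolynomial, RateSet
from .smoothing import DerivativeEstimate, TimeSeriesData

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "random_tree",
    "random_cyclic",
    "sample_rates",
    "generate",
    "seedling_grid",
    "benchmark_grid",
]


def benchmark_grid() -> np.ndarray:
    """20 equidistant points on [0, 10] (dense enough for stable splines)."""
    return np.linspace(0.0, 10.0, 20)


def seedling_grid() -> np.ndarray:
    """Five daily samples on days 5-9, as in the tomato seedling series."""
    return np.arange(5.0, 10.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Coefficient ranges are chosen so that trajectories stay positive and
    span roughly the same order of magnitude as the motivating metabolite
    concentrations (O(0.1) to O(10)).
    """

    n_nodes: int = 7
    topology: str = "tree"  # "tree" | "cyclic"
    alpha_range: tuple[float, float] = (-0.02, 0.02)
    beta_range: tuple[float, float] = (-0.1, 0.1)
    gamma_range: tuple[float, float] = (0.1, 1.0)
    b1_range: tuple[float, float] = (0.5, 2.0)
    x0_root_range: tuple[float, float] = (1.0, 5.0)
    x0_other_range: tuple[float, float] = (0.1, 0.5)
    times: np.ndarray = field(default_factory=benchmark_grid)
    noise_level: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.n_nodes < 1:
            raise ValueError("need at least one node")
        if self.topology not in ("tree", "cyclic"):
            raise ValueError("topology must be 'tree' or 'cyclic'")


@dataclass(frozen=True)
class SimulatedDataset:
    network: Network
    rateset: RateSet
    clean: TimeSeriesData
    noisy: TimeSeriesData
    exact_derivatives: DerivativeEstimate
    x0: np.ndarray


def _streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    """Independent child streams (topology, rates, noise) from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def random_tree(n_nodes: int, seed: int | np.random.Generator = 0) -> Network:
    """Random rooted directed tree: node i > 0 picks a parent among 0..i-1."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [f"X{i + 1}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        edges.append((nodes[parent], nodes[i]))
    return Network(nodes=tuple(nodes), edges=tuple(edges), influx_node=nodes[0])


def random_cyclic(
    n_nodes: int, seed: int | np.random.Generator = 0, extra_edges: int = 1
) -> Network:
    """A random tree plus extra forward edges, each closing an undirected cycle.

    The added edges point from an earlier to a later node in the tree
    order, so the directed graph stays acyclic (solutions remain bounded)
    while the undirected cycle destroys the tree property.
    """
    if n_nodes < 3:
        raise ValueError("a cyclic network needs at least 3 nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = random_tree(n_nodes, rng)
    edges = list(net.edges)
    existing = set(edges)
    added = 0
    attempts = 0
    while added < extra_edges and attempts < 1000:
        attempts += 1
        i = int(rng.integers(0, n_nodes - 1))
        j = int(rng.integers(i + 1, n_nodes))
        e = (net.nodes[i], net.nodes[j])
        if e in existing:
            continue
        existing.add(e)
        edges.append(e)
        added += 1
    if added < extra_edges:
        raise RuntimeError("could not add a cycle-closing edge")
    return Network(nodes=net.nodes, edges=tuple(edges), influx_node=net.influx_node)


def sample_rates(
    network: Network,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    max_draws: int = 1000,
) -> RateSet:
    """Draw per-edge quadratic coefficients, rejecting curves that go negative
    anywhere on the time grid."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    t = spec.times
    rates = {}
    for e in network.edges:
        for _ in range(max_draws):
            a = rng.uniform(*spec.alpha_range)
            b = rng.uniform(*spec.beta_range)
            g = rng.uniform(*spec.gamma_range)
            poly = RatePolynomial(a, b, g)
            if np.all(poly(t) >= 0.0):
                rates[e] = poly
                break
        else:
            raise RuntimeError(
                f"could not draw a non-negative rate for edge {e} in {max_draws} "
                "attempts; widen gamma_range"
            )
    b1 = rng.uniform(*spec.b1_range)
    return RateSet(rates=rates, b1=float(b1))


def exact_derivatives(
    network: Network, rateset: RateSet, clean: TimeSeriesData
) -> DerivativeEstimate:
    """dX/dt from the ODE right-hand side at the grid points (no differencing)."""
    A2, A1, A0, b = _polynomial_system(network, rateset)
    t = clean.times
    Xdot = np.empty_like(clean.X)
    for k, tk in enumerate(t):
        Xdot[:, k] = (A2 * tk * tk + A1 * tk + A0) @ clean.X[:, k] + b
    return DerivativeEstimate(times=t, Xdot=Xdot, labels=clean.labels, method="exact")


def generate(spec: SimulationSpec, network: Network | None = None,
             rateset: RateSet | None = None) -> SimulatedDataset:
    """Simulate one dataset: topology, truth rates, trajectories, noise.

    Noise is multiplicative uniform: noisy = clean * (1 + u) with
    u ~ U(-noise_level, +noise_level) i.i.d. per cell.
    """
    rng_topo, rng_rates, rng_noise = _streams(spec.seed)
    if network is None:
        if spec.topology == "tree":
            network = random_tree(spec.n_nodes, rng_topo)
        else:
            network = random_cyclic(spec.n_nodes, rng_topo)
    if rateset is None:
        rateset = sample_rates(network, spec, rng_rates)
    x0 = np.empty(network.n_nodes)
    root_i = network.index(network.influx_node)
    for i in range(network.n_nodes):
        lo, hi = spec.x0_root_range if i == root_i else spec.x0_other_range
        x0[i] = rng_rates.uniform(lo, hi)
    X = model_trajectories(network, rateset, x0, spec.times)
    clean = TimeSeriesData(times=spec.times, X=X, labels=network.nodes)
    u = rng_noise.uniform(-spec.noise_level, spec.noise_level, size=X.shape)
    noisy = TimeSeriesData(times=spec.times, X=X * (1.0 + u), labels=network.nodes)
    deriv = exact_derivatives(network, rateset, clean)
    return SimulatedDataset(
        network=network, rateset=rateset, clean=clean, noisy=noisy,
        exact_derivatives=deriv, x0=x0,
    )
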