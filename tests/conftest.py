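import numpy as np
import pytest

from kinetree import Network, RatePolynomial, RateSet, SimulationSpec, generate


@pytest.fixture(scope="session")
def balanced_tree() -> Network:
    """The 7-node, 6-edge balanced tree used throughout as worked example."""
    nodes = tuple(f"X{i}" for i in range(1, 8))
    edges = (
        ("X1", "X2"), ("X1", "X3"),
        ("X2", "X4"), ("X2", "X5"),
        ("X3", "X6"), ("X3", "X7"),
    )
    return Network(nodes=nodes, edges=edges, influx_node="X1")


@pytest.fixture(scope="session")
def quadratic_rates(balanced_tree) -> RateSet:
    """Deterministic, everywhere-nonnegative quadratic rates on the tree."""
    coefs = [
        (0.004, -0.05, 0.60), (-0.003, 0.04, 0.35),
        (0.002, 0.01, 0.25), (-0.002, 0.03, 0.45),
        (0.005, -0.04, 0.50), (0.001, -0.02, 0.30),
    ]
    rates = {
        e: RatePolynomial(*c) for e, c in zip(balanced_tree.edges, coefs)
    }
    return RateSet(rates=rates, b1=1.5)


@pytest.fixture(scope="session")
def clean_dataset(balanced_tree, quadratic_rates):
    """Noiseless 20-point trajectories from known quadratic rates."""
    spec = SimulationSpec(noise_level=0.0, seed=7)
    return generate(spec, network=balanced_tree, rateset=quadratic_rates)


@pytest.fixture(scope="session")
def noisy_dataset(balanced_tree, quadratic_rates):
    spec = SimulationSpec(noise_level=0.10, seed=7)
    return generate(spec, network=balanced_tree, rateset=quadratic_rates)


def rate_curve_rms(fit, dataset) -> float:
    """Relative Frobenius error of estimated vs true rate curves."""
    from kinetree.estimation import canonical_edges

    t = dataset.clean.times
    edges = canonical_edges(dataset.network)
    K_true = dataset.rateset.curves(edges, t)
    K_est = fit.rateset.curves(edges, t)
    return float(np.linalg.norm(K_est - K_true) / np.linalg.norm(K_true))
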