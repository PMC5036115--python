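"""Readers and writers for networks, time series, expression tables, fits.

Tabular files are tab-separated with a header row of time values and row
labels in the first column; networks are JSON (``nodes``, ``edges``,
``influx_node``) or a two-column edge list whose root is the unique
in-degree-zero node.  Structured outputs (fits, configs) are JSON with
full-precision floats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, canonical_edges
from .genes import ExpressionTable
from .network import Network, RatePolynomial, RateSet
from .smoothing import TimeSeriesData

__all__ = [
    "RunConfig",
    "read_network",
    "write_network",
    "read_timeseries",
    "write_timeseries",
    "read_expression",
    "write_expression",
    "fit_to_dict",
    "write_fit",
    "read_fit",
]


def read_network(path: str | Path) -> Network:
    """Read a network from JSON or a 2-column TSV edge list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return Network(
            nodes=tuple(payload["nodes"]),
            edges=tuple((a, b) for a, b in payload["edges"]),
            influx_node=payload["influx_node"],
            decay_nodes=tuple(payload.get("decay_nodes", [])),
        )
    rows = [
        line.split("\t")
        for line in path.read_text().strip().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    edges = tuple((a.strip(), b.strip()) for a, b in rows)
    nodes: list[str] = []
    for a, b in edges:
        for n in (a, b):
            if n not in nodes:
                nodes.append(n)
    targets = {b for _, b in edges}
    roots = [n for n in nodes if n not in targets]
    if len(roots) != 1:
        raise ValueError(
            f"edge list must have exactly one in-degree-0 node, found {roots}"
        )
    return Network(nodes=tuple(nodes), edges=edges, influx_node=roots[0])


def write_network(network: Network, path: str | Path) -> None:
    payload = {
        "nodes": list(network.nodes),
        "edges": [list(e) for e in network.edges],
        "influx_node": network.influx_node,
    }
    if network.decay_nodes:
        payload["decay_nodes"] = list(network.decay_nodes)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _read_labelled_matrix(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate row labels: {dupes}")
    try:
        times = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError("header must contain numeric time values") from exc
    X = df.to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    if not np.array_equal(order, np.arange(times.size)):
        warnings.warn("time columns were unordered; sorting by time", stacklevel=2)
        times, X = times[order], X[:, order]
    if np.any(np.diff(times) <= 0):
        raise ValueError("time values must be distinct")
    return [str(i) for i in df.index], times, X


def read_timeseries(path: str | Path) -> TimeSeriesData:
    """Read a node-by-time concentration table (TSV, first column = node ID)."""
    labels, times, X = _read_labelled_matrix(path)
    return TimeSeriesData(times=times, X=X, labels=tuple(labels))


def write_timeseries(data: TimeSeriesData, path: str | Path) -> None:
    df = pd.DataFrame(
        data.X, index=list(data.labels), columns=[repr(float(t)) for t in data.times]
    )
    df.to_csv(path, sep="\t", index_label="node", float_format="%.17g")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a gene-by-time expression table (TSV, first column = gene ID)."""
    genes, times, E = _read_labelled_matrix(path)
    return ExpressionTable(genes=tuple(genes), times=times, E=E)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    df = pd.DataFrame(
        expr.E, index=list(expr.genes), columns=[repr(float(t)) for t in expr.times]
    )
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def _rate_to_payload(rate) -> dict | float:
    if isinstance(rate, RatePolynomial):
        return {"alpha": rate.alpha, "beta": rate.beta, "gamma": rate.gamma}
    return float(rate)


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-safe summary of a fit (coefficients, residual, trajectories)."""
    edges = canonical_edges(fit.network)
    rates = {f"{p}->{c}": _rate_to_payload(fit.rateset.rates[(p, c)]) for p, c in edges}
    decay = {d: _rate_to_payload(r) for d, r in fit.rateset.decay.items()}
    diag = {
        k: v
        for k, v in fit.diagnostics.items()
        if isinstance(v, (int, float, str, bool, list, dict))
    }
    return {
        "scheme": fit.scheme,
        "network": {
            "nodes": list(fit.network.nodes),
            "edges": [list(e) for e in fit.network.edges],
            "influx_node": fit.network.influx_node,
            "decay_nodes": list(fit.network.decay_nodes),
        },
        "b1": fit.rateset.b1,
        "rates": rates,
        "decay": decay,
        "param_names": list(fit.param_names),
        "theta": np.asarray(fit.theta).tolist(),
        "residual": fit.residual,
        "times": None if fit.times is None else np.asarray(fit.times).tolist(),
        "trajectories": None
        if fit.trajectories is None
        else np.asarray(fit.trajectories).tolist(),
        "diagnostics": diag,
    }


def write_fit(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")


def read_fit(path: str | Path) -> FitResult:
    """Rebuild a (summary-level) FitResult from a fit JSON file.

    The stored fit carries coefficients and trajectories but not the
    in-memory objective; diagnostics note that it was deserialized.
    """
    payload = json.loads(Path(path).read_text())
    net = Network(
        nodes=tuple(payload["network"]["nodes"]),
        edges=tuple((a, b) for a, b in payload["network"]["edges"]),
        influx_node=payload["network"]["influx_node"],
        decay_nodes=tuple(payload["network"].get("decay_nodes", [])),
    )
    rates = {}
    for key, val in payload["rates"].items():
        p, c = key.split("->")
        rates[(p, c)] = (
            RatePolynomial(**val) if isinstance(val, dict) else float(val)
        )
    decay = {
        d: RatePolynomial(**v) if isinstance(v, dict) else float(v)
        for d, v in payload.get("decay", {}).items()
    }
    rs = RateSet(rates=rates, b1=payload["b1"], decay=decay)
    return FitResult(
        scheme=payload["scheme"],
        network=net,
        rateset=rs,
        param_names=list(payload["param_names"]),
        theta=np.asarray(payload["theta"], dtype=float),
        residual=float(payload["residual"]),
        times=None if payload["times"] is None else np.asarray(payload["times"]),
        trajectories=None
        if payload["trajectories"] is None
        else np.asarray(payload["trajectories"]),
        diagnostics={**payload.get("diagnostics", {}), "deserialized": True},
    )


@dataclass
class RunConfig:
    """Flat, JSON-round-trippable settings for reproducible runs."""

    scheme: str = "2"
    derivative_method: str = "pspline"
    penalty: str | float = "auto"
    restarts: int = 5
    seed: int = 0
    objective_norm: str = "l2_squared"
    noise_level: float = 0.10
    n_nodes: int = 7
    replicates: int = 20
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
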