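"""Candidate-gene (glycosyltransferase) selection from estimated rate dynamics.

The catalytic rate of an enzymatic conversion aggregates kinetic constants
with the enzyme's concentration, so its estimated time course should echo
the expression trend of the gene coding for that enzyme.  The selection
procedure is:

1. fit the kinetic model on the best-supported network and keep the
   estimated rate curves as reference;
2. correlate each candidate gene's standardized expression series with
   each standardized rate curve on the shared time grid;
3. rank genes by their best-edge correlation and carry the top of the
   list forward to experimental validation.

The ranking is validated computationally by a Metropolis Monte-Carlo
search: gene expression curves from a high-ranked and a lower-ranked set
are substituted (positively scaled) for the rate curves, the model is
re-integrated, and the distributions of best-achieved residuals of the
two sets are compared with mean and variance tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .estimation import (
    FitResult,
    _polynomial_system,
    _rk4_trajectories,
    canonical_edges,
)
from .network import Edge, Network, RatePolynomial, RateSet
from .smoothing import TimeSeriesData

__all__ = [
    "ExpressionTable",
    "GeneRanking",
    "McmcValidation",
    "standardize",
    "rank_genes",
    "synthesize_expression",
    "mcmc_validate",
    "genes_by_rank",
]


class DegenerateSeriesError(ValueError):
    """Raised for constant (zero-variance) series that cannot be standardized."""


@dataclass(frozen=True)
class ExpressionTable:
    """Gene-expression matrix (genes x times) on a time grid."""

    genes: tuple[str, ...]
    times: np.ndarray
    E: np.ndarray
    dispersion: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "E", E)
        if times.size < 2:
            raise ValueError("need at least two time points")
        if E.shape != (len(self.genes), times.size):
            raise ValueError("expression matrix shape mismatch")
        if not np.all(np.isfinite(E)):
            raise ValueError("expression values must be finite")
        if self.dispersion is not None:
            d = np.asarray(self.dispersion, dtype=float)
            object.__setattr__(self, "dispersion", d)
            if d.shape != (len(self.genes),):
                raise ValueError("dispersion must be one value per gene")

    def row(self, gene: str) -> np.ndarray:
        return self.E[self.genes.index(gene)]


def standardize(series: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Z-score a series: subtract the mean, divide by the standard deviation.

    Constant series raise :class:`DegenerateSeriesError` so callers can
    exclude them explicitly rather than silently zeroing them.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least two values to standardize")
    mu = series.mean()
    sd = series.std()
    if sd < tol * max(abs(mu), 1.0):
        raise DegenerateSeriesError("zero-variance series cannot be standardized")
    return (series - mu) / sd


@dataclass
class GeneRanking:
    """Per-gene best-edge correlation with the estimated rate curves."""

    genes: list[str]
    edges: list[Edge]
    correlations: np.ndarray  # genes x edges
    best_correlation: np.ndarray
    best_edge: list[Edge]
    order: list[str]  # gene ids, descending score
    excluded: list[str]
    method: str = "pearson"
    weighted: bool = False

    def rank_of(self, gene: str) -> int:
        """1-based rank of a gene (1 = best)."""
        return self.order.index(gene) + 1


def _rate_curves_at(fit: FitResult, times: np.ndarray) -> tuple[list[Edge], np.ndarray]:
    edges = canonical_edges(fit.network)
    return edges, fit.rateset.curves(edges, times)


def rank_genes(
    fit: FitResult,
    expr: ExpressionTable,
    weighting: Literal["none", "dispersion"] = "none",
    method: Literal["pearson", "spearman"] = "pearson",
) -> GeneRanking:
    """Correlate every gene with every estimated rate curve and rank genes.

    Both sides are standardized before correlating; a gene's score is its
    maximum (signed) correlation over edges.  With
    ``weighting="dispersion"`` the score is divided by one plus the
    gene's replicate dispersion, favoring precisely measured genes.
    """
    edges, K = _rate_curves_at(fit, expr.times)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    kept, excluded = [], []
    K_std = []
    for row in K:
        K_std.append(standardize(row) if row.std() > 1e-12 else None)
    C = np.full((len(expr.genes), len(edges)), np.nan)
    for gi, gene in enumerate(expr.genes):
        try:
            g = standardize(expr.E[gi])
        except DegenerateSeriesError:
            excluded.append(gene)
            continue
        kept.append(gene)
        for ei in range(len(edges)):
            if K_std[ei] is None:
                C[gi, ei] = 0.0  # flat rate curve carries no dynamic signal
            else:
                C[gi, ei] = float(corr_fn(g, K_std[ei])[0])
    best = np.nanmax(np.where(np.isnan(C), -np.inf, C), axis=1)
    best_edge = [
        edges[int(np.nanargmax(np.where(np.isnan(C[gi]), -np.inf, C[gi])))]
        if expr.genes[gi] not in excluded
        else edges[0]
        for gi in range(len(expr.genes))
    ]
    score = best.copy()
    weighted = False
    if weighting == "dispersion" and expr.dispersion is not None:
        score = score / (1.0 + expr.dispersion)
        weighted = True
    rankable = [g for g in expr.genes if g not in excluded]
    order = sorted(rankable, key=lambda g: -score[expr.genes.index(g)])
    return GeneRanking(
        genes=list(expr.genes),
        edges=edges,
        correlations=C,
        best_correlation=best,
        best_edge=best_edge,
        order=order,
        excluded=excluded,
        method=method,
        weighted=weighted,
    )


def genes_by_rank(ranking: GeneRanking, lo: int, hi: int) -> list[str]:
    """Genes with 1-based ranks in [lo, hi]."""
    return ranking.order[lo - 1 : hi]


def synthesize_expression(
    rateset: RateSet,
    edges: Sequence[Edge],
    times: np.ndarray,
    n_decoys: int = 200,
    noise: float = 0.05,
    seed: int = 0,
) -> ExpressionTable:
    """Synthetic expression panel: planted enzymes plus smooth decoys.

    Expression is stored as positive, unit-mean abundance curves (the
    scale of microarray intensities is arbitrary anyway, and the
    downstream ranking standardizes before correlating).  Planted genes
    are the true rate curves scaled to unit mean plus Gaussian noise, so
    a single positive scale factor maps them back onto the rates exactly
    -- the relationship the selection procedure assumes.  Decoys are
    draws from a smooth Gaussian process (squared-exponential kernel,
    length scale a quarter of the window), shifted positive and scaled to
    unit mean: smooth like real expression trends, but not confined to
    the quadratic shape family of the rate model -- decoys drawn from
    that same family would mimic rate curves by construction and make any
    ranking meaningless.  A test fixture for the selection procedure, not
    a microarray model.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows, names = [], []
    for p, c in edges:
        curve = rateset.curves([(p, c)], times)[0]
        mean = curve.mean()
        if mean <= 0:
            raise ValueError(f"rate curve for edge ({p}, {c}) is not positive")
        g = curve / mean
        rows.append(g + rng.normal(0.0, noise * max(g.std(), 0.05),
                                   size=times.size))
        names.append(f"GT_true_{p}_{c}")
    span = times[-1] - times[0]
    ell = span / 4.0
    K = np.exp(-0.5 * ((times[:, None] - times[None, :]) / ell) ** 2)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(times.size))
    for i in range(n_decoys):
        curve = L @ rng.normal(size=times.size)
        if curve.std() < 1e-9:
            curve = curve + (times - times.mean()) / span
        curve = curve - curve.min() + 0.25 * curve.std()
        rows.append(curve / curve.mean())
        names.append(f"GT_decoy_{i:03d}")
    return ExpressionTable(genes=tuple(names), times=times, E=np.vstack(rows))


@dataclass
class McmcValidation:
    """Mean/variance comparison of best residuals reached by two gene sets."""

    set_a: list[str]
    set_b: list[str]
    residuals_a: np.ndarray
    residuals_b: np.ndarray
    mean_statistic: float
    mean_pvalue: float
    variance_statistic: float
    variance_pvalue: float
    iterations: int
    samples: int
    seed: int
    temperature: float


class _GeneKineticSampler:
    """Metropolis sampler over (edge -> gene assignment, positive scales).

    Each state substitutes ``k_e(t) = s_e * g(t)`` for the rate curves,
    with ``g`` the assigned gene's quadratic least-squares approximation
    and ``s_e > 0`` a single per-edge scale factor (expression magnitudes
    are arbitrary; shapes are not).  The energy is the summed squared
    distance between the re-integrated model and the data.
    """

    def __init__(
        self,
        network: Network,
        data: TimeSeriesData,
        expr: ExpressionTable,
        gene_pool: Sequence[str],
        reference: FitResult,
        rng: np.random.Generator,
        scale_step: float = 0.2,
    ) -> None:
        self.network = network
        self.data = data.reordered(network.nodes)
        self.edges = canonical_edges(network)
        self.pool = list(gene_pool)
        self.rng = rng
        self.scale_step = scale_step
        t = self.data.times
        self.times = t
        self.x0 = self.data.X[:, 0]
        self.b1 = reference.rateset.b1
        # quadratic approximation of every pool gene's expression curve
        V = np.stack([t**2, t, np.ones_like(t)], axis=1)
        self.gene_quad = {}
        for g in self.pool:
            coefs = np.linalg.lstsq(V, expr.row(g), rcond=None)[0]
            self.gene_quad[g] = coefs
        # least-squares scale matching each gene to each reference rate curve
        _, K = reference.rate_curves(t)
        self.ref_curves = {e: K[i] for i, e in enumerate(self.edges)}
        self.init_scale = {}
        for e in self.edges:
            for g in self.pool:
                gq = V @ self.gene_quad[g]
                denom = float(gq @ gq)
                s = float(gq @ self.ref_curves[e]) / denom if denom > 0 else 1.0
                self.init_scale[(e, g)] = max(s, 1e-6)

    def initial_state(self):
        assign = {e: self.pool[self.rng.integers(len(self.pool))] for e in self.edges}
        scales = {e: self.init_scale[(e, assign[e])] for e in self.edges}
        return assign, scales

    def energy(self, assign, scales) -> float:
        rates = {}
        for e in self.edges:
            s = scales[e]
            a, b, c = self.gene_quad[assign[e]]
            poly = RatePolynomial(s * a, s * b, s * c)
            worst = float(np.min(poly(self.times)))
            if worst < 0:  # keep the substituted rate curve admissible
                poly = RatePolynomial(poly.alpha, poly.beta, poly.gamma - worst)
            rates[e] = poly
        rs = RateSet(rates=rates, b1=self.b1)
        A2, A1, A0, b = _polynomial_system(self.network, rs)
        try:
            with np.errstate(over="raise", invalid="raise"):
                traj = _rk4_trajectories(A2, A1, A0, b, self.x0, self.times)
        except FloatingPointError:
            return float("inf")
        if not np.all(np.isfinite(traj)):
            return float("inf")
        return float(np.sum((traj - self.data.X) ** 2))

    def propose(self, assign, scales):
        assign = dict(assign)
        scales = dict(scales)
        e = self.edges[self.rng.integers(len(self.edges))]
        if self.rng.random() < 0.5:
            assign[e] = self.pool[self.rng.integers(len(self.pool))]
            scales[e] = self.init_scale[(e, assign[e])]
        else:
            scales[e] *= float(np.exp(self.rng.normal(0.0, self.scale_step)))
        return assign, scales

    def calibrate_temperature(self, n_pilot: int = 20, target: float = 0.4) -> float:
        """Pick T so that uphill moves from the initial state are accepted
        at roughly the target rate."""
        assign, affine = self.initial_state()
        e0 = self.energy(assign, affine)
        deltas = []
        for _ in range(n_pilot):
            a2, f2 = self.propose(assign, affine)
            e2 = self.energy(a2, f2)
            if np.isfinite(e2) and e2 > e0:
                deltas.append(e2 - e0)
        if not deltas:
            return 1e-6
        return float(np.median(deltas) / max(-np.log(target), 1e-9))

    def run_chain(self, steps: int, temperature: float) -> float:
        assign, affine = self.initial_state()
        e = self.energy(assign, affine)
        best = e
        for _ in range(steps):
            a2, f2 = self.propose(assign, affine)
            e2 = self.energy(a2, f2)
            if e2 <= e or self.rng.random() < np.exp(-(e2 - e) / temperature):
                assign, affine, e = a2, f2, e2
                best = min(best, e)
        return best


def mcmc_validate(
    network: Network,
    data: TimeSeriesData,
    expr: ExpressionTable,
    reference: FitResult,
    set_a: Sequence[str],
    set_b: Sequence[str],
    iterations: int = 200,
    samples: int = 1000,
    seed: int = 0,
    mean_test: Literal["welch"] = "welch",
    variance_test: Literal["f", "levene"] = "f",
) -> McmcValidation:
    """Compare residuals achievable by two gene sets via Metropolis sampling.

    For each set, ``iterations`` independent chains of ``samples`` steps
    explore gene-to-edge assignments and per-edge positive scale factors; each
    chain contributes its best (lowest) residual.  The two collections
    are compared with a Welch two-sample t-test on means and an F-test
    (or Levene's test) on variances.
    """
    set_a, set_b = list(set_a), list(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("gene sets must be disjoint")
    for s, name in ((set_a, "A"), (set_b, "B")):
        if not s:
            raise ValueError(f"set {name} is empty")
        missing = [g for g in s if g not in expr.genes]
        if missing:
            raise KeyError(f"set {name} genes not in expression table: {missing}")
    rng_a, rng_b = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    sampler_a = _GeneKineticSampler(network, data, expr, set_a, reference, rng_a)
    sampler_b = _GeneKineticSampler(network, data, expr, set_b, reference, rng_b)
    T = max(sampler_a.calibrate_temperature(), sampler_b.calibrate_temperature())
    res_a = np.array([sampler_a.run_chain(samples, T) for _ in range(iterations)])
    res_b = np.array([sampler_b.run_chain(samples, T) for _ in range(iterations)])
    t_stat, t_p = stats.ttest_ind(res_a, res_b, equal_var=False)
    if variance_test == "levene":
        v_stat, v_p = stats.levene(res_a, res_b)
    else:
        va, vb = res_a.var(ddof=1), res_b.var(ddof=1)
        F = va / vb if vb > 0 else np.inf
        dfa, dfb = res_a.size - 1, res_b.size - 1
        p_one = stats.f.sf(F, dfa, dfb) if F >= 1 else stats.f.cdf(F, dfa, dfb)
        v_stat, v_p = float(F), float(min(1.0, 2.0 * p_one))
    return McmcValidation(
        set_a=set_a,
        set_b=set_b,
        residuals_a=res_a,
        residuals_b=res_b,
        mean_statistic=float(t_stat),
        mean_pvalue=float(t_p),
        variance_statistic=float(v_stat),
        variance_pvalue=float(v_p),
        iterations=iterations,
        samples=samples,
        seed=seed,
        temperature=float(T),
    )
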