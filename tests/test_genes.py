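"""Gene ranking by rate-curve correlation and Monte-Carlo validation."""

import numpy as np
import pytest

from kinetree import (
    ExpressionTable,
    genes_by_rank,
    mcmc_validate,
    rank_genes,
    scheme2,
    standardize,
    synthesize_expression,
)
from kinetree.estimation import canonical_edges
from kinetree.genes import DegenerateSeriesError


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = standardize(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, rel=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(size=10))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_series_flagged(self):
        with pytest.raises(DegenerateSeriesError):
            standardize(np.full(5, 2.0))


@pytest.fixture(scope="module")
def ranking_setup(balanced_tree, quadratic_rates):
    from kinetree.simulate import SimulationSpec, generate

    ds = generate(
        SimulationSpec(noise_level=0.0, seed=31),
        network=balanced_tree,
        rateset=quadratic_rates,
    )
    fit = scheme2(ds.network, ds.clean, deriv=ds.exact_derivatives)
    edges = canonical_edges(ds.network)
    expr = synthesize_expression(
        ds.rateset, edges, ds.clean.times, n_decoys=50, noise=0.02, seed=5
    )
    return ds, fit, edges, expr


class TestRankGenes:
    def test_planted_gene_is_rank_one(self, ranking_setup):
        ds, fit, edges, _ = ranking_setup
        t = ds.clean.times
        planted = standardize(ds.rateset.rates[edges[0]](t))
        rng = np.random.default_rng(1)
        decoys = rng.normal(size=(5, t.size))
        expr = ExpressionTable(
            genes=("planted", "d1", "d2", "d3", "d4", "d5"),
            times=t,
            E=np.vstack([planted + rng.normal(0, 0.01, t.size), decoys]),
        )
        ranking = rank_genes(fit, expr)
        assert ranking.order[0] == "planted"
        gi = ranking.genes.index("planted")
        assert ranking.best_correlation[gi] > 0.99

    def test_negated_curve_ranks_last_under_signed_score(self, ranking_setup):
        ds, fit, edges, _ = ranking_setup
        t = ds.clean.times
        z = standardize(ds.rateset.rates[edges[0]](t))
        expr = ExpressionTable(
            genes=("match", "anti"), times=t, E=np.vstack([z, -z])
        )
        ranking = rank_genes(fit, expr)
        assert ranking.order[-1] == "anti"
        ai = ranking.genes.index("anti")
        # the negated gene may correlate with another edge; against its
        # own source edge the correlation is exactly -1
        e0 = ranking.edges.index(edges[0])
        assert ranking.correlations[ai, e0] == pytest.approx(-1.0, abs=1e-9)

    def test_affine_invariance(self, ranking_setup):
        ds, fit, edges, expr = ranking_setup
        shifted = ExpressionTable(
            genes=expr.genes, times=expr.times, E=3.7 * expr.E + 11.0
        )
        r1 = rank_genes(fit, expr)
        r2 = rank_genes(fit, shifted)
        assert r1.order == r2.order
        np.testing.assert_allclose(r1.correlations, r2.correlations, atol=1e-10)

    def test_constant_gene_excluded(self, ranking_setup):
        _, fit, _, expr = ranking_setup
        E = np.vstack([expr.E, np.full(expr.times.size, 5.0)])
        expr2 = ExpressionTable(
            genes=expr.genes + ("flatliner",), times=expr.times, E=E
        )
        ranking = rank_genes(fit, expr2)
        assert "flatliner" in ranking.excluded
        assert "flatliner" not in ranking.order

    def test_planted_panel_lands_in_top_ranks(self, ranking_setup):
        ds, fit, edges, expr = ranking_setup
        ranking = rank_genes(fit, expr)
        top = set(ranking.order[:10])
        planted = {g for g in expr.genes if g.startswith("GT_true_")}
        assert planted <= top


class TestSynthesizeExpression:
    def test_zero_noise_correlates_perfectly(self, ranking_setup):
        ds, fit, edges, _ = ranking_setup
        t = ds.clean.times
        expr = synthesize_expression(ds.rateset, edges, t, n_decoys=3,
                                     noise=0.0, seed=0)
        for j, e in enumerate(edges):
            z = standardize(ds.rateset.rates[e](t))
            r = np.corrcoef(expr.E[j], z)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_under_seed(self, ranking_setup):
        ds, _, edges, _ = ranking_setup
        t = ds.clean.times
        a = synthesize_expression(ds.rateset, edges, t, seed=3)
        b = synthesize_expression(ds.rateset, edges, t, seed=3)
        np.testing.assert_array_equal(a.E, b.E)

    def test_decoy_correlations_center_near_zero(self, ranking_setup):
        ds, _, edges, _ = ranking_setup
        t = np.linspace(0, 10, 20)
        expr = synthesize_expression(ds.rateset, edges, t, n_decoys=300, seed=9)
        z = standardize(ds.rateset.rates[edges[0]](t))
        corrs = [
            np.corrcoef(expr.E[i], z)[0, 1]
            for i in range(len(edges), len(expr.genes))
        ]
        assert abs(np.mean(corrs)) < 0.1


class TestMcmcValidate:
    def test_planted_set_beats_decoy_set(self, ranking_setup):
        ds, fit, edges, expr = ranking_setup
        ranking = rank_genes(fit, expr)
        set_a = genes_by_rank(ranking, 1, 10)
        set_b = genes_by_rank(ranking, 11, 20)
        out = mcmc_validate(
            ds.network, ds.clean, expr, fit, set_a, set_b,
            iterations=12, samples=60, seed=2,
        )
        assert out.residuals_a.mean() < out.residuals_b.mean()
        assert out.mean_pvalue < 0.05

    def test_oracle_assignment_reaches_noise_floor(self, ranking_setup):
        ds, fit, edges, _ = ranking_setup
        t = ds.clean.times
        expr = synthesize_expression(ds.rateset, edges, t, n_decoys=6,
                                     noise=0.0, seed=0)
        planted = [g for g in expr.genes if g.startswith("GT_true_")]
        decoys = [g for g in expr.genes if g.startswith("GT_decoy_")]
        out = mcmc_validate(
            ds.network, ds.clean, expr, fit, planted, decoys,
            iterations=8, samples=200, seed=4,
        )
        # noiseless expression IS the truth up to a positive scale: the
        # planted set should reach residuals at the solver-error floor
        floor = np.sum(ds.clean.X**2) * 1e-4
        assert out.residuals_a.min() < floor
        assert out.residuals_b.min() > out.residuals_a.min()

    def test_overlapping_sets_rejected(self, ranking_setup):
        ds, fit, _, expr = ranking_setup
        with pytest.raises(ValueError):
            mcmc_validate(ds.network, ds.clean, expr, fit,
                          [expr.genes[0]], [expr.genes[0]],
                          iterations=1, samples=1)

    def test_reproducible_under_seed(self, ranking_setup):
        ds, fit, _, expr = ranking_setup
        ranking = rank_genes(fit, expr)
        kw = dict(iterations=4, samples=20, seed=11)
        a = mcmc_validate(ds.network, ds.clean, expr, fit,
                          genes_by_rank(ranking, 1, 8),
                          genes_by_rank(ranking, 9, 16), **kw)
        b = mcmc_validate(ds.network, ds.clean, expr, fit,
                          genes_by_rank(ranking, 1, 8),
                          genes_by_rank(ranking, 9, 16), **kw)
        np.testing.assert_array_equal(a.residuals_a, b.residuals_a)
        np.testing.assert_array_equal(a.residuals_b, b.residuals_b)
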