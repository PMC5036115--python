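"""Constant-rate fitting, the three time-varying schemes, and model solves."""

import numpy as np
import pytest

from kinetree import (
    Network,
    RatePolynomial,
    RateSet,
    estimate_constant_rates,
    frobenius_norm,
    model_trajectories,
    scheme1,
    scheme2,
    scheme3,
    select_best_network,
)
from kinetree.estimation import canonical_edges, pointwise_solve
from kinetree.network import NetworkStructureError
from kinetree.simulate import SimulationSpec, exact_derivatives, generate
from kinetree.smoothing import DerivativeEstimate, TimeSeriesData

from conftest import rate_curve_rms


class TestFrobeniusNorm:
    def test_identity(self):
        assert frobenius_norm(np.eye(2)) == pytest.approx(np.sqrt(2))

    def test_zero(self):
        assert frobenius_norm(np.zeros((3, 5))) == 0.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(3, 4))
        total = 0.0
        for i in range(3):
            for j in range(4):
                total += M[i, j] ** 2
        assert frobenius_norm(M) == pytest.approx(np.sqrt(total), rel=1e-14)


class TestModelTrajectories:
    def test_zero_rates_frozen_state(self, balanced_tree):
        rs = RateSet(rates={e: 0.0 for e in balanced_tree.edges}, b1=0.0)
        x0 = np.linspace(1, 2, 7)
        traj = model_trajectories(balanced_tree, rs, x0, np.linspace(0, 5, 6))
        np.testing.assert_allclose(traj, np.tile(x0[:, None], (1, 6)), atol=1e-10)

    def test_total_mass_grows_linearly_with_influx(self, balanced_tree,
                                                   quadratic_rates):
        x0 = np.full(7, 0.5)
        t = np.linspace(0, 8, 9)
        traj = model_trajectories(balanced_tree, quadratic_rates, x0, t)
        totals = traj.sum(axis=0)
        np.testing.assert_allclose(
            totals, totals[0] + quadratic_rates.b1 * t, atol=1e-7
        )

    def test_constant_rates_match_matrix_exponential(self, balanced_tree):
        from scipy.linalg import expm

        from kinetree import build_system_matrix

        rs = RateSet(
            rates={e: 0.1 + 0.05 * i for i, e in enumerate(balanced_tree.edges)},
            b1=1.0,
        )
        sm = build_system_matrix(balanced_tree, rs)
        x0 = np.linspace(0.5, 2.0, 7)
        t = np.array([0.0, 1.0, 2.5])
        traj = model_trajectories(balanced_tree, rs, x0, t)
        # affine-system oracle via the augmented matrix exponential
        n = 7
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = sm.A
        M[:n, n] = sm.b
        z0 = np.concatenate([x0, [1.0]])
        for k, tk in enumerate(t):
            z = expm(M * tk) @ z0
            np.testing.assert_allclose(traj[:, k], z[:n], atol=1e-8)

    def test_fast_integrator_agrees_with_adaptive(self, balanced_tree,
                                                  quadratic_rates):
        x0 = np.full(7, 0.8)
        t = np.linspace(0, 10, 20)
        slow = model_trajectories(balanced_tree, quadratic_rates, x0, t)
        fast = model_trajectories(balanced_tree, quadratic_rates, x0, t, fast=True)
        assert np.max(np.abs(slow - fast)) < 1e-4 * np.max(np.abs(slow))


class TestConstantRates:
    def test_recovers_truth_with_exact_derivatives(self, balanced_tree):
        rs = RateSet(
            rates={e: 0.2 + 0.07 * i for i, e in enumerate(balanced_tree.edges)},
            b1=1.3,
        )
        spec = SimulationSpec(noise_level=0.0, seed=2)
        ds = generate(spec, network=balanced_tree, rateset=rs)
        fit = estimate_constant_rates(
            balanced_tree, ds.clean, deriv=ds.exact_derivatives
        )
        for e in balanced_tree.edges:
            assert fit.rateset.rates[e] == pytest.approx(rs.rates[e], rel=1e-6)
        assert fit.rateset.b1 == pytest.approx(1.3, rel=1e-6)

    def test_zero_derivatives_give_zero_rates(self, balanced_tree):
        t = np.linspace(0, 4, 5)
        X = np.tile(np.linspace(1, 2, 7)[:, None], (1, 5))
        data = TimeSeriesData(times=t, X=X, labels=balanced_tree.nodes)
        zero = DerivativeEstimate(times=t, Xdot=np.zeros_like(X),
                                  labels=balanced_tree.nodes, method="exact")
        fit = estimate_constant_rates(balanced_tree, data, deriv=zero)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in fit.rateset.rates.values())
        assert fit.rateset.b1 == pytest.approx(0.0, abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-9)

    def test_nonnegativity_constraint_binds(self):
        # a two-node chain whose leaf shrinks forces the unconstrained
        # solution negative; the constrained fit clamps it at zero
        net = Network(nodes=("R", "L"), edges=(("R", "L"),), influx_node="R")
        t = np.linspace(0, 3, 4)
        X = np.vstack([np.full_like(t, 2.0), 1.0 - 0.2 * t])
        data = TimeSeriesData(times=t, X=X, labels=("R", "L"))
        deriv = DerivativeEstimate(
            times=t,
            Xdot=np.vstack([np.zeros_like(t), np.full_like(t, -0.2)]),
            labels=("R", "L"),
            method="exact",
        )
        fit = estimate_constant_rates(net, data, deriv=deriv)
        # pseudo-inverse oracle of the unconstrained problem
        M = np.zeros((2 * 4, 2))
        M[4:, 0] += X[0]
        M[:4, 0] -= X[0]
        M[:4, 1] = 1.0
        unconstrained = np.linalg.lstsq(M, deriv.Xdot.reshape(-1), rcond=None)[0]
        assert unconstrained[0] < 0
        assert fit.rateset.rates[("R", "L")] == pytest.approx(0.0, abs=1e-9)
        unc_res = np.linalg.norm(M @ unconstrained - deriv.Xdot.reshape(-1))
        assert fit.residual >= unc_res - 1e-12

    def test_edge_exclusion(self, balanced_tree, clean_dataset):
        allowed = balanced_tree.edges[:3]
        fit = estimate_constant_rates(
            balanced_tree, clean_dataset.clean, allowed_edges=allowed
        )
        for e in balanced_tree.edges[3:]:
            assert fit.rateset.rates[e] == 0.0


class TestScheme1:
    def test_exact_derivatives_recover_pointwise_truth(self, clean_dataset):
        ds = clean_dataset
        fit = scheme1(ds.network, ds.clean, deriv=ds.exact_derivatives)
        t = ds.clean.times
        edges = canonical_edges(ds.network)
        truth = np.vstack(
            [np.full_like(t, ds.rateset.b1)]
            + [ds.rateset.rates[e](t) for e in edges]
        )
        np.testing.assert_allclose(fit.pointwise, truth, rtol=1e-8, atol=1e-10)
        assert rate_curve_rms(fit, ds) < 1e-8

    def test_constant_rate_data_yields_flat_polynomials(self, balanced_tree):
        rs = RateSet(
            rates={e: 0.3 + 0.05 * i for i, e in enumerate(balanced_tree.edges)},
            b1=1.0,
        )
        ds = generate(SimulationSpec(noise_level=0.0, seed=3),
                      network=balanced_tree, rateset=rs)
        fit = scheme1(ds.network, ds.clean, deriv=ds.exact_derivatives)
        for e in balanced_tree.edges:
            poly = fit.rateset.rates[e]
            assert abs(poly.alpha) < 1e-3 * abs(poly.gamma)
            assert abs(poly.beta) < 1e-3 * abs(poly.gamma)

    def test_two_node_chain_hand_inversion(self):
        net = Network(nodes=("R", "L"), edges=(("R", "L"),), influx_node="R")
        x = np.array([2.0, 1.0])
        xdot = np.array([0.3, 0.8])
        theta, names = pointwise_solve(net, x, xdot)
        assert names == ["b1", "k_R_L"]
        assert theta[1] == pytest.approx(xdot[1] / x[0])  # k = Xdot_leaf/X_root
        assert theta[0] == pytest.approx(xdot[0] + xdot[1])  # b1 = sum of rates

    def test_non_tree_rejected_by_default(self, clean_dataset):
        from kinetree import random_cyclic

        net = random_cyclic(7, seed=0)
        with pytest.raises(NetworkStructureError):
            scheme1(net, clean_dataset.clean)


class TestScheme2:
    def test_exact_derivative_recovery(self, clean_dataset):
        ds = clean_dataset
        fit = scheme2(ds.network, ds.clean, deriv=ds.exact_derivatives)
        for e in canonical_edges(ds.network):
            est = np.array(fit.rateset.rates[e].coefficients)
            true = np.array(ds.rateset.rates[e].coefficients)
            np.testing.assert_allclose(est, true, rtol=1e-2, atol=1e-8)
        assert rate_curve_rms(fit, ds) < 1e-6

    def test_agrees_with_scheme1_on_noiseless_tree(self, clean_dataset):
        # both schemes target the same zero-residual solution, so with the
        # same (exact) derivative estimates their rate curves must agree
        ds = clean_dataset
        f1 = scheme1(ds.network, ds.clean, deriv=ds.exact_derivatives)
        f2 = scheme2(ds.network, ds.clean, deriv=ds.exact_derivatives)
        t = ds.clean.times
        edges = canonical_edges(ds.network)
        K1 = f1.rateset.curves(edges, t)
        K2 = f2.rateset.curves(edges, t)
        assert np.linalg.norm(K1 - K2) / np.linalg.norm(K1) < 0.02

    def test_constant_rate_data_gives_flat_polynomials(self, balanced_tree):
        rs = RateSet(
            rates={e: 0.25 + 0.1 * i for i, e in enumerate(balanced_tree.edges)},
            b1=0.8,
        )
        ds = generate(SimulationSpec(noise_level=0.0, seed=5),
                      network=balanced_tree, rateset=rs)
        fit = scheme2(ds.network, ds.clean, deriv=ds.exact_derivatives)
        for e in balanced_tree.edges:
            poly = fit.rateset.rates[e]
            assert abs(poly.alpha) < 1e-6 and abs(poly.beta) < 1e-6

    def test_rates_nonnegative_at_measurement_times(self, noisy_dataset):
        ds = noisy_dataset
        fit = scheme2(ds.network, ds.noisy)
        t = ds.clean.times
        for e in canonical_edges(ds.network):
            assert np.all(fit.rateset.rates[e](t) >= -1e-10)


class TestScheme3:
    def test_truth_start_stays_at_global_minimum(self, clean_dataset):
        ds = clean_dataset
        edges = canonical_edges(ds.network)
        truth = np.concatenate(
            [[ds.rateset.b1]]
            + [np.array(ds.rateset.rates[e].coefficients) for e in edges]
        )
        fit = scheme3(ds.network, ds.clean, initial_guess=truth, restarts=0,
                      seed=0)
        assert fit.residual < 1e-4
        assert rate_curve_rms(fit, ds) < 0.02

    def test_final_objective_beats_every_start(self, clean_dataset):
        ds = clean_dataset
        fit = scheme3(ds.network, ds.clean, restarts=3, seed=7, maxiter=300)
        final = min(h["final_objective"] for h in fit.diagnostics["restarts"])
        for h in fit.diagnostics["restarts"]:
            assert final <= h["start_objective"] + 1e-12

    def test_reproducible_under_seed(self, clean_dataset):
        ds = clean_dataset
        a = scheme3(ds.network, ds.clean, restarts=2, seed=3, maxiter=200)
        b = scheme3(ds.network, ds.clean, restarts=2, seed=3, maxiter=200)
        np.testing.assert_array_equal(a.theta, b.theta)


class TestSelectBestNetwork:
    def test_single_candidate_returned(self, clean_dataset):
        ds = clean_dataset
        best, fits = select_best_network([ds.network], ds.clean, scheme="2")
        assert best is ds.network and len(fits) == 1

    def test_true_topology_wins_under_noise(self, balanced_tree):
        from kinetree import random_tree

        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            ds = generate(
                SimulationSpec(noise_level=0.10, seed=200 + rep),
                network=balanced_tree,
            )
            decoys = [random_tree(7, seed=500 + 3 * rep + j) for j in range(3)]
            decoys = [d for d in decoys if d.edges != balanced_tree.edges][:3]
            candidates = [balanced_tree] + decoys
            best, _ = select_best_network(candidates, ds.noisy, scheme="2")
            if best is balanced_tree:
                wins += 1
        assert wins >= int(0.9 * n_rep)
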