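"""First-order perturbation theory vs finite-difference and dense oracles."""

import numpy as np
import pytest

import graphsurgery.coalescence as coal_mod
from graphsurgery import (
    EdgePerturbation,
    WeightedNetwork,
    bc_slope,
    bc_star,
    coalescence_times,
    delta_M_action,
    delta_pi,
    delta_T,
    fixture,
    precompute,
    random_walk_ensemble,
    theta_matrices,
)
from graphsurgery.coalescence import build_redundant_system
from graphsurgery.perturb import delta_M_structure

from conftest import random_connected, random_weighted


def perturbed_net(net, i0, j0, eps):
    return net.with_edge_weight(i0, j0, net.weights[i0, j0] + eps)


def central_diff(net, i0, j0, h, func):
    hi = func(perturbed_net(net, i0, j0, h))
    lo = func(perturbed_net(net, i0, j0, -h))
    return (hi - lo) / (2 * h)


def pick_pairs(net, rng, k):
    """Sample k node pairs, mixing existing edges and non-edges."""
    edges = net.edges()
    nonedges = net.nonedges()
    picks = []
    for t in range(k):
        pool = edges if (t % 2 == 0 or not nonedges) else nonedges
        picks.append(pool[int(rng.integers(len(pool)))])
    return picks


def fd_base(net, i, j):
    """A network where central differences in w_ij are feasible.

    Non-adjacent pairs get an interior base weight of 0.5 so that both
    one-sided displacements stay nonnegative; the first-order formulas are
    the same at any base point.
    """
    if net.weights[i, j] == 0:
        return net.with_edge_weight(i, j, 0.5)
    return net


class TestDeltaPi:
    def test_triangle_pair_values(self, triangle):
        ws = precompute(triangle)
        d = delta_pi(ws, EdgePerturbation(0, 1))
        assert d == pytest.approx([1 / 18, 1 / 18, -1 / 9])

    def test_k2_symmetric_zero(self, k2):
        ws = precompute(k2)
        assert delta_pi(ws, EdgePerturbation(0, 1)) == pytest.approx([0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 5])
    def test_sums_to_zero_and_matches_fd(self, seed):
        net = random_weighted(9, seed=seed)
        rng = np.random.default_rng(seed)
        for (i, j) in pick_pairs(net, rng, 4):
            base = fd_base(net, i, j)
            d = delta_pi(precompute(base), EdgePerturbation(i, j))
            assert d.sum() == pytest.approx(0.0, abs=1e-14)
            fd = central_diff(base, i, j, 1e-6,
                              lambda g: random_walk_ensemble(g).pi)
            assert d == pytest.approx(fd, abs=1e-7)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            EdgePerturbation(2, 2)


class TestThetaMatrices:
    def test_triangle_entries(self, triangle):
        ws = precompute(triangle)
        th1, _, _ = theta_matrices(ws, EdgePerturbation(0, 1))
        assert th1[0, 1] == pytest.approx(1 / 4)
        assert th1[0, 2] == pytest.approx(-1 / 4)
        assert th1[0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 7])
    def test_rows_sum_zero_and_sparsity(self, seed):
        net = random_connected(10, seed=seed)
        ws = precompute(net)
        i, j = net.edges()[0]
        th1, th2, th3 = theta_matrices(ws, EdgePerturbation(i, j))
        for th in (th1, th2, th3):
            assert th.sum(axis=1) == pytest.approx(np.zeros(10), abs=1e-12)
        # first-order rows outside the perturbed pair are exactly zero
        others = [r for r in range(10) if r not in (i, j)]
        assert np.all(th1[others] == 0.0)

    @pytest.mark.parametrize("seed", list(range(5)))
    def test_entrywise_equals_composed(self, seed):
        """Closed-form entries agree with the product-rule composition."""
        net = random_weighted(int(np.random.default_rng(seed).integers(6, 20)),
                              seed=seed)
        ws = precompute(net)
        rng = np.random.default_rng(seed + 100)
        for (i, j) in pick_pairs(net, rng, 3):
            ent = theta_matrices(ws, EdgePerturbation(i, j), method="entrywise")
            comp = theta_matrices(ws, EdgePerturbation(i, j), method="composed")
            for a, b in zip(ent, comp):
                assert np.abs(a - b).max() < 1e-10

    def test_matches_finite_difference(self):
        net = random_weighted(8, seed=3)
        ws = precompute(net)
        i, j = net.edges()[1]
        th = theta_matrices(ws, EdgePerturbation(i, j))
        for k, thk in enumerate(th, start=1):
            fd = central_diff(net, i, j, 1e-6, lambda g, k=k: np.linalg.
                              matrix_power(random_walk_ensemble(g).P, k))
            assert np.abs(thk - fd).max() < 1e-7


class TestDeltaM:
    @pytest.mark.parametrize("n,seed", [(6, 0), (9, 1), (12, 2)])
    def test_structural_rows_are_4n_minus_6(self, n, seed):
        net = random_connected(n, seed=seed)
        ws = precompute(net)
        rng = np.random.default_rng(seed)
        for (i, j) in pick_pairs(net, rng, 3):
            dM = delta_M_structure(ws, EdgePerturbation(i, j))
            nz_rows = np.unique(dM.tocoo().row)
            assert len(nz_rows) == 4 * n - 6
            # and they are exactly the ordered pairs touching i0 or j0
            a, b = nz_rows // n, nz_rows % n
            assert np.all((a != b) & ((a == i) | (a == j) | (b == i) | (b == j)))

    def test_action_zero_off_pattern_and_matches_dense(self):
        net = random_connected(8, seed=4)
        ws = precompute(net)
        i0, j0 = net.edges()[2]
        V = delta_M_action(ws, EdgePerturbation(i0, j0))
        others = [r for r in range(8) if r not in (i0, j0)]
        assert np.all(V[np.ix_(others, others)] == 0.0)
        # dense finite-difference of the explicitly assembled system
        h = 1e-6
        Mh, _ = build_redundant_system(
            random_walk_ensemble(perturbed_net(net, i0, j0, h)).P)
        Ml, _ = build_redundant_system(
            random_walk_ensemble(perturbed_net(net, i0, j0, -h)).P)
        dM_fd = (Mh - Ml) / (2 * h)
        v_fd = dM_fd @ ws.coalescence.T.ravel()
        assert np.abs(V.ravel() - v_fd).max() < 1e-7


class TestDeltaT:
    def test_k2_delta_T_zero(self, k2):
        ws = precompute(k2)
        dT = delta_T(ws, EdgePerturbation(0, 1))
        assert np.abs(dT).max() < 1e-12

    def test_matches_dense_linear_algebra_oracle(self):
        net = random_connected(8, seed=9)
        ws = precompute(net)
        i0, j0 = net.edges()[0]
        pert = EdgePerturbation(i0, j0)
        dT = delta_T(ws, pert)
        M = ws.coalescence.M.toarray()
        dM = delta_M_structure(ws, pert).toarray()
        vec_dT = -np.linalg.solve(M, dM @ ws.coalescence.T.ravel())
        assert np.abs(dT.ravel() - vec_dT).max() < 1e-8
        assert dT == pytest.approx(dT.T, abs=1e-12)
        assert np.all(np.diag(dT) == 0.0)

    def test_matches_full_resolve_fd(self):
        net = random_weighted(8, seed=11)
        ws = precompute(net)
        i0, j0 = net.edges()[3]
        dT = delta_T(ws, EdgePerturbation(i0, j0))
        fd = central_diff(net, i0, j0, 1e-5, lambda g: coalescence_times(g).T)
        assert np.abs(dT - fd).max() < 1e-6


class TestBcSlope:
    def test_vertex_transitive_symmetry(self, cycle6):
        ws = precompute(cycle6)
        slopes = [bc_slope(ws, EdgePerturbation(i, j)) for i, j in cycle6.edges()]
        assert np.ptp(slopes) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1])
    def test_quadratic_convergence_of_fd_residual(self, seed):
        """Central-difference residuals of the slope decay as O(h^2)."""
        net = random_connected(10, seed=seed + 20)
        rng = np.random.default_rng(seed)
        for (i, j) in pick_pairs(net, rng, 3):
            base = fd_base(net, i, j)
            slope = bc_slope(precompute(base), EdgePerturbation(i, j))
            res = []
            for h in (1e-2, 1e-3):
                fd = central_diff(base, i, j, h, lambda g: bc_star(g).bc_star)
                res.append(abs(fd - slope))
            order = np.log(res[0] / res[1]) / np.log(10)
            assert 1.7 < order < 2.3 or res[1] < 1e-11

    def test_gamma_matches_tau_fd(self):
        net = random_weighted(9, seed=13)
        ws = precompute(net)
        i, j = net.edges()[1]
        terms = bc_slope(ws, EdgePerturbation(i, j), full=True)
        for k in (1, 2, 3):
            fd = central_diff(net, i, j, 1e-5,
                              lambda g, k=k: getattr(bc_star(g), f"tau{k}"))
            assert terms.gamma[k - 1] == pytest.approx(fd, abs=1e-6, rel=1e-5)

    def test_degenerate_base_rejected(self):
        ws = precompute(fixture("cycle", 4))
        with pytest.raises(ValueError, match="degenerate|undefined"):
            bc_slope(ws, EdgePerturbation(0, 1))


class TestWorkspaceReuse:
    def test_per_edge_queries_do_not_refactorize(self):
        net = random_connected(12, seed=17)
        ws = precompute(net)
        before = coal_mod.FACTORIZATION_COUNT
        for (i, j) in net.edges()[:5]:
            bc_slope(ws, EdgePerturbation(i, j))
        assert coal_mod.FACTORIZATION_COUNT == before

    def test_precompute_deterministic(self):
        net = random_connected(10, seed=23)
        a = precompute(net)
        b = precompute(net)
        assert np.array_equal(a.coalescence.T, b.coalescence.T)
        assert a.tau.bc_star == b.tau.bc_star
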