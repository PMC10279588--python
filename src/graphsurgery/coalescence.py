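"""Coalescing random walks and the critical benefit-to-cost ratio.

Under death-birth updating with weak selection, whether cooperation is
favored on a connected weighted network is governed by the threshold
(b/c)* = tau2 / (tau3 - tau1), where tau_k = pi (P^k o T) 1 is the
expected meeting time of the two endpoints of a k-step stationary random
walk.  T is the matrix of pairwise mean coalescence times of two walkers,
one of which (picked with probability 1/2) moves at each step:

    t_ij = 0                                        if i = j,
    t_ij = 1 + (1/2) sum_k (p_ik t_jk + p_jk t_ik)  otherwise.

Formulations
------------
Three equivalent routes to T are maintained.

* ``spectral`` (default): off the diagonal the system is the Lyapunov-type
  matrix equation  T - (P T + T P^T)/2 = 1 1^T - diag(c), with an unknown
  diagonal correction c pinned by the N constraints t_ii = 0.  Because
  P = D^{-1} W is similar to the symmetric matrix D^{-1/2} W D^{-1/2}, one
  eigendecomposition diagonalizes the Lyapunov operator, and every
  subsequent solve (including the per-edge perturbation solves) costs a
  few dense N x N products.  This keeps dense O(N^3) scaling with a small
  constant; sparse LU of the pair system suffers massive fill-in.
* ``compact``: sparse LU of the N(N-1)/2-unknown folded system, one
  equation per unordered pair.
* the redundant N^2 x N^2 vectorization  M(0) vec(T) = d  with one
  equation per ordered pair: the object the single-edge perturbation
  theory differentiates, exposed for oracles and for the sparse-structure
  contracts (4N - 6 nonzero rows of dM).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh, lu_factor, lu_solve
from scipy.sparse.linalg import splu

from .netio import WeightedNetwork

__all__ = [
    "GameParams",
    "RandomWalkEnsemble",
    "CoalescenceSolution",
    "TauSummary",
    "random_walk_ensemble",
    "coalescence_times",
    "tau_summary",
    "regular_reference",
    "fixation_linear",
    "bc_star",
    "pair_coupling_matrix",
    "build_redundant_system",
]

#: incremented on every from-scratch factorization/decomposition of the
#: coalescence system; lets tests assert that per-edge perturbation
#: queries reuse the workspace instead of re-solving.
FACTORIZATION_COUNT = 0


@dataclass(frozen=True)
class GameParams:
    """Donation-game parameters: benefit b > cost c > 0, selection strength eta."""

    b: float
    c: float
    eta: float = 0.0

    def __post_init__(self):
        if not (self.b > self.c > 0):
            raise ValueError("donation game requires b > c > 0")
        if self.eta < 0:
            raise ValueError("selection strength eta must be >= 0")


@dataclass(frozen=True)
class RandomWalkEnsemble:
    """Stationary random-walk quantities of a weighted network.

    pi_i = s_i / S with s_i the node strength and S their sum; P = D^-1 W
    is the one-step transition matrix, P2 and P3 its powers.
    """

    pi: np.ndarray
    P: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    strengths: np.ndarray
    total_strength: float


@dataclass(frozen=True)
class TauSummary:
    """tau_1..tau_3 and the critical ratio (b/c)* = tau2 / (tau3 - tau1).

    ``degenerate`` is True when tau3 == tau1 (bc_star is signed infinity);
    a nonpositive ``bc_star`` means cooperation is never favored at any
    benefit-to-cost ratio.
    """

    tau1: float
    tau2: float
    tau3: float
    bc_star: float
    degenerate: bool = False

    @property
    def cooperation_possible(self) -> bool:
        return (not self.degenerate) and self.bc_star > 0


def random_walk_ensemble(net: WeightedNetwork) -> RandomWalkEnsemble:
    """Stationary distribution and transition-matrix powers (P = D^-1 W)."""
    w = net.weights
    s = w.sum(axis=1)
    if np.any(s <= 0):
        raise ValueError("isolated node (zero strength)")
    S = float(s.sum())
    P = w / s[:, None]
    P2 = P @ P
    return RandomWalkEnsemble(pi=s / S, P=P, P2=P2, P3=P2 @ P,
                              strengths=s, total_strength=S)


def pair_coupling_matrix(Q: np.ndarray, n: int) -> sp.csr_matrix:
    """Sparse A(Q) with A[(i,j),(j,k)] = Q_ik / 2 and A[(i,j),(i,k)] = Q_jk / 2.

    Rows are ordered pairs (i, j) at index i*n + j; rows with i == j are
    structurally zero.  With Q = P this is the coupling part of the
    redundant coalescence system (M = I - A(P)); with Q the first-order
    transition derivative Theta^(1) it is -dM/d(epsilon).
    """
    # a pre-built sparse Q may carry explicit zeros to preserve structural
    # pattern (e.g. a leaf node's transition derivative)
    Qs = Q.tocoo() if sp.issparse(Q) else sp.coo_matrix(Q)
    r, c, v = Qs.row, Qs.col, Qs.data
    nnz = len(v)
    idx = np.arange(n)
    # row (i, j) -> col (j, k), value Q_ik / 2, for all j
    rows1 = np.repeat(r, n) * n + np.tile(idx, nnz)
    cols1 = np.tile(idx, nnz) * n + np.repeat(c, n)
    # row (i, j) -> col (i, k), value Q_jk / 2, for all i
    rows2 = np.tile(idx, nnz) * n + np.repeat(r, n)
    cols2 = np.tile(idx, nnz) * n + np.repeat(c, n)
    rows = np.concatenate([rows1, rows2])
    cols = np.concatenate([cols1, cols2])
    vals = np.concatenate([np.repeat(v, n), np.repeat(v, n)]) * 0.5
    keep = (rows // n) != (rows % n)  # diagonal-pair rows carry t_ii = 0 instead
    A = sp.coo_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n * n, n * n))
    return A.tocsr()


def build_redundant_system(P: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Redundant system M vec(T) = d over all ordered pairs.

    Row (i, j) with i != j encodes t_ij - (1/2) sum_k (p_ik t_jk
    + p_jk t_ik) = 1; row (i, i) encodes t_ii = 0.
    """
    n = P.shape[0]
    M = (sp.identity(n * n, format="csr") - pair_coupling_matrix(P, n)).tocsr()
    d = np.ones(n * n)
    d[np.arange(n) * n + np.arange(n)] = 0.0
    return M, d


class SpectralPairSolver:
    """Diagonalized solver for  X - (P X + X P^T)/2 = G - diag(c), x_ii = 0.

    With A = D^{-1/2} W D^{-1/2} = U diag(lam) U^T, substituting
    X = D^{-1/2} U Y U^T D^{-1/2} turns the Lyapunov operator into the
    entrywise factor  delta_ab = 1 - (lam_a + lam_b)/2, which vanishes
    only at the top pair (Perron eigenvalue 1, kernel 1 1^T / S).  The
    unknown diagonal correction c and the kernel coefficient alpha are
    pinned by the N zero-diagonal constraints plus the solvability
    condition s^T (G - diag(c)) s = 0; their (N+1) x (N+1) coefficient
    matrix is right-hand-side independent and LU-factorized once.
    """

    def __init__(self, net: WeightedNetwork, tol: float = 1e-10,
                 block: int = 64):
        global FACTORIZATION_COUNT
        FACTORIZATION_COUNT += 1
        w = net.weights
        self.n = n = w.shape[0]
        self.s = s = w.sum(axis=1)
        self.S = float(s.sum())
        rt = np.sqrt(s)
        A = w / np.outer(rt, rt)
        lam, U = eigh(A)
        if lam[-1] < 1 - 1e-8 or (n > 1 and lam[-2] > 1 - 1e-12):
            raise np.linalg.LinAlgError(
                "Perron eigenvalue not simple; is the network connected?")
        delta = 1.0 - 0.5 * (lam[:, None] + lam[None, :])
        R = np.zeros_like(delta)
        mask = np.abs(delta) > tol
        R[mask] = 1.0 / delta[mask]
        R[-1, -1] = 0.0  # kernel direction handled via alpha
        self.lam, self.U, self.R = lam, U, R
        self.Urt = U * rt[:, None]        # rows: D^{1/2}-weighted eigvecs
        self.Uinvrt = U / rt[:, None]     # rows: D^{-1/2}-weighted eigvecs
        # B_ij = (s_j / s_i) H_ij with H_ij = z_ij^T R z_ij, z_ij = U_i o U_j:
        # diagonal response of the particular solution to diag(e_j) inputs
        H = np.empty((n, n))
        for lo in range(0, n, block):
            hi = min(lo + block, n)
            Z = U[lo:hi, None, :] * U[None, :, :]      # (b, n, n_eig)
            H[lo:hi] = np.einsum("ijk,ijk->ij", Z @ R, Z)
        B = H * (s[None, :] / s[:, None])
        sys = np.zeros((n + 1, n + 1))
        sys[:n, :n] = -B
        sys[:n, n] = 1.0 / self.S
        sys[n, :n] = s ** 2
        self._sys_lu = lu_factor(sys)

    def _particular(self, G: np.ndarray) -> np.ndarray:
        """F(G): kernel-free solution of the Lyapunov equation L(X) = G."""
        Gt = self.Urt.T @ G @ self.Urt
        return self.Uinvrt @ (self.R * Gt) @ self.Uinvrt.T

    def solve(self, G: np.ndarray) -> np.ndarray:
        """Symmetric zero-diagonal X with off-diagonal L(X)_ij = G_ij.

        Equivalently M vec(X) = vec(G') where G' is G with its diagonal
        zeroed and M is the redundant pair system.
        """
        n = self.n
        Tp = self._particular(G)
        rhs = np.empty(n + 1)
        rhs[:n] = -np.diag(Tp)
        rhs[n] = self.s @ G @ self.s
        sol = lu_solve(self._sys_lu, rhs)
        c, alpha = sol[:n], sol[n]
        X = Tp - self._particular(np.diag(c)) + alpha / self.S
        X = 0.5 * (X + X.T)
        np.fill_diagonal(X, 0.0)
        return X


@dataclass
class CoalescenceSolution:
    """Pairwise mean coalescence times and the reusable linear system.

    ``T`` is symmetric with zero diagonal.  ``solve_symmetric`` applies
    M(0)^{-1} to the vectorization of a symmetric zero-diagonal right-hand
    side, reusing the stored decomposition; the sparse redundant system
    ``M``, ``d`` is materialized lazily for oracles and structure checks.
    """

    T: np.ndarray
    P: np.ndarray
    _solver: SpectralPairSolver

    @cached_property
    def M(self) -> sp.csr_matrix:
        return build_redundant_system(self.P)[0]

    @cached_property
    def d(self) -> np.ndarray:
        return build_redundant_system(self.P)[1]

    def solve_symmetric(self, rhs: np.ndarray) -> np.ndarray:
        """X with M vec(X) = vec(rhs), for symmetric zero-diagonal rhs."""
        return self._solver.solve(np.asarray(rhs, dtype=float))


def _coalescence_compact(P: np.ndarray) -> np.ndarray:
    """Reference route: sparse LU of the folded N(N-1)/2-unknown system."""
    n = P.shape[0]
    M, _ = build_redundant_system(P)
    iu, ju = np.triu_indices(n, k=1)
    npairs = len(iu)
    rows = np.concatenate([iu * n + ju, ju * n + iu])
    cols = np.concatenate([np.arange(npairs), np.arange(npairs)])
    C = sp.coo_matrix((np.ones(2 * npairs), (rows, cols)),
                      shape=(n * n, npairs)).tocsr()
    Mc = M[iu * n + ju, :] @ C
    t = splu(Mc.tocsc()).solve(np.ones(npairs))
    T = np.zeros((n, n))
    T[iu, ju] = t
    T[ju, iu] = t
    return T


def coalescence_times(net: WeightedNetwork, method: str = "spectral",
                      residual_tol: float = 1e-9) -> CoalescenceSolution:
    """Solve the pairwise mean-coalescence-time system exactly.

    ``method='spectral'`` (default) uses the diagonalized Lyapunov solver;
    ``'compact'`` solves the folded sparse system by LU (slow for large N,
    kept as an independent route).  The residual of the defining equations
    is verified below ``residual_tol`` in max norm.
    """
    global FACTORIZATION_COUNT
    n = net.n_nodes
    ens = random_walk_ensemble(net)
    solver = SpectralPairSolver(net)
    if n == 1:
        return CoalescenceSolution(T=np.zeros((1, 1)), P=ens.P, _solver=solver)
    if method == "spectral":
        T = solver.solve(np.ones((n, n)))
    elif method == "compact":
        FACTORIZATION_COUNT += 1
        T = _coalescence_compact(ens.P)
    else:
        raise ValueError(f"unknown method {method!r}")
    # residual of the defining recurrence, off-diagonal entries
    resid = T - 0.5 * (ens.P @ T + T @ ens.P.T) - 1.0
    np.fill_diagonal(resid, 0.0)
    worst = np.abs(resid).max()
    if worst > residual_tol:
        raise np.linalg.LinAlgError(
            f"coalescence residual {worst:.3e} exceeds {residual_tol:.1e}")
    if np.any(T[~np.eye(n, dtype=bool)] < 1.0 - 1e-9):
        raise np.linalg.LinAlgError("coalescence times below 1; solver failure")
    return CoalescenceSolution(T=T, P=ens.P, _solver=solver)


def tau_summary(net: WeightedNetwork,
                ens: RandomWalkEnsemble | None = None,
                coal: CoalescenceSolution | None = None) -> TauSummary:
    """tau_k = pi (P^k o T) 1 for k = 1, 2, 3 and (b/c)* = tau2/(tau3 - tau1)."""
    if ens is None:
        ens = random_walk_ensemble(net)
    if coal is None:
        coal = coalescence_times(net)
    T = coal.T
    one = np.ones(net.n_nodes)
    tau1 = float(ens.pi @ (ens.P * T) @ one)
    tau2 = float(ens.pi @ (ens.P2 * T) @ one)
    tau3 = float(ens.pi @ (ens.P3 * T) @ one)
    denom = tau3 - tau1
    if denom == 0.0:
        return TauSummary(tau1, tau2, tau3,
                          bc_star=np.inf if tau2 >= 0 else -np.inf,
                          degenerate=True)
    return TauSummary(tau1, tau2, tau3, bc_star=tau2 / denom)


def bc_star(net: WeightedNetwork) -> TauSummary:
    """Convenience pipeline: ensemble + coalescence + tau summary."""
    ens = random_walk_ensemble(net)
    coal = coalescence_times(net)
    return tau_summary(net, ens, coal)


def regular_reference(n: int, k: int) -> TauSummary:
    """Closed forms for unweighted regular graphs of degree k on n nodes.

    tau1 = n - 1, tau2 = n - 2, tau3 = n + n/k - 3, so that
    (b/c)* = (n - 2) / (n/k - 2), approaching k as n grows.
    """
    if k <= 0:
        raise ValueError("degree k must be positive")
    if k > n - 1:
        raise ValueError("regular degree k cannot exceed n - 1")
    tau1 = float(n - 1)
    tau2 = float(n - 2)
    tau3 = n + n / k - 3.0
    denom = tau3 - tau1
    if denom == 0.0:
        return TauSummary(tau1, tau2, tau3,
                          bc_star=np.inf if tau2 >= 0 else -np.inf,
                          degenerate=True)
    return TauSummary(tau1, tau2, tau3, bc_star=tau2 / denom)


def fixation_linear(tau: TauSummary, game: GameParams, n: int) -> float:
    """First-order weak-selection fixation probability of cooperation.

    rho_C = 1/N + (eta / 2N) [ -c tau2 + b (tau3 - tau1) ] + O(eta^2),
    for a single cooperator placed uniformly at random.
    """
    return 1.0 / n + (game.eta / (2.0 * n)) * (
        -game.c * tau.tau2 + game.b * (tau.tau3 - tau.tau1))
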