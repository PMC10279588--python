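"""First-order perturbation theory for single-edge graph surgery.

Changing the weight of one edge (i0, j0) by epsilon shifts every
random-walk quantity; to first order,

    pi(eps)  = pi(0)  + eps * dpi,
    P^k(eps) = P^k(0) + eps * Theta^(k),      k = 1, 2, 3,
    T(eps)   = T(0)   + eps * dT,
    tau_k(eps) = tau_k(0) + eps * Gamma_k,

and the slope of the critical ratio follows by the quotient rule:

    d(b/c)* = [ (tau3 - tau1) Gamma_2 - tau2 (Gamma_3 - Gamma_1) ]
              / (tau3 - tau1)^2.

dT solves  M(0) vec(dT) = -dM vec(T(0)),  where dM is the epsilon
derivative of the redundant coalescence system.  dM has at most 4N - 6
structurally nonzero rows (the ordered pairs touching i0 or j0), so its
action costs O(N^2) and the whole per-edge query stays within O(N^3)
after a one-time precomputation on the base network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .coalescence import (
    CoalescenceSolution,
    RandomWalkEnsemble,
    TauSummary,
    coalescence_times,
    pair_coupling_matrix,
    random_walk_ensemble,
    tau_summary,
)
from .netio import WeightedNetwork

__all__ = [
    "EdgePerturbation",
    "FirstOrderTerms",
    "PerturbationWorkspace",
    "precompute",
    "delta_pi",
    "theta_matrices",
    "delta_M_action",
    "delta_T",
    "bc_slope",
]

Mode = Literal["removal", "addition", "enhancement"]


@dataclass(frozen=True)
class EdgePerturbation:
    """A signed weight change epsilon on the node pair (i0, j0), i0 != j0.

    ``mode`` encodes the surgery type: removal reduces the weight of an
    existing edge (-w <= eps < 0), addition creates a new edge (eps > 0
    where none exists), enhancement increases an existing weight (eps > 0).
    The first-order objects depend only on (i0, j0); epsilon scales them.
    """

    i0: int
    j0: int
    epsilon: float = 0.0
    mode: Mode | None = None

    def __post_init__(self):
        if self.i0 == self.j0:
            raise ValueError("self-loop perturbations (i0 == j0) are not supported")

    def validate_against(self, net: WeightedNetwork) -> None:
        """Check the mode/epsilon constraints against the base weights."""
        w = net.weights[self.i0, self.j0]
        if self.mode == "removal":
            if w <= 0:
                raise ValueError("removal requires an existing edge")
            if not (-w <= self.epsilon < 0):
                raise ValueError(f"removal requires -{w} <= eps < 0")
        elif self.mode == "addition":
            if w != 0:
                raise ValueError("addition requires w[i0, j0] == 0")
            if self.epsilon <= 0:
                raise ValueError("addition requires eps > 0")
        elif self.mode == "enhancement":
            if w <= 0:
                raise ValueError("enhancement requires an existing edge")
            if self.epsilon <= 0:
                raise ValueError("enhancement requires eps > 0")

    def chi(self, n: int) -> np.ndarray:
        """Symmetric indicator matrix of the perturbed pair."""
        chi = np.zeros((n, n))
        chi[self.i0, self.j0] = chi[self.j0, self.i0] = 1.0
        return chi


@dataclass(frozen=True)
class FirstOrderTerms:
    """All first-order derivatives for one edge perturbation."""

    delta_pi: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    theta3: np.ndarray
    delta_T: np.ndarray
    gamma: tuple[float, float, float]
    slope: float


@dataclass(frozen=True)
class PerturbationWorkspace:
    """Base-network quantities reused across per-edge slope queries.

    Built once per network; per-edge queries only form the sparse dM
    action and back-substitute through the retained factorization, never
    re-solving the coalescence system from scratch.
    """

    net: WeightedNetwork
    ensemble: RandomWalkEnsemble
    coalescence: CoalescenceSolution
    tau: TauSummary


def precompute(net: WeightedNetwork) -> PerturbationWorkspace:
    """Solve the base network once and package everything per-edge queries need."""
    ens = random_walk_ensemble(net)
    coal = coalescence_times(net)
    tau = tau_summary(net, ens, coal)
    return PerturbationWorkspace(net=net, ensemble=ens, coalescence=coal, tau=tau)


def delta_pi(ws: PerturbationWorkspace, pert: EdgePerturbation) -> np.ndarray:
    """d pi_i / d eps = (delta_{i,i0} + delta_{i,j0}) / S - 2 pi_i / S."""
    n = ws.net.n_nodes
    S = ws.ensemble.total_strength
    d = -2.0 * ws.ensemble.pi / S
    d[pert.i0] += 1.0 / S
    d[pert.j0] += 1.0 / S
    return d


def _theta1(ws: PerturbationWorkspace, pert: EdgePerturbation) -> np.ndarray:
    """Entrywise first-order transition derivative.

    theta^(1)_ij = chi_{i0j0}(i, j)/s_i - p_ij (delta_{i,i0}+delta_{i,j0})/s_i;
    only rows i0 and j0 are nonzero.
    """
    n = ws.net.n_nodes
    s = ws.ensemble.strengths
    P = ws.ensemble.P
    i0, j0 = pert.i0, pert.j0
    th = np.zeros((n, n))
    th[i0] = -P[i0] / s[i0]
    th[i0, j0] += 1.0 / s[i0]
    th[j0] = -P[j0] / s[j0]
    th[j0, i0] += 1.0 / s[j0]
    return th


def _theta23_entrywise(ws: PerturbationWorkspace,
                       pert: EdgePerturbation) -> tuple[np.ndarray, np.ndarray]:
    """Theta^(2), Theta^(3) written out entrywise (no matrix products)."""
    n = ws.net.n_nodes
    s = ws.ensemble.strengths
    P, P2, P3 = ws.ensemble.P, ws.ensemble.P2, ws.ensemble.P3
    i0, j0 = pert.i0, pert.j0

    th2 = np.zeros((n, n))
    th2[i0] += P[j0] / s[i0]
    th2[j0] += P[i0] / s[j0]
    th2[i0] -= P2[i0] / s[i0]
    th2[j0] -= P2[j0] / s[j0]
    th2[:, j0] += P[:, i0] / s[i0]
    th2[:, i0] += P[:, j0] / s[j0]
    th2 -= np.outer(P[:, i0], P[i0]) / s[i0]
    th2 -= np.outer(P[:, j0], P[j0]) / s[j0]

    th3 = np.zeros((n, n))
    th3[i0] += P2[j0] / s[i0]
    th3[j0] += P2[i0] / s[j0]
    th3[i0] -= P3[i0] / s[i0]
    th3[j0] -= P3[j0] / s[j0]
    th3 += np.outer(P[:, i0], P[j0]) / s[i0]
    th3 += np.outer(P[:, j0], P[i0]) / s[j0]
    th3 -= np.outer(P[:, i0], P2[i0]) / s[i0]
    th3 -= np.outer(P[:, j0], P2[j0]) / s[j0]
    th3[:, j0] += P2[:, i0] / s[i0]
    th3[:, i0] += P2[:, j0] / s[j0]
    th3 -= np.outer(P2[:, i0], P[i0]) / s[i0]
    th3 -= np.outer(P2[:, j0], P[j0]) / s[j0]
    return th2, th3


def theta_matrices(ws: PerturbationWorkspace, pert: EdgePerturbation,
                   method: Literal["entrywise", "composed"] = "entrywise",
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order derivatives of P, P^2, P^3 with respect to epsilon.

    ``entrywise`` evaluates the closed-form entries; ``composed`` uses the
    product rule  Theta^(2) = Theta^(1) P + P Theta^(1)  and
    Theta^(3) = Theta^(1) P^2 + P Theta^(1) P + P^2 Theta^(1).  The two
    agree to rounding and serve as mutual cross-checks.
    """
    th1 = _theta1(ws, pert)
    if method == "entrywise":
        th2, th3 = _theta23_entrywise(ws, pert)
    elif method == "composed":
        P, P2 = ws.ensemble.P, ws.ensemble.P2
        th2 = th1 @ P + P @ th1
        th3 = th1 @ P2 + P @ th1 @ P + P2 @ th1
    else:
        raise ValueError(f"unknown method {method!r}")
    return th1, th2, th3


def delta_M_structure(ws: PerturbationWorkspace,
                      pert: EdgePerturbation) -> sp.csr_matrix:
    """The sparse dM matrix itself (epsilon derivative of the redundant system).

    dM = -A(Theta^(1)) in the notation of
    :func:`graphsurgery.coalescence.pair_coupling_matrix`: its structurally
    nonzero rows are exactly the 4N - 6 ordered pairs (i, j), i != j, with
    i or j in {i0, j0}.
    """
    n = ws.net.n_nodes
    th1 = _theta1(ws, pert)
    # keep explicit zeros: the structural pattern of a transition-derivative
    # row is (neighbors of the node) + the perturbed partner, even where the
    # value cancels exactly (leaf nodes)
    rows, cols, vals = [], [], []
    for a, other in ((pert.i0, pert.j0), (pert.j0, pert.i0)):
        pattern = set(np.nonzero(ws.net.weights[a])[0].tolist()) | {other}
        for k in sorted(pattern):
            rows.append(a)
            cols.append(k)
            vals.append(th1[a, k])
    th1_struct = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return (-pair_coupling_matrix(th1_struct, n)).tocsr()


def delta_M_action(ws: PerturbationWorkspace, pert: EdgePerturbation,
                   theta1: np.ndarray | None = None) -> np.ndarray:
    """v = dM vec(T(0)) as an N x N matrix, touching only the 4N - 6 rows.

    Row (i, j) of dM holds -theta^(1)_ik / 2 on column (j, k) and
    -theta^(1)_jk / 2 on column (i, k), so
    v_ij = -(1/2) [ (Theta^(1) T)_ij + (Theta^(1) T)_ji ]  for i != j,
    which is nonzero only when i or j is the perturbed pair.  Cost O(N^2):
    Theta^(1) has two nonzero rows.
    """
    if theta1 is None:
        theta1 = _theta1(ws, pert)
    T = ws.coalescence.T
    i0, j0 = pert.i0, pert.j0
    # Theta^(1) T has only rows i0, j0 nonzero
    rows = {i0: theta1[i0] @ T, j0: theta1[j0] @ T}
    n = ws.net.n_nodes
    V = np.zeros((n, n))
    for a in (i0, j0):
        V[a, :] -= 0.5 * rows[a]
        V[:, a] -= 0.5 * rows[a]
    np.fill_diagonal(V, 0.0)
    return V


def delta_T(ws: PerturbationWorkspace, pert: EdgePerturbation,
            theta1: np.ndarray | None = None) -> np.ndarray:
    """dT solving  M(0) vec(dT) = -dM vec(T(0)), symmetric, zero diagonal."""
    V = delta_M_action(ws, pert, theta1=theta1)
    return ws.coalescence.solve_symmetric(-V)


def bc_slope(ws: PerturbationWorkspace, pert: EdgePerturbation,
             full: bool = False):
    """Gamma_1..3 and the slope d(b/c)* for one edge perturbation.

    Gamma_k = dpi (P^k o T) 1 + pi (Theta^(k) o T) 1 + pi (P^k o dT) 1.
    Raises on a degenerate base (tau3 == tau1).
    """
    if ws.tau.degenerate:
        raise ValueError("(b/c)* undefined on the base network: tau3 == tau1")
    ens = ws.ensemble
    T = ws.coalescence.T
    n = ws.net.n_nodes
    one = np.ones(n)
    dpi = delta_pi(ws, pert)
    th1, th2, th3 = theta_matrices(ws, pert)
    dT = delta_T(ws, pert, theta1=th1)
    gammas = []
    for Pk, thk in ((ens.P, th1), (ens.P2, th2), (ens.P3, th3)):
        g = (dpi @ (Pk * T) @ one
             + ens.pi @ (thk * T) @ one
             + ens.pi @ (Pk * dT) @ one)
        gammas.append(float(g))
    g1, g2, g3 = gammas
    denom = ws.tau.tau3 - ws.tau.tau1
    slope = (denom * g2 - ws.tau.tau2 * (g3 - g1)) / denom ** 2
    if full:
        return FirstOrderTerms(delta_pi=dpi, theta1=th1, theta2=th2,
                               theta3=th3, delta_T=dT,
                               gamma=(g1, g2, g3), slope=slope)
    return slope
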