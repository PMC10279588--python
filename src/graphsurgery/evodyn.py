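"""Forward death-birth evolutionary dynamics of the donation game.

Validators for the coalescence-based theory: a Monte-Carlo estimator of
the fixation probability rho_C of cooperation, and an exact 2^N
absorbing-Markov-chain oracle for small networks.

One update round: a node i to be replaced is drawn uniformly at random;
one of its neighbors j is drawn with probability proportional to
w_ij * R_j(x), where R_j(x) = 1 + eta * f_j(x) and
f_j(x) = -c x_j + b sum_l p_jl x_l is the neighbor-averaged donation-game
payoff; i then copies j's type.  At eta = 0 this is the voter model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .coalescence import GameParams
from .netio import WeightedNetwork

__all__ = [
    "EvoState",
    "FixationEstimate",
    "db_step",
    "simulate_fixation",
    "exact_fixation_small",
]

_EXACT_CAP = 14
_STEP_CAP = 10 ** 9


@dataclass
class EvoState:
    """Binary type vector: x_i = 1 for a cooperator, 0 for a defector."""

    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.int8)
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("state entries must be 0 or 1")

    @property
    def absorbed(self) -> bool:
        s = int(self.x.sum())
        return s == 0 or s == len(self.x)


@dataclass(frozen=True)
class FixationEstimate:
    """Fixation probability of cooperation with its Monte-Carlo error."""

    rho_C: float
    stderr: float
    replicates: int


def _payoffs(x: np.ndarray, P: np.ndarray, game: GameParams) -> np.ndarray:
    return -game.c * x + game.b * (P @ x)


def _check_rates(R: np.ndarray, game: GameParams) -> None:
    if np.any(R <= 0):
        raise ValueError(
            "nonpositive reproductive rate; use a smaller selection strength "
            f"eta (payoffs lie in [{-game.c}, {game.b}], need eta < "
            f"{1.0 / max(game.c, game.b):.4g})")


def selection_probabilities(state: EvoState, net: WeightedNetwork,
                            game: GameParams, i: int) -> np.ndarray:
    """Probability that each node reproduces into node i in one update.

    Neighbor j of the dying node i is selected with probability
    proportional to w_ij * R_j(x); at eta = 0 this reduces to the simple
    random-walk step w_ij / s_i (voter model).
    """
    x = state.x.astype(float)
    P = net.weights / net.weights.sum(axis=1, keepdims=True)
    R = 1.0 + game.eta * _payoffs(x, P, game)
    _check_rates(R, game)
    weights = net.weights[i] * R
    return weights / weights.sum()


def db_step(state: EvoState, net: WeightedNetwork, game: GameParams,
            rng: np.random.Generator) -> EvoState:
    """One death-birth update (returns a new state)."""
    i = int(rng.integers(net.n_nodes))
    probs = selection_probabilities(state, net, game, i)
    j = int(rng.choice(net.n_nodes, p=probs))
    new_x = state.x.copy()
    new_x[i] = state.x[j]
    return EvoState(new_x)


def _run_to_absorption(net: WeightedNetwork, game: GameParams,
                       start: int, rng: np.random.Generator) -> bool:
    """Simulate from a single cooperator at ``start``; True if C fixates."""
    n = net.n_nodes
    w = net.weights
    P = w / w.sum(axis=1, keepdims=True)
    x = np.zeros(n)
    x[start] = 1.0
    n_coop = 1
    for _ in range(_STEP_CAP):
        i = int(rng.integers(n))
        f = _payoffs(x, P, game)
        R = 1.0 + game.eta * f
        _check_rates(R, game)
        weights = w[i] * R
        j = int(rng.choice(n, p=weights / weights.sum()))
        if x[i] != x[j]:
            n_coop += int(x[j] - x[i])
            x[i] = x[j]
            if n_coop == 0:
                return False
            if n_coop == n:
                return True
    raise RuntimeError("absorption not reached within the step cap")


def simulate_fixation(net: WeightedNetwork, game: GameParams,
                      replicates: int, rng) -> FixationEstimate:
    """Monte-Carlo rho_C under uniform single-cooperator initialization.

    Each replicate gets its own deterministic substream so results are
    reproducible given the seed regardless of execution order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(rng, (int, np.integer)):
        base_seed = int(rng)
    else:
        base_seed = int(np.random.default_rng(rng).integers(2 ** 31))
    fixed = 0
    for rep in range(replicates):
        sub = np.random.default_rng([base_seed, rep])
        start = int(sub.integers(net.n_nodes))
        fixed += _run_to_absorption(net, game, start, sub)
    p = fixed / replicates
    stderr = float(np.sqrt(p * (1 - p) / replicates))
    return FixationEstimate(rho_C=p, stderr=stderr, replicates=replicates)


def exact_fixation_small(net: WeightedNetwork, game: GameParams,
                         per_start: bool = False):
    """Exact rho_C from the 2^N absorbing Markov chain (N <= 14).

    Builds the full state-space transition matrix of the death-birth
    process and solves the absorption probabilities into the all-cooperator
    state.  Averaged over the N single-cooperator initial states; with
    ``per_start=True`` also returns the length-N vector of per-start
    fixation probabilities.
    """
    n = net.n_nodes
    if n > _EXACT_CAP:
        raise ValueError(f"exact oracle capped at N = {_EXACT_CAP}")
    w = net.weights
    P = w / w.sum(axis=1, keepdims=True)
    n_states = 1 << n
    all_c = n_states - 1

    rows, cols, vals = [], [], []
    absorb = np.zeros(n_states)    # probability mass into the all-C state
    absorb_d = np.zeros(n_states)  # probability mass into the all-D state
    for s in range(1, all_c):
        x = np.array([(s >> i) & 1 for i in range(n)], dtype=float)
        f = _payoffs(x, P, game)
        R = 1.0 + game.eta * f
        _check_rates(R, game)
        for i in range(n):
            weights = w[i] * R
            probs = weights / weights.sum()
            for j in np.nonzero(w[i])[0]:
                if x[i] == x[j]:
                    continue
                t = s | (1 << i) if x[j] == 1 else s & ~(1 << i)
                p_trans = probs[j] / n
                if t == all_c:
                    absorb[s] += p_trans
                elif t == 0:
                    absorb_d[s] += p_trans
                else:
                    rows.append(s)
                    cols.append(t)
                    vals.append(p_trans)
    # rho(s) = sum_t Q(s,t) rho(t) + absorb(s) over transient states 1..2^N-2
    transient = np.arange(1, all_c)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    Q = Q[transient][:, transient]
    # the remaining mass is the self-transition (update leaves the state as is)
    stay = (1.0 - np.asarray(Q.sum(axis=1)).ravel()
            - absorb[transient] - absorb_d[transient])
    A = sp.identity(len(transient), format="csr") - Q \
        - sp.diags(stay, format="csr")
    rho = spsolve(A.tocsc(), absorb[transient])
    starts = np.array([rho[(1 << i) - 1] for i in range(n)])
    # state index of single cooperator at node i is 1 << i; position in
    # the transient array is (1 << i) - 1
    est = FixationEstimate(rho_C=float(starts.mean()), stderr=0.0,
                           replicates=0)
    if per_start:
        return est, starts
    return est
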