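"""Graph-surgery experiments: sweeps, slope-vs-actual correlations, greedy removal.

The perturbation slope is only a first-order object; these drivers measure
how well it predicts the actually recomputed change in (b/c)* at finite
epsilon (complete removal eps = -1, unweighted addition eps = +1, weight
enhancement 1 -> 2), and use it to pick edges for sequential removal
against the degree-sum heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .coalescence import bc_star
from .netio import WeightedNetwork
from .perturb import EdgePerturbation, PerturbationWorkspace, bc_slope, precompute

__all__ = [
    "SweepCurve",
    "PairRecord",
    "SurgeryReport",
    "GreedyTrajectory",
    "actual_change",
    "epsilon_sweep",
    "correlation_experiment",
    "greedy_removal",
    "degree_heuristic_removal",
]


@dataclass(frozen=True)
class SweepCurve:
    """(b/c)*(eps) - (b/c)*(0) along a grid of edge-weight changes."""

    pair: tuple[int, int]
    mode: str
    grid: np.ndarray
    values: np.ndarray

    def chord_deviation(self) -> float:
        """Max |curve - chord| over the grid, a nonlinearity statistic.

        The chord joins the curve's endpoints; a perfectly linear response
        (where the first-order slope is exact) gives 0.
        """
        g, v = self.grid, self.values
        if len(g) < 3:
            return 0.0
        chord = v[0] + (v[-1] - v[0]) * (g - g[0]) / (g[-1] - g[0])
        return float(np.abs(v - chord).max())


@dataclass(frozen=True)
class PairRecord:
    pair: tuple[int, int]
    slope: float
    actual: float | None
    valid: bool


@dataclass(frozen=True)
class SurgeryReport:
    """Per-pair slope vs actual change, and their Pearson correlation."""

    mode: str
    records: list[PairRecord]
    pearson_r: float
    p_value: float
    n: int
    n_excluded: int


@dataclass(frozen=True)
class GreedyTrajectory:
    """Edges removed in order and the exact (b/c)* after each removal."""

    strategy: str
    removed: list[tuple[int, int]]
    bc_values: list[float]
    base_bc: float
    stopped_early: bool = False


def _perturbed(net: WeightedNetwork, pert: EdgePerturbation) -> WeightedNetwork:
    new_w = net.weights[pert.i0, pert.j0] + pert.epsilon
    if new_w < 0 and new_w > -1e-12:
        new_w = 0.0
    return net.with_edge_weight(pert.i0, pert.j0, new_w)


def actual_change(net: WeightedNetwork, pert: EdgePerturbation,
                  base: float | None = None) -> float:
    """Exactly recomputed (b/c)*(eps) - (b/c)*(0).

    Raises ValueError if the perturbed network is disconnected (removal of
    a bridge) or (b/c)* is degenerate.
    """
    pert.validate_against(net)
    if base is None:
        base = bc_star(net).bc_star
    perturbed = _perturbed(net, pert)  # WeightedNetwork rejects disconnection
    return bc_star(perturbed).bc_star - base


def epsilon_sweep(net: WeightedNetwork, pair: tuple[int, int],
                  mode: str | None, grid=None) -> SweepCurve:
    """Actual change in (b/c)* along a grid of epsilon values.

    ``mode=None`` with an explicit grid skips the mode/epsilon-range
    validation (useful for two-sided grids around 0).
    """
    i0, j0 = pair
    if grid is None:
        if mode is None:
            raise ValueError("an explicit grid is required when mode is None")
        grid = {
            "removal": -np.arange(0.0, 1.05, 0.1),
            "addition": np.arange(0.0, 1.05, 0.1),
            "enhancement": np.arange(0.0, 1.05, 0.1),
        }[mode]
    grid = np.asarray(grid, dtype=float)
    base = bc_star(net).bc_star
    values = np.empty_like(grid)
    for idx, eps in enumerate(grid):
        if eps == 0.0:
            values[idx] = 0.0
            continue
        pert = EdgePerturbation(i0, j0, epsilon=float(eps), mode=mode)
        values[idx] = actual_change(net, pert, base=base)
    return SweepCurve(pair=(i0, j0), mode=mode, grid=grid, values=values)


def _bridges(net: WeightedNetwork) -> set[tuple[int, int]]:
    g = net.to_networkx()
    return {(min(u, v), max(u, v)) for u, v in nx.bridges(g)}


def has_bridges(net: WeightedNetwork) -> bool:
    """True if some edge's removal would disconnect the network."""
    return bool(_bridges(net))


def bridgeless_instance(make_net, seeds):
    """First network from ``make_net(seed)`` with no bridges.

    Removal experiments are defined on networks where every single edge
    can be removed without disconnection (the published instances satisfy
    this: their correlation sample sizes equal their edge counts).
    """
    for s in seeds:
        net = make_net(int(s))
        if not has_bridges(net):
            return net
    raise RuntimeError("no bridge-free instance found in the given seeds")


def _eligible_pairs(net: WeightedNetwork, mode: str):
    """(pairs, excluded_count): bridges are excluded in removal mode."""
    if mode == "removal":
        bridges = _bridges(net)
        edges = net.edges()
        return [e for e in edges if e not in bridges], len(bridges)
    if mode == "enhancement":
        return net.edges(), 0
    if mode == "addition":
        return net.nonedges(), 0
    raise ValueError(f"unknown mode {mode!r}")


def correlation_experiment(net: WeightedNetwork, mode: str,
                           workspace: PerturbationWorkspace | None = None,
                           ) -> SurgeryReport:
    """Slope vs actually recomputed change for every eligible pair.

    Finite epsilon per mode: -1 (complete removal), +1 (new unweighted
    edge), +1 (weight 1 -> 2).  Pearson r is taken over valid pairs;
    bridges are excluded from removal with a logged count.
    """
    ws = workspace if workspace is not None else precompute(net)
    base = ws.tau.bc_star
    eps = -1.0 if mode == "removal" else 1.0
    pairs, n_excluded = _eligible_pairs(net, mode)
    records = []
    for (i, j) in pairs:
        pert = EdgePerturbation(i, j, epsilon=eps, mode=mode)
        slope = bc_slope(ws, pert)
        try:
            actual = actual_change(net, pert, base=base)
        except (ValueError, np.linalg.LinAlgError):
            records.append(PairRecord((i, j), slope, None, False))
            n_excluded += 1
            continue
        records.append(PairRecord((i, j), slope, actual, True))
    valid = [r for r in records if r.valid]
    if len(valid) < 3:
        raise ValueError(f"fewer than 3 valid pairs in mode {mode!r}")
    slopes = np.array([r.slope for r in valid])
    actuals = np.array([r.actual for r in valid])
    r, p = stats.pearsonr(slopes, actuals)
    return SurgeryReport(mode=mode, records=records, pearson_r=float(r),
                         p_value=float(p), n=len(valid), n_excluded=n_excluded)


def _remove_edge(net: WeightedNetwork, i: int, j: int) -> WeightedNetwork:
    return net.with_edge_weight(i, j, 0.0)


def greedy_removal(net: WeightedNetwork, steps: int = 5) -> GreedyTrajectory:
    """Sequentially remove the edge with the largest perturbation slope.

    At each step all slopes are recomputed on the current network, the
    maximum-slope non-bridge edge is removed (ties broken by the lowest
    lexicographic pair), and the exact (b/c)* of the reduced network is
    recorded.
    """
    base = bc_star(net).bc_star
    removed: list[tuple[int, int]] = []
    values: list[float] = []
    current = net
    stopped = False
    for _ in range(steps):
        ws = precompute(current)
        candidates, _ = _eligible_pairs(current, "removal")
        if not candidates:
            stopped = True
            break
        slopes = np.array([
            bc_slope(ws, EdgePerturbation(i, j, epsilon=-current.weights[i, j],
                                          mode="removal"))
            for (i, j) in candidates])
        top = slopes.max()
        # symmetry-equal slopes differ only by rounding; tie-break lexicographic
        tol = 1e-9 * max(1.0, abs(top))
        i, j = min(e for e, s in zip(candidates, slopes) if s >= top - tol)
        current = _remove_edge(current, i, j)
        removed.append((i, j))
        values.append(bc_star(current).bc_star)
    return GreedyTrajectory(strategy="perturbation", removed=removed,
                            bc_values=values, base_bc=base,
                            stopped_early=stopped)


def degree_heuristic_removal(net: WeightedNetwork, steps: int = 5,
                             max_branches: int = 64, seed: int = 0,
                             score: str = "sum") -> list[GreedyTrajectory]:
    """Sequential removal of the edge with the largest degree score.

    ``score='sum'`` removes the edge maximizing k_i + k_j, ``'product'``
    maximizes k_i * k_j.  All tie-resolution scenarios are enumerated as
    separate trajectories, capped at ``max_branches`` by seeded uniform
    subsampling.
    """
    if score not in ("sum", "product"):
        raise ValueError(f"unknown score {score!r}")
    rng = np.random.default_rng(seed)
    base = bc_star(net).bc_star

    def tie_set(current: WeightedNetwork) -> list[tuple[int, int]]:
        candidates, _ = _eligible_pairs(current, "removal")
        if not candidates:
            return []
        deg = current.degrees()
        if score == "sum":
            scores = [deg[i] + deg[j] for i, j in candidates]
        else:
            scores = [deg[i] * deg[j] for i, j in candidates]
        top = max(scores)
        return [e for e, sc in zip(candidates, scores) if sc == top]

    # breadth-first over removal scenarios, subsampling whenever the number
    # of open branches exceeds the cap
    partials = [(net, [], [], False)]  # (network, removed, bc_values, stopped)
    for _ in range(steps):
        nxt = []
        for current, removed, values, stopped in partials:
            if stopped:
                nxt.append((current, removed, values, True))
                continue
            ties = tie_set(current)
            if not ties:
                nxt.append((current, removed, values, True))
                continue
            for (i, j) in ties:
                reduced = _remove_edge(current, i, j)
                nxt.append((reduced, removed + [(i, j)],
                            values + [bc_star(reduced).bc_star], False))
        if len(nxt) > max_branches:
            keep = rng.choice(len(nxt), size=max_branches, replace=False)
            nxt = [nxt[k] for k in sorted(keep)]
        partials = nxt
    return [GreedyTrajectory(strategy=f"degree_{score}", removed=removed,
                             bc_values=values, base_bc=base,
                             stopped_early=stopped)
            for _, removed, values, stopped in partials]
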