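"""Weighted undirected networks: container, generators, and edge-list I/O.

All downstream computations consume :class:`WeightedNetwork`, a dense
symmetric nonnegative weight matrix with a connectivity guarantee.  The
random generators reproduce the synthetic network classes used throughout
the experiments: Erdős–Rényi with a fixed number of edges, Barabási–Albert
grown from a 4-node star, the planted ℓ-partition (random partition)
model, and the LFR benchmark.  Random models are rejection-sampled until
connected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "WeightedNetwork",
    "GeneratorConfig",
    "generate_er",
    "generate_ba",
    "generate_planted_partition",
    "generate_lfr",
    "fixture",
    "read_edgelist",
    "write_edgelist",
]


def _is_connected(weights: np.ndarray) -> bool:
    off = weights.copy()
    np.fill_diagonal(off, 0.0)
    n_comp, _ = connected_components(csr_matrix(off > 0), directed=False)
    return n_comp == 1


@dataclass(frozen=True)
class WeightedNetwork:
    """A connected undirected network with nonnegative edge weights.

    Parameters
    ----------
    weights
        N x N symmetric matrix of edge weights ``w[i, j] >= 0``.  A zero
        entry means no edge.  Self-loops (``w[i, i] > 0``) are
        representable but never produced by the generators here.
    node_labels
        Optional external labels, in internal index order 0..N-1.
    """

    weights: np.ndarray
    node_labels: tuple = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, rtol=0, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("edge weights must be nonnegative")
        if not _is_connected(w):
            raise ValueError("network must be connected")
        object.__setattr__(self, "weights", w)
        if not self.node_labels:
            object.__setattr__(self, "node_labels", tuple(range(w.shape[0])))
        elif len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must equal number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of distinct edges i < j with positive weight."""
        return len(self.edges())

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of (i, j) with i < j and w_ij > 0."""
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def nonedges(self) -> list[tuple[int, int]]:
        """Sorted list of distinct non-adjacent pairs (i, j), i < j."""
        upper = np.triu(np.ones_like(self.weights, dtype=bool), k=1)
        iu, ju = np.nonzero(upper & (self.weights == 0))
        return list(zip(iu.tolist(), ju.tolist()))

    def strengths(self) -> np.ndarray:
        """Weighted degrees s_i = sum_j w_ij."""
        return self.weights.sum(axis=1)

    def degrees(self) -> np.ndarray:
        """Unweighted degrees (number of incident edges, self-loops excluded)."""
        off = self.weights.copy()
        np.fill_diagonal(off, 0.0)
        return (off > 0).sum(axis=1)

    def mean_degree(self) -> float:
        return float(self.degrees().mean())

    def with_edge_weight(self, i: int, j: int, weight: float) -> "WeightedNetwork":
        """A copy with w_ij = w_ji set to ``weight`` (may disconnect -> error)."""
        w = self.weights.copy()
        w[i, j] = weight
        w[j, i] = weight
        return WeightedNetwork(w, self.node_labels)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j in self.edges():
            g.add_edge(i, j, weight=self.weights[i, j])
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedNetwork":
        nodes = sorted(g.nodes())
        index = {u: k for k, u in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w[index[u], index[v]] = w[index[v], index[u]] = data.get("weight", 1.0)
        return cls(w, tuple(nodes))


@dataclass
class GeneratorConfig:
    """Record of a generator invocation (model, parameters, seed, retries)."""

    model: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    retries: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"model": self.model, "parameters": self.parameters,
             "seed": self.seed, "retries": self.retries},
            sort_keys=True,
        )


_MAX_RETRIES = 10_000


def generate_er(n: int, m_edges: int, seed: int,
                return_config: bool = False):
    """Erdős–Rényi G(n, M): exactly ``m_edges`` unit-weight edges.

    Edges are drawn uniformly without replacement from the n(n-1)/2 node
    pairs; whole graphs are resampled (advancing the RNG) until the result
    is connected.
    """
    max_edges = n * (n - 1) // 2
    if m_edges > max_edges:
        raise ValueError(f"m_edges={m_edges} exceeds n(n-1)/2={max_edges}")
    if m_edges < n - 1:
        raise ValueError(f"m_edges={m_edges} < n-1={n - 1}: connectivity unreachable")
    rng = np.random.default_rng(seed)
    pairs = np.transpose(np.triu_indices(n, k=1))
    for retry in range(_MAX_RETRIES):
        chosen = rng.choice(max_edges, size=m_edges, replace=False)
        w = np.zeros((n, n))
        ii, jj = pairs[chosen, 0], pairs[chosen, 1]
        w[ii, jj] = 1.0
        w[jj, ii] = 1.0
        if _is_connected(w):
            net = WeightedNetwork(w)
            if return_config:
                cfg = GeneratorConfig("er", {"n": n, "m_edges": m_edges}, seed, retry)
                return net, cfg
            return net
    raise RuntimeError(f"no connected ER graph found in {_MAX_RETRIES} draws")


def generate_ba(n: int, m: int = 3, seed: int = 0,
                return_config: bool = False):
    """Barabási–Albert growth from an (m+1)-node star.

    Each new node attaches to ``m`` distinct existing nodes, drawn
    sequentially without replacement with probability proportional to the
    current degree (degree weights renormalized after each draw).  With
    m = 3 the result has exactly 3 + 3(n - 4) edges.
    """
    seed_size = m + 1
    if n < seed_size:
        raise ValueError(f"n={n} below seed-graph size {seed_size}")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    # star seed: node 0 is the hub
    for leaf in range(1, seed_size):
        w[0, leaf] = w[leaf, 0] = 1.0
    degree = w.sum(axis=1)
    for new in range(seed_size, n):
        probs = degree[:new] / degree[:new].sum()
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for t in targets:
            w[new, t] = w[t, new] = 1.0
            degree[t] += 1.0
        degree[new] = m
    net = WeightedNetwork(w)
    if return_config:
        return net, GeneratorConfig("ba", {"n": n, "m": m}, seed, 0)
    return net


def generate_planted_partition(n: int, l: int, p_in: float, p_out: float,
                               seed: int, return_config: bool = False):
    """Planted ℓ-partition (random partition) graph.

    Nodes are split into ``l`` equal groups of n/l; within-group pairs are
    adjacent with probability ``p_in``, between-group pairs with ``p_out``.
    Resampled until connected.
    """
    if n % l != 0:
        raise ValueError(f"l={l} does not divide n={n}")
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("require 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    group = np.repeat(np.arange(l), n // l)
    same = group[:, None] == group[None, :]
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    p_mat = np.where(same, p_in, p_out)
    for retry in range(_MAX_RETRIES):
        draw = rng.random((n, n)) < p_mat
        adj = np.where(upper, draw, False)
        w = (adj | adj.T).astype(float)
        if _is_connected(w):
            net = WeightedNetwork(w)
            if return_config:
                cfg = GeneratorConfig(
                    "planted_partition",
                    {"n": n, "l": l, "p_in": p_in, "p_out": p_out}, seed, retry)
                return net, cfg
            return net
    raise RuntimeError(f"no connected planted-partition graph in {_MAX_RETRIES} draws")


def _powerlaw_bins(exponent: float, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Integers k and probabilities P(round(x) = k) for x ~ x^-exponent on [lo, hi]."""
    ks = np.arange(int(np.floor(lo)), int(np.ceil(hi)) + 1)

    def cdf_mass(a, b):  # integral of x^-exponent
        a, b = np.clip(a, lo, hi), np.clip(b, lo, hi)
        if exponent == 1.0:
            return np.log(b) - np.log(a)
        e = 1.0 - exponent
        return (b ** e - a ** e) / e

    mass = np.array([cdf_mass(k - 0.5, k + 0.5) for k in ks])
    keep = mass > 0
    ks, mass = ks[keep], mass[keep]
    return ks, mass / mass.sum()


def _lfr_degree_sequence(n: int, gamma: float, mean_degree: float,
                         k_max: int, rng: np.random.Generator) -> np.ndarray:
    """Power-law degrees with the lower cutoff calibrated to the target mean."""
    lo_a, lo_b = 1.5, float(k_max) / 2

    def mean_for(lo):
        ks, p = _powerlaw_bins(gamma, lo, k_max)
        return float(ks @ p)

    for _ in range(60):  # bisection on the continuous lower cutoff
        mid = 0.5 * (lo_a + lo_b)
        if mean_for(mid) < mean_degree:
            lo_a = mid
        else:
            lo_b = mid
    ks, p = _powerlaw_bins(gamma, 0.5 * (lo_a + lo_b), k_max)
    degrees = rng.choice(ks, size=n, p=p)
    if degrees.sum() % 2:  # need an even stub count
        degrees[int(rng.integers(n))] += 1
    return degrees


def _match_stubs(stubs: np.ndarray, forbidden_groups: np.ndarray | None,
                 rng: np.random.Generator, passes: int = 40) -> set[tuple[int, int]]:
    """Random stub matching into simple edges; leftovers are re-shuffled.

    ``forbidden_groups`` bans within-group matches (used for inter-community
    edges).  Unmatchable leftover stubs are dropped.
    """
    edges: set[tuple[int, int]] = set()
    pool = list(stubs)
    for _ in range(passes):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        leftover = []
        for a, b in zip(pool[::2], pool[1::2]):
            if a == b:
                leftover.extend((a, b))
                continue
            if forbidden_groups is not None and \
                    forbidden_groups[a] == forbidden_groups[b]:
                leftover.extend((a, b))
                continue
            e = (min(a, b), max(a, b))
            if e in edges:
                leftover.extend((a, b))
                continue
            edges.add(e)
        if len(pool) % 2:
            leftover.append(pool[-1])
        if len(leftover) == len(pool):
            break
        pool = leftover
    return edges


def generate_lfr(n: int = 100, gamma: float = 3.0, kappa: float = 2.0,
                 mean_degree: float = 6.0, k_max: int = 100, mu: float = 0.1,
                 seed: int = 0, max_retries: int = 200,
                 return_config: bool = False):
    """LFR-style benchmark graph with community structure.

    Degrees follow a truncated power law with exponent ``gamma`` (lower
    cutoff calibrated so the expected mean degree matches ``mean_degree``),
    community sizes a power law with exponent ``kappa``, and each node
    places a fraction ``mu`` of its edges outside its community.  Edges are
    wired by configuration-model stub matching (simple graph, unmatchable
    stubs dropped), and whole realizations are resampled until connected.

    networkx's LFR implementation does not converge for community-size
    exponents near 2 at these sizes, so the construction is done here.
    """
    if not (0 < mu < 1):
        raise ValueError("mixing parameter mu must be in (0, 1)")
    for retry in range(max_retries):
        rng = np.random.default_rng([seed, retry])
        degrees = _lfr_degree_sequence(n, gamma, mean_degree, k_max, rng)
        d_int = np.rint((1.0 - mu) * degrees).astype(int)
        # community sizes: power law on [s_min, n], summed to exactly n
        s_min = min(max(10, int(d_int.max()) + 1), n)
        sizes_k, sizes_p = _powerlaw_bins(kappa, s_min, n)
        sizes: list[int] = []
        while sum(sizes) < n:
            sizes.append(int(rng.choice(sizes_k, p=sizes_p)))
        excess = sum(sizes) - n
        if excess:
            if sizes[-1] - excess >= s_min:
                sizes[-1] -= excess
            elif len(sizes) > 1:
                sizes.pop()
                sizes[-1] += n - sum(sizes)
            else:
                sizes = [n]
        membership = np.repeat(np.arange(len(sizes)), sizes)
        rng.shuffle(membership)
        # internal degree cannot reach the community size
        cap = np.array(sizes)[membership] - 1
        d_int = np.minimum(d_int, cap)
        d_ext = degrees - d_int
        if len(sizes) == 1:
            # a single community cannot realize the mixing parameter
            continue
        edges: set[tuple[int, int]] = set()
        for c in range(len(sizes)):
            members = np.nonzero(membership == c)[0]
            stubs = np.repeat(members, d_int[members])
            edges |= _match_stubs(stubs, None, rng)
        ext_stubs = np.repeat(np.arange(n), d_ext)
        edges |= _match_stubs(ext_stubs, membership, rng)
        w = np.zeros((n, n))
        for u, v in edges:
            w[u, v] = w[v, u] = 1.0
        if _is_connected(w) and abs(2 * len(edges) / n - mean_degree) <= 1.0:
            net = WeightedNetwork(w)
            if return_config:
                cfg = GeneratorConfig(
                    "lfr",
                    {"n": n, "gamma": gamma, "kappa": kappa,
                     "mean_degree": mean_degree, "k_max": k_max, "mu": mu,
                     "community_sizes": [int(s) for s in sizes],
                     "membership": [int(c) for c in membership]},
                    seed, retry)
                return net, cfg
            return net
    raise RuntimeError(
        f"LFR generator failed to produce a connected realization with mean "
        f"degree within 1 of {mean_degree} in {max_retries} attempts")


def fixture(kind: str, n: int) -> WeightedNetwork:
    """Canonical unit-weight graphs: cycle, complete, star, path.

    The star's hub is node 0; cycles and paths are labeled in walk order.
    """
    if kind == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        g = nx.cycle_graph(n)
    elif kind == "complete":
        if n < 2:
            raise ValueError("complete graph needs n >= 2")
        g = nx.complete_graph(n)
    elif kind == "star":
        if n < 2:
            raise ValueError("star needs n >= 2")
        g = nx.star_graph(n - 1)
    elif kind == "path":
        if n < 2:
            raise ValueError("path needs n >= 2")
        g = nx.path_graph(n)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    w = np.zeros((n, n))
    for u, v in g.edges():
        w[u, v] = w[v, u] = 1.0
    return WeightedNetwork(w)


def circulant(n: int, offsets: Sequence[int]) -> WeightedNetwork:
    """Circulant graph: node i adjacent to i +- d (mod n) for d in offsets."""
    w = np.zeros((n, n))
    for i in range(n):
        for d in offsets:
            j = (i + d) % n
            if i != j:
                w[i, j] = w[j, i] = 1.0
    return WeightedNetwork(w)


def _parse_lines(lines: Iterator[str]) -> WeightedNetwork:
    edges: dict[tuple, float] = {}
    labels: set = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"line {lineno}: expected 'u v [weight]', got {raw!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
            weight = float(parts[2]) if len(parts) == 3 else 1.0
        except ValueError as err:
            raise ValueError(f"line {lineno}: malformed entry: {raw!r}") from err
        if weight < 0:
            raise ValueError(f"line {lineno}: negative weight {weight}")
        key = (min(u, v), max(u, v))
        if key in edges and edges[key] != weight:
            raise ValueError(
                f"line {lineno}: conflicting duplicate weight for edge {key}")
        edges[key] = weight
        labels.update((u, v))
    if not edges:
        raise ValueError("empty edge list")
    ordered = sorted(labels)
    index = {u: k for k, u in enumerate(ordered)}
    w = np.zeros((len(ordered), len(ordered)))
    for (u, v), weight in edges.items():
        w[index[u], index[v]] = weight
        w[index[v], index[u]] = weight
    return WeightedNetwork(w, tuple(ordered))


def read_edgelist(path) -> WeightedNetwork:
    """Read a whitespace-separated "u v weight" edge list ('#' comments).

    Weight defaults to 1.  Node labels are arbitrary integers, mapped to
    internal indices in sorted order.  Disconnected input, negative
    weights, and conflicting duplicate edges are rejected.
    """
    with open(path) as fh:
        return _parse_lines(iter(fh))


def write_edgelist(net: WeightedNetwork, path) -> Path:
    """Write the network in the "u v weight" format read by read_edgelist."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, j in net.edges():
            u, v = net.node_labels[i], net.node_labels[j]
            fh.write(f"{u} {v} {net.weights[i, j]:.12g}\n")
        if np.any(np.diag(net.weights) > 0):
            for i in range(net.n_nodes):
                if net.weights[i, i] > 0:
                    u = net.node_labels[i]
                    fh.write(f"{u} {u} {net.weights[i, i]:.12g}\n")
    return path
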