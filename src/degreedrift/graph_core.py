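"""Graph representation, edge-list I/O, network generators, and degree statistics.

A population of reproducing individuals is modelled as the node set of an
undirected simple graph; edges mark which individuals compete with one
another.  The dynamics modules only ever need three structural quantities:
the neighbor lists, each node's degree ``k_i``, and the average degree
``<k> = 2|E|/N``.  Degree *heterogeneity* is summarised by the fluctuation

    Delta = <k^2> / <k>^2 - 1,

the normalised variance of the degree distribution ``p(k) = N_k / N``.
Delta is exactly zero for regular graphs and grows with the tail weight of
``p(k)``; it is the structural quantity the fixation probability responds to.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "DegreeStats",
    "read_edge_list",
    "write_edge_list",
    "make_star",
    "make_complete",
    "make_ring_lattice",
    "make_small_world",
    "make_scale_free",
    "degree_stats",
    "theoretical_fluctuation",
    "make_twelve_node_example",
    "TwelveNodeExample",
]


class GraphError(ValueError):
    """Invalid graph structure or generator parameters."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with cached adjacency in CSR form.

    Nodes are the integers ``0 .. n_nodes-1``.  Edges are stored canonically
    as sorted ``(i, j)`` pairs with ``i < j``.  Construction validates
    simplicity (no self-loops, no duplicate edges); connectivity is exposed
    as a property and enforced by the dynamics layer, where fixation is
    otherwise ill-defined.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    _indptr: np.ndarray = field(repr=False, compare=False)
    _indices: np.ndarray = field(repr=False, compare=False)
    _degrees: np.ndarray = field(repr=False, compare=False)

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        if n_nodes < 1:
            raise GraphError("graph needs at least one node")
        canon = []
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise GraphError(f"self-loop at node {i}")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise GraphError(f"edge ({i}, {j}) outside node range 0..{n_nodes - 1}")
            canon.append((min(i, j), max(i, j)))
        uniq = sorted(set(canon))
        if len(uniq) != len(canon):
            raise GraphError("duplicate edges")
        deg = np.zeros(n_nodes, dtype=np.int64)
        for i, j in uniq:
            deg[i] += 1
            deg[j] += 1
        indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        indices = np.empty(2 * len(uniq), dtype=np.int64)
        cursor = indptr[:-1].copy()
        for i, j in uniq:
            indices[cursor[i]] = j
            cursor[i] += 1
            indices[cursor[j]] = i
            cursor[j] += 1
        return cls(n_nodes, tuple(uniq), indptr, indices, deg)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = list(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        return cls.from_edges(len(nodes), ((index[u], index[v]) for u, v in g.edges()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    # -- structural queries -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: int) -> int:
        self._check_node(node)
        return int(self._degrees[node])

    @property
    def degrees(self) -> np.ndarray:
        """Degree of every node (read-only view)."""
        v = self._degrees.view()
        v.flags.writeable = False
        return v

    @property
    def avg_degree(self) -> Fraction:
        """<k> = 2|E|/N as an exact rational."""
        return Fraction(2 * self.n_edges, self.n_nodes)

    def neighbors(self, node: int) -> np.ndarray:
        self._check_node(node)
        return self._indices[self._indptr[node]:self._indptr[node + 1]]

    @property
    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) arrays for the flat neighbor lists."""
        return self._indptr, self._indices

    @property
    def connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        if self.n_edges == 0:
            return False
        return nx.is_connected(self.to_networkx())

    def _check_node(self, node: int) -> None:
        if not (0 <= node < self.n_nodes):
            raise GraphError(f"node {node} not in graph of size {self.n_nodes}")


@dataclass(frozen=True)
class DegreeStats:
    """Exact degree-distribution summary.

    All moments are rationals built from integer counts, so regularity
    (``fluctuation == 0``) is detected exactly rather than to round-off.
    """

    distribution: Mapping[int, Fraction]
    mean: Fraction
    second_moment: Fraction
    fluctuation: Fraction


def degree_stats(graph: Graph) -> DegreeStats:
    """Compute p(k) = N_k/N and the fluctuation Delta = <k^2>/<k>^2 - 1."""
    n = graph.n_nodes
    counts: dict[int, int] = {}
    for k in graph.degrees:
        counts[int(k)] = counts.get(int(k), 0) + 1
    dist = {k: Fraction(c, n) for k, c in sorted(counts.items())}
    mean = Fraction(int(graph.degrees.sum()), n)
    second = Fraction(int((graph.degrees.astype(object) ** 2).sum()), n)
    fluct = second / mean**2 - 1
    return DegreeStats(dist, mean, second, fluct)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(source: IO[str] | str) -> Graph:
    """Read a whitespace/CSV edge list.

    Lines starting with ``#`` are comments.  Node tokens may be arbitrary
    integers or strings; they are renumbered ``0..N-1`` in order of first
    appearance.  Duplicate edges are collapsed with a warning; self-loops are
    an error (with the offending line number).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) != 2:
            raise GraphError(f"line {lineno}: expected two node tokens, got {tokens!r}")
        a, b = tokens
        if a == b:
            raise GraphError(f"line {lineno}: self-loop on node {a!r}")
        pairs.append((a, b))
    if not pairs:
        raise GraphError("empty edge list")
    tokens_seen = {t for p in pairs for t in p}
    if all(t.isdigit() for t in tokens_seen) and {int(t) for t in tokens_seen} == set(
        range(len(tokens_seen))
    ):
        # labels already form 0..N-1: keep them, so write->read is the identity
        index = {t: int(t) for t in tokens_seen}
    else:
        index = {}
        for a, b in pairs:
            for t in (a, b):
                if t not in index:
                    index[t] = len(index)
    edges = []
    seen: set[tuple[int, int]] = set()
    dupes = 0
    for a, b in pairs:
        e = (min(index[a], index[b]), max(index[a], index[b]))
        if e in seen:
            dupes += 1
            continue
        seen.add(e)
        edges.append(e)
    if dupes:
        warnings.warn(f"collapsed {dupes} duplicate edge(s)", stacklevel=2)
    graph = Graph.from_edges(len(index), edges)
    if not graph.connected:
        warnings.warn("edge list describes a disconnected graph", stacklevel=2)
    return graph


def write_edge_list(graph: Graph, sink: IO[str]) -> None:
    """Write one edge per line, smaller id first, sorted, with a header comment."""
    sink.write(f"# nodes: {graph.n_nodes}  edges: {graph.n_edges}\n")
    for i, j in graph.edges:
        sink.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_star(n_leaves: int) -> Graph:
    """Star graph: one core (node 0, degree n) and n degree-1 leaves.

    N = n+1 and <k> = 2n/(n+1); the most extreme degree-heterogeneous
    connected graph, and the one case solved in closed form (see
    :mod:`degreedrift.star_exact`).
    """
    if n_leaves < 1:
        raise GraphError("a star needs at least one leaf")
    return Graph.from_networkx(nx.star_graph(n_leaves))


def make_complete(n_nodes: int) -> Graph:
    if n_nodes < 2:
        raise GraphError("a complete graph needs at least two nodes")
    return Graph.from_networkx(nx.complete_graph(n_nodes))


def make_ring_lattice(n_nodes: int, even_degree: int) -> Graph:
    """Circular lattice: node i joined to the even_degree/2 nearest on each side."""
    if even_degree % 2 != 0 or even_degree < 2:
        raise GraphError("lattice degree must be even and >= 2")
    if even_degree >= n_nodes:
        raise GraphError("lattice degree must be < number of nodes")
    return Graph.from_networkx(nx.circulant_graph(n_nodes, range(1, even_degree // 2 + 1)))


def make_small_world(
    n_nodes: int,
    avg_degree: int,
    rewiring_prob: float,
    seed: int,
    max_retries: int = 100,
) -> Graph:
    """Watts–Strogatz small-world graph.

    Starts from :func:`make_ring_lattice`; each lattice edge has its far
    endpoint reattached to a uniformly random node with probability
    ``rewiring_prob`` (self-loops and duplicates rejected), so the edge count
    N*k/2 is conserved for every q.  q=0 returns the lattice unchanged; q=1
    is a fully randomized graph.  Regenerates from fresh seed-derived streams
    until connected, up to ``max_retries``.
    """
    if not 0.0 <= rewiring_prob <= 1.0:
        raise GraphError("rewiring probability must lie in [0, 1]")
    if avg_degree % 2 != 0 or not 2 <= avg_degree < n_nodes:
        raise GraphError("average degree must be even with 2 <= k < N")
    ss = np.random.SeedSequence([int(seed), 0x5357])
    for child in ss.spawn(max_retries):
        rng = np.random.RandomState(int(child.generate_state(1)[0]))
        g = nx.watts_strogatz_graph(n_nodes, avg_degree, rewiring_prob, seed=rng)
        if nx.is_connected(g):
            return Graph.from_networkx(g)
    raise GraphError(
        f"could not generate a connected small-world graph in {max_retries} tries"
    )


def _power_law_degrees(
    n_nodes: int, gamma: float, k_min: int, rng: np.random.Generator
) -> np.ndarray:
    ks = np.arange(k_min, n_nodes, dtype=np.int64)  # cutoff k <= N-1
    weights = ks.astype(np.float64) ** (-gamma)
    weights /= weights.sum()
    deg = rng.choice(ks, size=n_nodes, p=weights)
    # force an even stub total by resampling a single node
    for _ in range(1000):
        if deg.sum() % 2 == 0:
            return deg
        deg[rng.integers(n_nodes)] = rng.choice(ks, p=weights)
    raise GraphError("could not balance the degree-sequence parity")


def _pair_and_repair(
    degrees: np.ndarray, rng: np.random.Generator, max_swaps: int | None = None
) -> list[tuple[int, int]] | None:
    """Configuration model: pair stubs uniformly, then repair self-loops and
    multi-edges with degree-preserving double-edge swaps.  Returns None if
    the repair budget is exhausted (caller retries with a fresh pairing)."""
    stubs = np.repeat(np.arange(degrees.size), degrees)
    rng.shuffle(stubs)
    edges = [tuple(e) for e in stubs.reshape(-1, 2)]
    m = len(edges)
    count: dict[tuple[int, int], int] = {}
    for u, v in edges:
        key = (min(u, v), max(u, v))
        count[key] = count.get(key, 0) + 1
    def is_bad(u: int, v: int) -> bool:
        return u == v or count[(min(u, v), max(u, v))] > 1
    bad = {idx for idx, (u, v) in enumerate(edges) if is_bad(u, v)}
    budget = max_swaps if max_swaps is not None else 200 * m
    while bad and budget > 0:
        budget -= 1
        a = next(iter(bad)) if len(bad) == 1 else list(bad)[rng.integers(len(bad))]
        u, v = edges[a]
        if not is_bad(u, v):  # a former duplicate partner that became valid
            bad.discard(a)
            continue
        b = int(rng.integers(m))
        if a == b:
            continue
        x, y = edges[b]
        if rng.integers(2):
            x, y = y, x
        # propose (u,x) and (v,y)
        if u == x or v == y:
            continue
        e1 = (min(u, x), max(u, x))
        e2 = (min(v, y), max(v, y))
        if count.get(e1, 0) > 0 or count.get(e2, 0) > 0 or e1 == e2:
            continue
        for old in ((u, v), (x, y)):
            count[(min(old), max(old))] -= 1
        count[e1] = count.get(e1, 0) + 1
        count[e2] = count.get(e2, 0) + 1
        edges[a] = e1
        edges[b] = e2
        bad.discard(a)
        bad.discard(b)
        # the swap can leave former duplicates of the removed edges intact
        for idx in (a, b):
            if is_bad(*edges[idx]):
                bad.add(idx)
    if bad:
        return None
    return edges


def make_scale_free(
    n_nodes: int,
    gamma: float,
    k_min: int = 3,
    seed: int = 0,
    max_retries: int = 100,
) -> Graph:
    """Power-law configuration-model graph with a tunable exponent.

    Degrees are drawn i.i.d. from the discrete distribution
    ``p(k) ∝ k^{-gamma}`` on ``k_min <= k <= N-1`` (parity fixed by
    resampling one node), stubs are paired uniformly, and self-loops /
    multi-edges are erased by degree-preserving double-edge swaps; the whole
    draw is retried until the result is simple and connected.  Unlike
    preferential attachment — whose exponent is pinned near 3 — this gives an
    exponent that can be swept freely over gamma > 2 at fixed N.
    """
    if gamma <= 2:
        raise GraphError("gamma must exceed 2 (mean degree diverges otherwise)")
    if k_min < 1:
        raise GraphError("k_min must be >= 1")
    if n_nodes <= k_min + 1:
        raise GraphError("graph too small for the requested minimum degree")
    ss = np.random.SeedSequence([int(seed), 0x5346])
    for child in ss.spawn(max_retries):
        rng = np.random.default_rng(child)
        degrees = _power_law_degrees(n_nodes, gamma, k_min, rng)
        edges = _pair_and_repair(degrees, rng)
        if edges is None:
            continue
        graph = Graph.from_edges(n_nodes, edges)
        if graph.connected:
            return graph
    raise GraphError(
        f"no simple connected realization of p(k) ~ k^-{gamma} with k_min={k_min} "
        f"after {max_retries} attempts; try a larger n_nodes or k_min"
    )


def theoretical_fluctuation(gamma: float, kmax_over_kmean: float | None = None) -> float:
    """Closed-form degree fluctuation of an ideal power-law network.

    For gamma > 3 both moments converge and

        Delta = (gamma-2)^2 / ((gamma-1)(gamma-3)) - 1,

    a function of the exponent alone.  For 2 < gamma < 3 the second moment
    is cut off by the largest degree, which scales with network size, and

        Delta = (gamma-2)^2/((gamma-1)(gamma-3))
                * (1 - ((gamma-1)/(gamma-2) * k_max/<k>)^{3-gamma}) - 1

    requires the ratio ``k_max/<k>``.  gamma = 3 is singular (logarithmic
    divergence) and gamma <= 2 has no finite mean.
    """
    if gamma <= 2:
        raise GraphError("gamma must exceed 2")
    if gamma == 3:
        raise GraphError("gamma = 3 is singular (logarithmically divergent moments)")
    lead = (gamma - 2) ** 2 / ((gamma - 1) * (gamma - 3))
    if gamma > 3:
        return lead - 1.0
    if kmax_over_kmean is None or kmax_over_kmean <= 0:
        raise GraphError("for 2 < gamma < 3 a positive k_max/<k> ratio is required")
    ratio = (gamma - 1) / (gamma - 2) * kmax_over_kmean
    return lead * (1.0 - ratio ** (3.0 - gamma)) - 1.0


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwelveNodeExample:
    """The 12-node worked-example population used across docs and tests.

    ``graph`` uses internal 0-based ids; ``label(i) = i + 1`` recovers the
    1-based labels used in prose.  ``mutants`` is the internal id set of the
    three mutant-occupied nodes.
    """

    graph: Graph
    mutants: frozenset[int]

    @staticmethod
    def label(node: int) -> int:
        return node + 1

    @staticmethod
    def node(label: int) -> int:
        return label - 1


#: 18 edges on 1-based labels; <k> = 3.  Node 11 has neighbors {1,2,4,6,7,10};
#: k_2 = k_6 = 2 and k_10 = 5.  The remaining edges are one explicit completion
#: consistent with those constraints (the example pins only this much).
_TWELVE_NODE_EDGES_1BASED = (
    (11, 1), (11, 2), (11, 4), (11, 6), (11, 7), (11, 10),
    (2, 3), (6, 5),
    (10, 3), (10, 8), (10, 9), (10, 12),
    (1, 3), (1, 5), (4, 5), (7, 8), (9, 12), (3, 7),
)


def make_twelve_node_example() -> TwelveNodeExample:
    """Build the 12-node heterogeneous example with mutants on nodes {2, 6, 10}."""
    edges = [(a - 1, b - 1) for a, b in _TWELVE_NODE_EDGES_1BASED]
    graph = Graph.from_edges(12, edges)
    mutants = frozenset(TwelveNodeExample.node(l) for l in (2, 6, 10))
    return TwelveNodeExample(graph, mutants)
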