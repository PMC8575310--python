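"""Degree-coupled birth-death (BD) Moran dynamics on graphs.

The population lives on a connected simple graph; each node carries either a
wild-type (A) or mutant (B) occupant.  One update is a BD event: a reproducer
is chosen uniformly among all N nodes (every birth rate is 1), then one of
its neighbors dies — chosen proportionally to its death rate — and is
replaced by the reproducer's offspring.

Death rates couple the dynamics to the structure: a wild type dies at rate 1
everywhere, a mutant at node i dies at rate k_i / <k>.  Averaged over the
graph the mutant death rate is exactly 1 (sum k_i = N <k>), so the mutant is
neutral *on average* only; locally it is favored on low-degree nodes and
disfavored on hubs.  This "average neutral drift" breaks the isothermal
theorem on any non-regular graph: the fixation probability of a single
mutant deviates from 1/N and responds to the degree fluctuation.

Two routes to the fixation probability are provided: a Monte-Carlo estimator
(JIT-compiled) for arbitrary graphs, and an exact absorbing-Markov-chain
solve over all 2^N occupation states for small graphs, which serves as the
oracle the simulator is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _sim
from .graph_core import Graph, GraphError

__all__ = [
    "WILD",
    "MUTANT",
    "DegreeCoupledRates",
    "PopulationState",
    "FixationEstimate",
    "RunResult",
    "mutant_death_rate",
    "reproducer_probability",
    "death_selection_probs",
    "bd_step",
    "run_to_fixation",
    "estimate_fixation_probability",
    "exact_fixation_markov",
]

WILD: int = 0
MUTANT: int = 1

_DEFAULT_MAX_STEPS = 10**9


class DegreeCoupledRates:
    """Rates of the degree-coupled model: r_A = r_B = 1, d_A = 1, d_B(i) = k_i/<k>."""

    def __init__(self, graph: Graph):
        self.graph = graph
        self._avg = graph.avg_degree

    def birth_rate(self, node: int, occupant: int) -> Fraction:
        self.graph._check_node(node)
        return Fraction(1)

    def death_rate(self, node: int, occupant: int) -> Fraction:
        self.graph._check_node(node)
        if occupant == WILD:
            return Fraction(1)
        return Fraction(self.graph.degree(node)) / self._avg

    def death_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(wild, mutant) per-node death-rate arrays as float64."""
        wild = np.ones(self.graph.n_nodes)
        mut = self.graph.degrees / float(self._avg)
        return wild, mut

    def mean_mutant_death_rate(self) -> Fraction:
        """Population average of d_B; identically 1 for this model."""
        total = sum(
            (self.death_rate(i, MUTANT) for i in range(self.graph.n_nodes)),
            Fraction(0),
        )
        return total / self.graph.n_nodes


@dataclass
class PopulationState:
    """Occupant label per node plus the running mutant count."""

    labels: np.ndarray  # uint8, WILD/MUTANT per node
    mutant_count: int

    @classmethod
    def from_mutants(cls, graph: Graph, mutants) -> "PopulationState":
        labels = np.zeros(graph.n_nodes, dtype=np.uint8)
        for m in mutants:
            graph._check_node(m)
            labels[m] = MUTANT
        return cls(labels, int(labels.sum()))

    @classmethod
    def single_mutant(cls, graph: Graph, node: int) -> "PopulationState":
        return cls.from_mutants(graph, [node])

    @property
    def absorbing(self) -> bool:
        return self.mutant_count in (0, self.labels.size)

    def copy(self) -> "PopulationState":
        return PopulationState(self.labels.copy(), self.mutant_count)


@dataclass(frozen=True)
class RunResult:
    fixed: bool
    steps: int


@dataclass(frozen=True)
class FixationEstimate:
    """Pooled Monte-Carlo fixation estimate with binomial standard error."""

    successes: int
    runs: int
    seed: int
    total_steps: int
    per_graph: tuple[tuple[int, int], ...] = ()

    @property
    def probability(self) -> float:
        return self.successes / self.runs

    @property
    def std_error(self) -> float:
        p = self.probability
        return math.sqrt(p * (1.0 - p) / self.runs)

    @property
    def across_graph_sd(self) -> float:
        """Standard deviation of the per-graph estimates (0 for a single graph)."""
        if len(self.per_graph) < 2:
            return 0.0
        vals = [s / r for s, r in self.per_graph]
        return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Elementary quantities (exact rationals, used by the worked examples/tests)
# ---------------------------------------------------------------------------

def mutant_death_rate(graph: Graph, node: int) -> Fraction:
    """d_B(node) = degree(node) / <k>, exact."""
    return DegreeCoupledRates(graph).death_rate(node, MUTANT)


def reproducer_probability(graph: Graph) -> Fraction:
    """Every node reproduces with the same probability 1/N (unit birth rates)."""
    return Fraction(1, graph.n_nodes)


def death_selection_probs(
    graph: Graph,
    state: PopulationState,
    rates: DegreeCoupledRates,
    reproducer: int,
) -> dict[int, Fraction]:
    """Probability that each neighbor of the reproducer is the one to die.

    The neighborhood's death rates are renormalized: neighbor j dies with
    probability d(j) / sum_{l in neighbors} d(l).  A leaf therefore kills its
    only neighbor with probability 1 regardless of that neighbor's rate.
    """
    nbrs = graph.neighbors(reproducer)
    if nbrs.size == 0:
        raise GraphError(f"node {reproducer} has no neighbors")
    weights = {
        int(j): rates.death_rate(int(j), int(state.labels[j])) for j in nbrs
    }
    total = sum(weights.values(), Fraction(0))
    return {j: w / total for j, w in weights.items()}


def _select_victim(
    graph: Graph,
    state: PopulationState,
    rates: DegreeCoupledRates,
    reproducer: int,
    rng: np.random.Generator,
) -> int:
    probs = death_selection_probs(graph, state, rates, reproducer)
    nodes = list(probs)
    p = np.array([float(probs[j]) for j in nodes])
    return int(rng.choice(nodes, p=p / p.sum()))


def bd_step(
    graph: Graph,
    state: PopulationState,
    rates: DegreeCoupledRates,
    rng: np.random.Generator,
) -> PopulationState:
    """One birth-death event, in place; returns the updated state."""
    if state.absorbing:
        raise ValueError("cannot step an absorbing state")
    reproducer = int(rng.integers(graph.n_nodes))
    victim = _select_victim(graph, state, rates, reproducer, rng)
    if state.labels[victim] != state.labels[reproducer]:
        state.mutant_count += 1 if state.labels[reproducer] == MUTANT else -1
        state.labels[victim] = state.labels[reproducer]
    return state


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def _require_connected(graph: Graph) -> None:
    if not graph.connected:
        raise GraphError("fixation dynamics requires a connected graph")


def run_to_fixation(
    graph: Graph,
    rates: DegreeCoupledRates | None = None,
    initial_mutant: int | str = "uniform",
    seed: int = 0,
    max_steps: int = _DEFAULT_MAX_STEPS,
) -> RunResult:
    """Simulate one trajectory from a single initial mutant to absorption."""
    if graph.n_nodes < 2:
        raise GraphError("need at least two nodes")
    _require_connected(graph)
    rates = rates or DegreeCoupledRates(graph)
    rng = np.random.default_rng(seed)
    if initial_mutant == "uniform":
        start = int(rng.integers(graph.n_nodes))
    else:
        start = int(initial_mutant)
        graph._check_node(start)
    wild, mut = rates.death_vectors()
    indptr, indices = graph.adjacency_csr
    run_seed = int(rng.integers(2**31))
    outcome, steps = _sim.simulate_run(
        indptr, indices, wild, mut, start, run_seed, max_steps
    )
    if outcome < 0:
        raise RuntimeError(f"no absorption within {max_steps} steps")
    return RunResult(bool(outcome), int(steps))


def _batch_on_graph(
    graph: Graph,
    rates: DegreeCoupledRates,
    n_runs: int,
    seed_sequence: np.random.SeedSequence,
    max_steps: int,
    initial_mutant: int | str,
) -> tuple[int, int]:
    rng = np.random.default_rng(seed_sequence)
    if initial_mutant == "uniform":
        starts = rng.integers(0, graph.n_nodes, size=n_runs)
    else:
        starts = np.full(n_runs, int(initial_mutant), dtype=np.int64)
    seeds = rng.integers(0, 2**31, size=n_runs)
    wild, mut = rates.death_vectors()
    indptr, indices = graph.adjacency_csr
    outcomes, steps = _sim.simulate_batch(
        indptr, indices, wild, mut, starts, seeds, max_steps
    )
    if (outcomes < 0).any():
        raise RuntimeError(f"a run failed to absorb within {max_steps} steps")
    return int(outcomes.sum()), int(steps.sum())


def estimate_fixation_probability(
    graph: Graph | Callable[[int], Graph],
    ensemble_size: int,
    n_graphs: int = 1,
    seed: int = 0,
    initial_mutant: int | str = "uniform",
    max_steps: int = _DEFAULT_MAX_STEPS,
) -> FixationEstimate:
    """Monte-Carlo fixation probability of a single mutant.

    ``graph`` is either a fixed :class:`Graph` or a callable ``seed -> Graph``
    from which ``n_graphs`` fresh networks are drawn, the ensemble split
    evenly among them and the successes pooled.  Each run starts from one
    mutant placed uniformly at random (or at ``initial_mutant``); every
    source of randomness derives from ``seed`` via independent substreams of
    ``(seed, graph index)``, so results are reproducible and independent of
    batching.
    """
    if ensemble_size < 1 or n_graphs < 1:
        raise ValueError("ensemble_size and n_graphs must be >= 1")
    runs_per_graph = ensemble_size // n_graphs
    remainder = ensemble_size % n_graphs
    successes = 0
    total_steps = 0
    per_graph: list[tuple[int, int]] = []
    for g_idx in range(n_graphs):
        n_runs = runs_per_graph + (1 if g_idx < remainder else 0)
        if n_runs == 0:
            continue
        if callable(graph):
            g = graph(int(np.random.SeedSequence([seed, g_idx, 0xA]).generate_state(1)[0] % 2**31))
        else:
            g = graph
        _require_connected(g)
        rates = DegreeCoupledRates(g)
        ss = np.random.SeedSequence([seed, g_idx])
        s, t = _batch_on_graph(g, rates, n_runs, ss, max_steps, initial_mutant)
        successes += s
        total_steps += t
        per_graph.append((s, n_runs))
    return FixationEstimate(
        successes=successes,
        runs=ensemble_size,
        seed=seed,
        total_steps=total_steps,
        per_graph=tuple(per_graph),
    )


# ---------------------------------------------------------------------------
# Exact absorbing-chain oracle
# ---------------------------------------------------------------------------

def exact_fixation_markov(
    graph: Graph,
    rates: DegreeCoupledRates | None = None,
    cap: int = 12,
) -> dict[int, float]:
    """Exact single-mutant fixation probabilities via the full 2^N chain.

    Enumerates every occupation state as a bitmask, assembles the one-step
    transition matrix of the BD process, and solves the absorbing-chain
    linear system for the probability of reaching the all-mutant state.
    Returns ``{start node: fixation probability}``.  Cost grows as
    ``2^N * N * <k>``; the ``cap`` guards against accidental blow-up.
    """
    n = graph.n_nodes
    if n > cap:
        raise GraphError(f"exact solver capped at N <= {cap} (got N = {n})")
    _require_connected(graph)
    rates = rates or DegreeCoupledRates(graph)
    wild, mut = rates.death_vectors()
    indptr, indices = graph.adjacency_csr
    full = (1 << n) - 1
    n_states = 1 << n

    # transient states: everything except 0 and full
    transient = [s for s in range(n_states) if s not in (0, full)]
    t_index = {s: i for i, s in enumerate(transient)}
    rows, cols, vals = [], [], []
    b = np.zeros(len(transient))
    inv_n = 1.0 / n
    for s in transient:
        i = t_index[s]
        for rep in range(n):
            rep_mut = (s >> rep) & 1
            lo, hi = indptr[rep], indptr[rep + 1]
            nbrs = indices[lo:hi]
            w = np.where((s >> nbrs) & 1 == 1, mut[nbrs], wild[nbrs])
            w = w / w.sum()
            for j, pj in zip(nbrs, w):
                s2 = (s | (1 << int(j))) if rep_mut else (s & ~(1 << int(j)))
                prob = inv_n * float(pj)
                if s2 == full:
                    b[i] += prob
                elif s2 != 0:
                    rows.append(i)
                    cols.append(t_index[s2])
                    vals.append(prob)
    q = sp.csr_matrix((vals, (rows, cols)), shape=(len(transient), len(transient)))
    h = spla.spsolve(sp.identity(len(transient), format="csr") - q, b)
    return {node: float(h[t_index[1 << node]]) for node in range(n)}
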