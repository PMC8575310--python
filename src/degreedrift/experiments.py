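"""Config-driven fixation-probability experiments: star curves and network sweeps.

Three experiment families are bundled:

* ``star`` — exact fixation probabilities of the star graph (core-start
  pi_0^1 and leaf-start pi_1^0) against Monte-Carlo estimates and the
  well-mixed 1/(n+1) baseline, per leaf count n.
* ``smallworld`` — fixation probability of a single uniformly placed mutant
  on Watts-Strogatz networks, swept over the rewiring probability q.
* ``scalefree`` — the same swept over the power-law exponent gamma of
  configuration-model networks.

Each sweep point draws ``n_graphs`` fresh networks, splits the ensemble
evenly among them, and pools successes; both the pooled binomial standard
error and the across-network standard deviation are reported, along with the
mean empirical degree fluctuation and the 1/N baseline.  Everything derives
from the master seed, so a config reproduces byte-identically.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, IO

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bd_dynamics import FixationEstimate, estimate_fixation_probability
from .graph_core import Graph, degree_stats, make_scale_free, make_small_world, make_star
from .star_exact import leaf_core_ratio, moran_fixation, solve_star

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "pooled_network_estimate",
    "run_smallworld_sweep",
    "run_scalefree_sweep",
    "run_star_experiment",
    "write_sweep",
]

_EXPERIMENTS = ("star", "smallworld", "scalefree")


@dataclass
class ExperimentConfig:
    """Validated description of one sweep experiment.

    ``avg_degree`` is the lattice degree for small-world sweeps and the
    minimum degree k_min for scale-free sweeps (the configuration model
    controls <k> only indirectly; the realized mean degree is recorded per
    network in the output).
    """

    experiment: str
    nodes: int
    avg_degree: int
    sweep: list[float]
    n_graphs: int = 10
    ensemble_size: int = 1000
    seed: int = 0
    output: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"experiment must be one of {_EXPERIMENTS}")
        if self.nodes < 2:
            raise ValueError("nodes must be >= 2")
        if self.n_graphs < 1 or self.ensemble_size < 1:
            raise ValueError("n_graphs and ensemble_size must be >= 1")
        if not self.sweep:
            raise ValueError("sweep values are required")
        self.sweep = [float(v) for v in self.sweep]
        if self.experiment == "smallworld":
            for q in self.sweep:
                if not 0.0 <= q <= 1.0:
                    raise ValueError(f"rewiring probability {q} outside [0, 1]")
        elif self.experiment == "scalefree":
            for g in self.sweep:
                if g <= 2.0:
                    raise ValueError(f"scale-free exponent {g} must exceed 2")
        else:  # star: sweep over leaf counts
            for n in self.sweep:
                if n < 1 or n != int(n):
                    raise ValueError(f"leaf count {n} must be a positive integer")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML/JSON config; schema violations name the offending field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in ExperimentConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    try:
        return ExperimentConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pooled estimation over a network ensemble
# ---------------------------------------------------------------------------

def pooled_network_estimate(
    factory: Callable[[int], Graph],
    ensemble_size: int,
    n_graphs: int,
    seed: int,
) -> tuple[FixationEstimate, float, float]:
    """Draw ``n_graphs`` networks, pool fixation runs, and summarize structure.

    Returns ``(estimate, mean_delta, mean_avg_degree)`` where the last two
    average the empirical degree fluctuation and mean degree over the drawn
    networks.  Graph seeds and run streams both derive from ``seed``.
    """
    ss = np.random.SeedSequence([int(seed), 0xE5])
    graph_seeds = [int(s) for s in ss.generate_state(n_graphs) % (2**31)]
    runs_per_graph = ensemble_size // n_graphs
    remainder = ensemble_size % n_graphs
    successes = 0
    total_steps = 0
    per_graph: list[tuple[int, int]] = []
    deltas: list[float] = []
    avg_degrees: list[float] = []
    for g_idx, g_seed in enumerate(graph_seeds):
        n_runs = runs_per_graph + (1 if g_idx < remainder else 0)
        if n_runs == 0:
            continue
        graph = factory(g_seed)
        stats = degree_stats(graph)
        deltas.append(float(stats.fluctuation))
        avg_degrees.append(float(stats.mean))
        est = estimate_fixation_probability(graph, n_runs, seed=g_seed)
        successes += est.successes
        total_steps += est.total_steps
        per_graph.append((est.successes, n_runs))
    pooled = FixationEstimate(
        successes=successes,
        runs=ensemble_size,
        seed=seed,
        total_steps=total_steps,
        per_graph=tuple(per_graph),
    )
    return pooled, float(np.mean(deltas)), float(np.mean(avg_degrees))


def _sweep_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    assert ((df["p_hat"] >= 0) & (df["p_hat"] <= 1)).all()
    return df


def _run_sweep(
    config: ExperimentConfig,
    factory_for: Callable[[float], Callable[[int], Graph]],
    param_name: str,
    log: bool = True,
) -> pd.DataFrame:
    rows = []
    for p_idx, value in enumerate(sorted(config.sweep)):
        point_seed = int(
            np.random.SeedSequence([config.seed, p_idx]).generate_state(1)[0] % 2**31
        )
        try:
            est, delta, kbar = pooled_network_estimate(
                factory_for(value), config.ensemble_size, config.n_graphs, point_seed
            )
        except Exception as exc:
            raise RuntimeError(f"sweep point {param_name}={value} failed: {exc}") from exc
        rows.append(
            {
                param_name: value,
                "p_hat": est.probability,
                "se": est.std_error,
                "sd_networks": est.across_graph_sd,
                "delta_mean": delta,
                "moran": 1.0 / config.nodes,
                "avg_degree_realized": kbar,
                "N": config.nodes,
                "runs": est.runs,
                "successes": est.successes,
                "seed": point_seed,
            }
        )
        if log:
            print(
                f"[{config.experiment}] {param_name}={value:g}: "
                f"p_hat={est.probability:.5f} (se={est.std_error:.5f})",
                file=sys.stderr,
            )
    return _sweep_frame(rows)


def run_smallworld_sweep(config: ExperimentConfig, log: bool = True) -> pd.DataFrame:
    """Fixation probability versus rewiring probability q."""
    if config.experiment != "smallworld":
        raise ValueError("config.experiment must be 'smallworld'")

    def factory_for(q: float) -> Callable[[int], Graph]:
        return lambda s: make_small_world(config.nodes, config.avg_degree, q, s)

    return _run_sweep(config, factory_for, "q", log=log)


def run_scalefree_sweep(config: ExperimentConfig, log: bool = True) -> pd.DataFrame:
    """Fixation probability versus power-law exponent gamma (k_min = avg_degree)."""
    if config.experiment != "scalefree":
        raise ValueError("config.experiment must be 'scalefree'")

    def factory_for(gamma: float) -> Callable[[int], Graph]:
        return lambda s: make_scale_free(config.nodes, gamma, k_min=config.avg_degree, seed=s)

    return _run_sweep(config, factory_for, "gamma", log=log)


def run_star_experiment(
    n_min: int,
    n_max: int,
    ensemble_size: int = 10000,
    seed: int = 0,
    simulate: bool = True,
) -> pd.DataFrame:
    """Exact star fixation probabilities per n, optionally with simulation.

    Columns: exact core-start pi_0^1 and leaf-start pi_1^0, Monte-Carlo
    estimates with the mutant forced onto the core (node 0) or a leaf
    (node 1), the well-mixed baseline 1/(n+1), and the closed-form ratio.
    """
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    rows = []
    for idx, n in enumerate(range(n_min, n_max + 1)):
        sol = solve_star(n)
        row = {
            "n": n,
            "pi_core": sol.core_start,
            "pi_leaf": sol.leaf_start,
            "moran_1_over_N": 1.0 / (n + 1),
            "ratio_check": float(leaf_core_ratio(n)),
        }
        if simulate:
            graph = make_star(n)
            point_seed = int(
                np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31
            )
            core = estimate_fixation_probability(
                graph, ensemble_size, seed=point_seed, initial_mutant=0
            )
            leaf = estimate_fixation_probability(
                graph, ensemble_size, seed=point_seed + 1, initial_mutant=1
            )
            row.update(
                p_core_sim=core.probability,
                se_core=core.std_error,
                p_leaf_sim=leaf.probability,
                se_leaf=leaf.std_error,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_sweep(result: pd.DataFrame, path: str | Path | IO[str], seed: int | None = None) -> None:
    """CSV with a comment header recording provenance (seed, package version)."""
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        fh.write(f"# degreedrift {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        result.to_csv(fh, index=False)
    finally:
        if own:
            fh.close()
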