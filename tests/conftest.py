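import numpy as np
import pytest
from hypothesis import settings

import degreedrift as dd

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example12():
    """The 12-node worked-example population (graph + mutant set)."""
    return dd.make_twelve_node_example()


@pytest.fixture(scope="session")
def example12_state(example12):
    return dd.PopulationState.from_mutants(example12.graph, example12.mutants)


@pytest.fixture(scope="session")
def small_graph_battery():
    """Connected graphs with N <= 10 for oracle cross-validation."""
    cycle = dd.make_ring_lattice(8, 2)
    path = dd.Graph.from_edges(6, [(i, i + 1) for i in range(5)])
    return {
        "star5": dd.make_star(5),
        "cycle8": cycle,
        "path6": path,
        "K5": dd.make_complete(5),
        "sf10": dd.make_scale_free(10, 3.5, k_min=2, seed=42),
    }


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba compilation once so per-test timings stay honest."""
    dd.estimate_fixation_probability(dd.make_complete(3), 2, seed=0)
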