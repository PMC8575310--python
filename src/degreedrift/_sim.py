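"""JIT-compiled Monte-Carlo kernels for the birth-death process.

The kernels work on the CSR adjacency arrays plus two per-node death-weight
vectors (one per occupant type); everything else about the model lives in
:mod:`degreedrift.bd_dynamics`.  Each run is seeded independently so batches
are reproducible run-by-run regardless of batching.
"""

import numpy as np
from numba import njit

__all__ = ["simulate_run", "simulate_batch"]


@njit(cache=True)
def simulate_run(indptr, indices, death_wild, death_mut, start, seed, max_steps):
    """One trajectory to absorption.

    Returns (outcome, steps): outcome 1 if the mutant lineage fixed, 0 if it
    was lost, -1 if ``max_steps`` elapsed first.
    """
    np.random.seed(seed)
    n = indptr.size - 1
    state = np.zeros(n, dtype=np.uint8)
    state[start] = 1
    mutants = 1
    steps = 0
    while 0 < mutants < n:
        if steps >= max_steps:
            return -1, steps
        steps += 1
        rep = np.random.randint(0, n)
        lo = indptr[rep]
        hi = indptr[rep + 1]
        total = 0.0
        for p in range(lo, hi):
            j = indices[p]
            total += death_mut[j] if state[j] == 1 else death_wild[j]
        r = np.random.random() * total
        victim = indices[hi - 1]
        acc = 0.0
        for p in range(lo, hi):
            j = indices[p]
            acc += death_mut[j] if state[j] == 1 else death_wild[j]
            if r < acc:
                victim = j
                break
        if state[victim] != state[rep]:
            mutants += 1 if state[rep] == 1 else -1
            state[victim] = state[rep]
    return (1 if mutants == n else 0), steps


@njit(cache=True)
def simulate_batch(indptr, indices, death_wild, death_mut, starts, seeds, max_steps):
    """Run one trajectory per (start, seed) pair; returns (outcomes, steps)."""
    n_runs = starts.size
    outcomes = np.empty(n_runs, dtype=np.int8)
    steps = np.empty(n_runs, dtype=np.int64)
    for r in range(n_runs):
        o, s = simulate_run(
            indptr, indices, death_wild, death_mut, starts[r], seeds[r], max_steps
        )
        outcomes[r] = o
        steps[r] = s
    return outcomes, steps
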