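# Methods

## Model

The process is a birth–death (BD) Moran model on a connected, undirected
simple graph with one individual per node. Each update:

1. a reproducer is drawn uniformly among all `N` nodes (all birth rates are
   1, for both types);
2. one neighbor of the reproducer is drawn to die, with probability
   proportional to its death rate renormalized over that neighborhood:
   `P(j dies) = d(j) / Σ_{l ∈ nbrs} d(l)`;
3. the victim's node takes the reproducer's type.

Death rates: `d_A = 1` for wild type everywhere; `d_B(i) = k_i / <k>` for a
mutant at node `i`. Because `Σ_i k_i = N <k>`, the population-averaged
mutant death rate is exactly 1 (asserted in rational arithmetic), so the
model is neutral in the mean — "average neutral drift". Two consequences
shape everything else:

- On a regular graph `k_i ≡ <k>`, every rate is 1 and the single-mutant
  fixation probability is the classical `1/N`.
- On a heterogeneous graph the renormalized death selection favors mutants
  on low-degree nodes and exposes mutants on hubs; fixation probability
  deviates from `1/N` in a direction and magnitude tied to the degree
  fluctuation `Δ = <k²>/<k>² − 1`.

The offspring always replaces a neighbor, never the reproducer itself
(no "self" loop in the update). A reproducer and victim of the same type
leave the composition unchanged; such steps still count as one event.
Fixation probability is invariant to this time parameterization, and
fixation *times* are deliberately out of scope.

## Star graph: exact solution

The star (core plus `n` leaves) has `<k> = 2n/(n+1)`, mutant death rates
`d_core = (n+1)/2` and `d = (n+1)/(2n)`. The process closes on the
`2(n+1)` configurations `(u, v)` — `u` mutant leaves, core occupancy `v` —
because all leaves are exchangeable. The non-trivial one-step transition
probabilities are

    α_i⁰ = 1/(n+1) · i·d/(i·d + n−i)      (i,0) → (i−1,0)
    β_i⁰ = i/(n+1)                        (i,0) → (i,1)
    α_i¹ = 1/(n+1) · (n−i)/(i·d + n−i)    (i,1) → (i+1,1)
    β_i¹ = (n−i)/(n+1)                    (i,1) → (i,0)

Note `d_core` appears nowhere: a leaf's only neighbor is the core, so the
renormalization collapses to probability 1 regardless of the core's rate.
This irrelevance is asserted explicitly in two independent ways (a `d_core`
parameter threaded through the chain construction, and a perturbed rate
model in the 2^N oracle).

Two solvers are provided and must agree to 1e−10:

- **Direct chain solve (default).** The `2(n+1)`-state absorbing chain is
  assembled from first principles of the BD step and solved sparsely. This
  is robust for all `n` tried (tested to `n = 200`) and is the reference
  path.
- **Matrix recursion (secondary).** Conditioning on a state change gives
  jump parameters `P_i^← , P_i^↓ , P_i^→ , P_i^↑` and a two-term recursion
  `X_i = A_i X_{i−1}` on `X_i = (π_i¹, π_i⁰)`; the n-fold product with the
  boundary conditions `π₀⁰ = 0`, `π_n¹ = 1` yields `π₀¹ = 1/M₀₀`. The
  product is accumulated with per-step max-norm renormalization (tracking
  the log of the scale) so large `n` cannot overflow.

The closed-form ratio between the two single-mutant starts is

    π₁⁰ / π₀¹ = (n+1)(2n² − n + 1) / (2n² + 2).

It follows in two lines from the recursion (`π₁¹ = (n+1) π₀¹` and
`π₁⁰ = P₁^↓ π₁¹` with `P₁^↓ = (2n²−n+1)/(2n²+2)`), passes the degeneracy
check at `n = 1` (the one-leaf star is K₂, which is regular, so the ratio
must be exactly 1), and matches both exact solvers to 1e−9 over
`n = 2..50`. The leaf-start probability `π₁⁰` is the product of a
decreasing `π₀¹` and this roughly linearly growing coefficient; scanning
`n = 2..30` locates its minimum at `n = 5`.

## Exact oracle for arbitrary small graphs

`exact_fixation_markov` enumerates all `2^N` occupation states, builds the
one-step transition matrix of the BD process, and solves the absorbing-chain
linear system `(I − Q) h = b` sparsely for the probability of reaching the
all-mutant state. Cost is `O(2^N · N · <k>)`; the default cap is `N ≤ 12`.
It is the ground truth the Monte-Carlo kernel and the star solvers are
validated against (agreement to 1e−10 exact-vs-exact, 3 binomial SEs
exact-vs-simulated).

## Monte-Carlo estimator

The kernel (numba-compiled) simulates trajectories to absorption on the CSR
adjacency with per-node death-weight vectors. Estimates report pooled
`successes/runs`, the binomial standard error `sqrt(p(1−p)/runs)`, and —
when an ensemble of networks is involved — the across-network standard
deviation of per-graph estimates as a second, more conservative error
flavor (the two answer different questions: sampling noise at fixed
structure versus structure-to-structure variability).

Seeding: every public entry point takes one integer seed; per-graph and
per-run substreams derive from `SeedSequence((seed, graph_index))`, and each
trajectory is seeded independently, so results are bit-reproducible and
independent of batching. A safety cap (default 10⁹ steps per run) turns a
non-absorbing run into a hard error rather than a silent hang; on connected
graphs absorption is certain and the cap is never approached at the sizes
used here.

## Network generators

- **Ring lattice / complete / star**: deterministic, via networkx, wrapped
  in the package's validated container (simple, undirected, connected).
- **Small world**: Watts–Strogatz. Starting from the ring lattice with even
  degree `k`, each lattice edge has its far endpoint reattached to a
  uniformly random node with probability `q`, rejecting self-loops and
  duplicates, so exactly `N·k/2` edges survive for every `q`. `q = 0`
  returns the lattice unchanged; disconnected draws are regenerated from
  fresh seed-derived streams (up to 100 tries, then an error — a silently
  disconnected graph would make fixation unreachable).
- **Scale free**: a configuration model with a freely tunable exponent.
  Degrees are drawn i.i.d. from the discrete distribution `p(k) ∝ k^−γ` on
  `k_min ≤ k ≤ N−1`, the stub-sum parity is fixed by resampling one node,
  stubs are paired uniformly, and self-loops/multi-edges are eliminated by
  degree-preserving double-edge swaps; the full draw is retried until the
  result is simple and connected. Growth-with-preferential-attachment is
  *not* used because it pins the exponent near 3; the configuration model
  is the standard construction when γ must be swept at fixed `N`. The
  realized degree sequence is preserved exactly by the repair step, so the
  empirical `Δ` of a generated graph equals the `Δ` of its drawn sequence.

**Default `k_min = 3`.** The minimum degree controls the realized average
degree (`<k> ≈ 3.5–6.5` across `γ ∈ [2.5, 5]` at `k_min = 3`), placing the
ensembles in the moderately dense regime where the model's headline trends
hold. This choice matters: at `k_min = 2` and large γ the graphs degenerate
toward a ring decorated with a few hubs (`<k> ≈ 2.25` at `γ = 5`), and in
that regime the hub penalty dominates — the exact oracle confirms fixation
probability *below* `1/N` on such graphs. That is a real property of the
model worth knowing, not an artifact, but it lies outside the
moderate-density conditions the sweep experiments are meant to probe.
`k_min` remains a user-settable parameter.

## Degree fluctuation: closed forms and their limits

`theoretical_fluctuation` implements the ideal power-law results
`Δ = (γ−2)²/[(γ−1)(γ−3)] − 1` for `γ > 3` and the `k_max/<k>`-cutoff form
for `2 < γ < 3`; `γ = 3` is singular and rejected. These are continuum
integrals. The generator samples the *discrete* distribution, whose moments
differ at small `k_min` (e.g. `Δ = 0.315` for `γ = 4, k_min = 3` by direct
summation, versus the continuum 1/3), and the finite-sample ratio estimator
`m₂/m₁²` is additionally biased low at moderate `N`. Tests therefore check
the generator against the exact moments of the distribution it samples
(computed independently by summation), and check the continuum value only
within the sampling dispersion of large-`N` ensembles, where hub-driven
variance dominates. For `γ < 3` the second moment's variance grows with the
cutoff `k_max ≈ N`, so seed-to-seed scatter in `Δ` is intrinsically large
there — an inherited property of power laws, not a generator defect.

## Sweep experiments

Per sweep point, `n_graphs` networks are generated and the run ensemble is
split evenly among them with successes pooled (the point estimate weights
networks equally up to integer division). Defaults — `N = 100`, 10 networks
× 1 000–2 000 runs per point, q-grid `{0, 0.01, 0.05, 0.1, 0.2, 0.4, 0.7,
1.0}` (log-ish, since the small-world transition concentrates at small q),
γ-grid `{2.2, 2.5, 2.8, 3.2, 3.6, 4, 5, 6}` — complete in minutes on one
CPU; larger settings are accepted and simply take proportionally longer.
Trend assertions in tests compare neighboring sweep points at three pooled
standard errors.

## What the synthetic networks do and do not capture

The generators produce the structural features the model couples to —
tunable degree fluctuation at fixed size, the lattice-to-random
interpolation, heavy-tailed degree sequences. They do not emulate degree
correlations, clustering beyond what the constructions imply, community
structure, or weighted/directed interactions, all of which real contact and
resource networks have; conclusions from passing tests are about the degree
distribution's effect in isolation. The 12-node worked example is one
explicit completion of a partially specified structure (hub neighborhood,
three fixed degrees, `<k> = 3`); every assertion made on it depends only on
the pinned features.

## Numerical conventions

- Exact where exactness is cheap: degree statistics, death rates, and
  death-selection probabilities use `fractions.Fraction`; regularity tests
  (`Δ = 0`, mean rate = 1) are exact, not toleranced.
- Exact-vs-exact comparisons: 1e−10 (solver precision); closed-form
  identities: 1e−9 over the tested range; Monte-Carlo-vs-exact: 3 standard
  errors.
- Problem sizes: simulation-backed tests use `N ≤ 128` networks and
  2×10⁴-run ensembles per point; the `2^N` oracle is exercised to `N = 12`;
  star solvers to `n = 200`. These sizes keep the full suite at a few
  minutes while leaving every statistical comparison with ≥3σ resolution.

## Known limitations

- Fixation time and survivorship statistics are not computed.
- The `2 < γ < 3` cutoff form requires the user to supply `k_max/<k>`; the
  package does not predict `k_max` scaling for a finite sample.
- The exact oracle is exponential in `N`; beyond `N = 12` the Monte-Carlo
  path with its binomial error is the only route.
- Directed, weighted, and dynamically growing graphs are unsupported.
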