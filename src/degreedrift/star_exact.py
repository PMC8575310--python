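"""Exact fixation machinery for the star graph under degree-coupled BD dynamics.

The star with a core and n leaves is the simplest strongly heterogeneous
graph: <k> = 2n/(n+1), so a mutant dies at rate d_o = (n+1)/2 in the core
and d = (n+1)/(2n) < 1 on a leaf.  Because every leaf's only neighbor is the
core, the core's death rate never enters the dynamics — a reproducing leaf
replaces the core with probability 1 — and the process closes on the
2(n+1) configurations (u, v): u mutant leaves, core occupancy v in {0, 1}.

Writing pi_i^v for the fixation probability started from configuration
(i, v), the one-step transition probabilities are

    alpha_i^0 = W((i,0)->(i-1,0)) = 1/(n+1) * i d / (i d + n - i)
    beta_i^0  = W((i,0)->(i,1))   = i/(n+1)
    alpha_i^1 = W((i,1)->(i+1,1)) = 1/(n+1) * (n - i) / (i d + n - i)
    beta_i^1  = W((i,1)->(i,0))   = (n - i)/(n+1)

with the remaining mass on staying put.  Conditioning on a state change
turns the first-step equations into a two-term recursion X_i = A_i X_{i-1}
on X_i = (pi_i^1, pi_i^0), whose n-fold product plus the boundary conditions
pi_0^0 = 0, pi_n^1 = 1 pins the whole solution; that product form is kept
here as the secondary path, while the default path solves the 2(n+1)-state
absorbing chain directly (sparse linear algebra, robust for large n).

The two closed forms checked against this machinery: the leaf/core ratio
pi_1^0 = [(n+1)(2n^2-n+1)/(2n^2+2)] pi_0^1, and the classical well-mixed
fixation probability rho_1 = (1-d/r)/(1-(d/r)^N).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "StarRates",
    "StarSolution",
    "star_death_rates",
    "star_transition_probs",
    "star_p_parameters",
    "star_recursion_matrix",
    "solve_star",
    "leaf_core_ratio",
    "leaf_start_minimum",
    "moran_fixation",
]


@dataclass(frozen=True)
class StarRates:
    """Mutant death rates on a star with n leaves (exact rationals)."""

    n: int
    d_core: Fraction
    d_leaf: Fraction


def star_death_rates(n: int) -> StarRates:
    """d_core = (n+1)/2 and d_leaf = (n+1)/(2n); their population mean is 1."""
    if n < 1:
        raise ValueError("a star needs at least one leaf")
    return StarRates(n, Fraction(n + 1, 2), Fraction(n + 1, 2 * n))


def _check_i(n: int, i: int) -> None:
    if not 0 <= i <= n:
        raise ValueError(f"leaf-mutant count i={i} outside 0..{n}")


def star_transition_probs(
    n: int, i: int, core_mutant: bool
) -> tuple[Fraction, Fraction, Fraction]:
    """(alpha, beta, stay) for configuration (i, core_mutant), exact.

    alpha is the mutant-count-decreasing move for a wild core
    ((i,0) -> (i-1,0)) and the increasing move for a mutant core
    ((i,1) -> (i+1,1)); beta flips the core occupancy.  The triple sums to 1
    exactly, and both absorbing configurations (0,0) and (n,1) return
    (0, 0, 1).
    """
    _check_i(n, i)
    d = star_death_rates(n).d_leaf
    if core_mutant:
        # core reproduces into a wild leaf / a wild leaf reproduces into the core
        alpha = (
            Fraction(1, n + 1) * Fraction(n - i) / (i * d + (n - i))
            if i < n
            else Fraction(0)
        )
        beta = Fraction(n - i, n + 1)
    else:
        # core reproduces into a mutant leaf / a mutant leaf reproduces into the core
        alpha = (
            Fraction(1, n + 1) * (i * d) / (i * d + (n - i)) if i > 0 else Fraction(0)
        )
        beta = Fraction(i, n + 1)
    return alpha, beta, 1 - alpha - beta


def star_p_parameters(
    n: int, i: int
) -> tuple[Fraction | None, Fraction | None, Fraction | None, Fraction | None]:
    """Conditional jump probabilities (P_left, P_down, P_right, P_up).

    Conditioning on a state change: from (i,0) the chain moves left to
    (i-1,0) w.p. P_left = alpha_i^0/(alpha_i^0+beta_i^0) or down to (i,1)
    w.p. P_down (defined for i >= 1); from (i,1) it moves right to (i+1,1)
    w.p. P_right = 1/(1 + i d + n - i) or up to (i,0) w.p. P_up (defined for
    i <= n-1).  Undefined branches (the absorbing ends, where the total jump
    probability vanishes) are returned as None.
    """
    _check_i(n, i)
    p_left = p_down = p_right = p_up = None
    a0, b0, _ = star_transition_probs(n, i, core_mutant=False)
    if a0 + b0 > 0:
        p_left = a0 / (a0 + b0)
        p_down = b0 / (a0 + b0)
    a1, b1, _ = star_transition_probs(n, i, core_mutant=True)
    if a1 + b1 > 0:
        p_right = a1 / (a1 + b1)
        p_up = b1 / (a1 + b1)
    return p_left, p_down, p_right, p_up


def star_recursion_matrix(n: int, i: int) -> np.ndarray:
    """The 2x2 matrix A_i with X_i = A_i X_{i-1}, X_i = (pi_i^1, pi_i^0).

    Entries combine the conditional jump parameters at i-1 (right/up) and at
    i (left/down); valid for 1 <= i <= n.
    """
    if not 1 <= i <= n:
        raise ValueError(f"recursion index i={i} outside 1..{n}")
    _, _, pr_prev, pu_prev = star_p_parameters(n, i - 1)
    pl, pd, _, _ = star_p_parameters(n, i)
    assert pr_prev is not None and pl is not None
    a00 = 1 / pr_prev
    a01 = -pu_prev / pr_prev
    a10 = pd / pr_prev
    a11 = pl - pu_prev * pd / pr_prev
    return np.array([[float(a00), float(a01)], [float(a10), float(a11)]])


@dataclass(frozen=True)
class StarSolution:
    """Fixation probabilities over all star configurations.

    ``pi0[i]`` starts from i mutant leaves and a wild-type core; ``pi1[i]``
    from i mutant leaves and a mutant core.  ``core_start`` (= pi1[0]) and
    ``leaf_start`` (= pi0[1]) are the two single-mutant cases.
    """

    n: int
    pi0: np.ndarray
    pi1: np.ndarray

    @property
    def core_start(self) -> float:
        return float(self.pi1[0])

    @property
    def leaf_start(self) -> float:
        return float(self.pi0[1])


def _solve_star_chain(n: int, d_core: float | None = None) -> StarSolution:
    """Default path: direct sparse solve of the 2(n+1)-state absorbing chain.

    Transitions are rebuilt from first principles of the BD step (uniform
    reproducer over the n+1 nodes, neighborhood-renormalized death rates),
    with the core death rate an explicit parameter — whose value provably
    cannot matter, since a leaf's only neighbor is chosen with probability 1.
    """
    d_leaf = float(star_death_rates(n).d_leaf)
    if d_core is None:
        d_core = float(star_death_rates(n).d_core)
    if d_core <= 0:
        raise ValueError("death rates must be positive")
    size = 2 * (n + 1)

    def idx(i: int, v: int) -> int:
        return 2 * i + v

    rows, cols, vals = [], [], []
    b = np.zeros(size)
    diag = np.zeros(size)
    for i in range(n + 1):
        for v in (0, 1):
            s = idx(i, v)
            if (i, v) in ((0, 0), (n, 1)):
                diag[s] = 1.0
                b[s] = 1.0 if v == 1 else 0.0
                continue
            if v == 1:
                # core mutant: core reproduces (1/(n+1)) into a leaf chosen by
                # death weight (mutant leaf d_leaf, wild leaf 1); any wild
                # leaf reproduces into the core, whose weight d_core
                # renormalizes over the single-neighbor set to d_core/d_core.
                denom = i * d_leaf + (n - i)
                alpha = (n - i) / ((n + 1) * denom)  # -> (i+1, 1)
                beta = ((n - i) / (n + 1)) * (d_core / d_core)  # -> (i, 0)
                targets = [(idx(i + 1, 1), alpha), (idx(i, 0), beta)]
            else:
                denom = i * d_leaf + (n - i)
                alpha = i * d_leaf / ((n + 1) * denom)  # -> (i-1, 0)
                beta = i / (n + 1)  # -> (i, 1): a mutant leaf replaces the core
                targets = [(idx(i - 1, 0), alpha), (idx(i, 1), beta)]
            move = alpha + beta
            diag[s] = move
            for t, p in targets:
                if p:
                    rows.append(s)
                    cols.append(t)
                    vals.append(-p)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(size, size)) + sp.diags(diag)
    h = spla.spsolve(a.tocsr(), b)
    pi0 = np.array([h[idx(i, 0)] for i in range(n + 1)])
    pi1 = np.array([h[idx(i, 1)] for i in range(n + 1)])
    return StarSolution(n, pi0, pi1)


def _solve_star_recursion(n: int) -> StarSolution:
    """Secondary path: the 2x2 matrix product with the boundary conditions.

    By linearity X_i = pi_0^1 * y_i with y_0 = (1, 0); the product is
    accumulated with per-step renormalization (tracking the log scale) so
    large n does not overflow, and pi_0^1 = 1 / (scale * y_n[0]).
    """
    y = np.array([1.0, 0.0])
    log_scale = 0.0
    ys = [(y.copy(), log_scale)]
    for i in range(1, n + 1):
        y = star_recursion_matrix(n, i) @ y
        norm = np.abs(y).max()
        y /= norm
        log_scale += np.log(norm)
        ys.append((y.copy(), log_scale))
    # boundary pi_n^1 = 1  =>  pi_0^1 * exp(log_scale) * y_n[0] = 1
    log_pi01 = -(log_scale + np.log(y[0]))
    pi0 = np.empty(n + 1)
    pi1 = np.empty(n + 1)
    for i, (yi, ls) in enumerate(ys):
        scale = np.exp(log_pi01 + ls)
        pi1[i] = yi[0] * scale
        pi0[i] = yi[1] * scale
    return StarSolution(n, pi0, pi1)


def solve_star(n: int, method: str = "chain", d_core: float | None = None) -> StarSolution:
    """Exact fixation probabilities for the star with n leaves.

    ``method="chain"`` (default) solves the 2(n+1)-state absorbing chain
    directly; ``method="recursion"`` follows the renormalized 2x2 matrix
    product.  The two agree to solver precision and are tested against each
    other and against the brute-force 2^N oracle.  ``d_core`` overrides the
    core death rate in the chain path (it cannot change the answer; exposed
    so that irrelevance is assertable).
    """
    if n < 1:
        raise ValueError("a star needs at least one leaf")
    if method == "chain":
        return _solve_star_chain(n, d_core=d_core)
    if method == "recursion":
        if d_core is not None:
            raise ValueError("the recursion path does not parameterize d_core")
        return _solve_star_recursion(n)
    raise ValueError(f"unknown method {method!r}")


def leaf_core_ratio(n: int) -> Fraction:
    """Closed-form ratio pi_1^0 / pi_0^1 = (n+1)(2n^2-n+1) / (2n^2+2).

    Follows from the first recursion step: pi_1^1 = (n+1) pi_0^1 and
    pi_1^0 = P_1^down pi_1^1 with P_1^down = (2n^2-n+1)/(2n^2+2).  Equals 1
    at n = 1 (the star degenerates to the regular K_2) and grows like n for
    large n.
    """
    if n < 1:
        raise ValueError("a star needs at least one leaf")
    return Fraction((n + 1) * (2 * n * n - n + 1), 2 * n * n + 2)


def leaf_start_minimum(n_min: int = 2, n_max: int = 30, method: str = "chain") -> int:
    """The leaf count n minimizing the leaf-start fixation probability pi_1^0.

    pi_0^1 decreases monotonically in n while the ratio pi_1^0/pi_0^1 grows
    roughly linearly, so their product dips and recovers; the minimum sits at
    n = 5 within any range containing it.
    """
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    values = {n: solve_star(n, method=method).leaf_start for n in range(n_min, n_max + 1)}
    return min(values, key=values.get)


def moran_fixation(d_ratio: float = 1.0, r_ratio: float = 1.0, N: int = 2) -> float:
    """Well-mixed Moran fixation probability rho_1 = (1 - d/r)/(1 - (d/r)^N).

    ``d_ratio`` and ``r_ratio`` are the mutant/wild-type death- and
    birth-rate ratios; the neutral case d/r = 1 returns the limit 1/N.
    """
    if N < 2:
        raise ValueError("population size must be >= 2")
    if d_ratio <= 0 or r_ratio <= 0:
        raise ValueError("rate ratios must be positive")
    x = d_ratio / r_ratio
    if abs(x - 1.0) < 1e-12:
        return 1.0 / N
    return (1.0 - x) / (1.0 - x**N)
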