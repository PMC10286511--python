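"""Hebbian-reinforcement Monte Carlo over switch complexions.

Repeatable signalling requires the switch ensemble to settle into cycles
through its 2^M complexion states.  A minimal mechanism: a Markov chain
over the complexions whose transition probabilities, initially uniform,
are reinforced multiplicatively whenever a transition is realized (the row
is then renormalized) — Hebbian learning on the flexible protein matrix.
Trajectories of a fixed number of steps are sampled from random initial
states until the greedy (argmax) transition graph stops changing; the
surviving argmax graph is a functional graph whose cycles are the learned
attractors and whose basins give the probability that a randomly chosen
state falls into each cycle.

For M = 4 the basin-weighted mean number of ON switches per run clusters
around M/2 = 2: large cycles sample the state space, whose mean ON count
is binomial, and dominate the basin weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConvergenceError",
    "TransitionMatrix",
    "CycleResult",
    "init_matrix",
    "run_trajectory",
    "train_until_fixed_point",
    "extract_cycles",
    "balance_statistic",
    "run_campaign",
]

_ROW_TOL = 1e-12


class ConvergenceError(RuntimeError):
    """Training hit its trajectory cap before the cycle structure froze."""


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities over the 2^M complexions.

    State ``s`` encodes a complexion as an integer whose binary expansion
    (switch 1 = most significant of M bits) gives the ON/OFF pattern.
    """

    n_switches: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        n = 2**self.n_switches
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix for M={self.n_switches}")
        self.check_stochastic()

    @property
    def n_states(self) -> int:
        return 2**self.n_switches

    def check_stochastic(self, tol: float = _ROW_TOL) -> None:
        if np.any(self.probabilities < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > max(tol, 1e-9)):
            raise ValueError("every row must sum to 1")


@dataclass
class CycleResult:
    """Attractor cycles of a converged argmax transition graph."""

    n_switches: int
    cycles: list[tuple[int, ...]]
    basin_probability: np.ndarray
    mean_on_count: np.ndarray

    def __post_init__(self) -> None:
        self.basin_probability = np.asarray(self.basin_probability, dtype=float)
        self.mean_on_count = np.asarray(self.mean_on_count, dtype=float)

    @property
    def weighted_mean_on(self) -> float:
        """Basin-probability-weighted mean ON count over cycles."""
        return float(np.dot(self.basin_probability, self.mean_on_count))

    def membership_weighted_mean_on(self) -> float:
        """Alternative weighting by cycle membership instead of basin size."""
        lengths = np.array([len(c) for c in self.cycles], dtype=float)
        return float(np.dot(lengths / lengths.sum(), self.mean_on_count))


def _popcount(state: int) -> int:
    return bin(state).count("1")


def init_matrix(m: int) -> TransitionMatrix:
    """Uniform transition matrix over all 2^M states, self-transitions included."""
    if not 1 <= m <= 12:
        raise ValueError("switch count must lie in [1, 12]")
    n = 2**m
    return TransitionMatrix(m, np.full((n, n), 1.0 / n))


def run_trajectory(
    matrix: TransitionMatrix,
    start_state: int,
    n_steps: int = 16,
    reinforcement: float = 0.10,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Sample one trajectory, reinforcing each realized transition in place.

    At every step the next state is drawn from the current row; the
    realized entry is multiplied by (1 + reinforcement) and the row
    renormalized, so the matrix stays exactly row-stochastic.  Returns the
    visited path including the start state.
    """
    if reinforcement < 0:
        raise ValueError("reinforcement must be non-negative")
    n = matrix.n_states
    if not 0 <= start_state < n:
        raise ValueError(f"start state must lie in [0, {n})")
    rng = np.random.default_rng(rng)
    p = matrix.probabilities
    path = [start_state]
    s = start_state
    for _ in range(n_steps):
        row = p[s]
        nxt = int(np.searchsorted(np.cumsum(row), rng.random(), side="right"))
        nxt = min(nxt, n - 1)  # guard the cumsum's float endpoint
        if reinforcement > 0:
            row[nxt] *= 1.0 + reinforcement
            row /= row.sum()
        path.append(nxt)
        s = nxt
    return path


def train_until_fixed_point(
    m: int,
    reinforcement: float = 0.10,
    n_steps: int = 16,
    p_star: float = 0.99,
    stable_window: int = 50,
    max_trajectories: int = 50_000,
    rng: np.random.Generator | int | None = None,
) -> TransitionMatrix:
    """Repeat reinforced trajectories until the cycle structure is frozen.

    Convergence requires every row's dominant probability to reach
    ``p_star`` and the argmax graph to remain unchanged for
    ``stable_window`` consecutive trajectories.  Each trajectory starts
    from a fresh uniformly drawn initial state.  Different seeds converge
    to different cycle sets; that variability is part of the model.
    """
    rng = np.random.default_rng(rng)
    matrix = init_matrix(m)
    p = matrix.probabilities
    prev_argmax = p.argmax(axis=1)
    stable = 0
    for _ in range(max_trajectories):
        start = int(rng.integers(matrix.n_states))
        run_trajectory(matrix, start, n_steps, reinforcement, rng)
        argmax = p.argmax(axis=1)
        stable = stable + 1 if np.array_equal(argmax, prev_argmax) else 0
        prev_argmax = argmax
        if stable >= stable_window and p.max(axis=1).min() >= p_star:
            return matrix
    raise ConvergenceError(
        f"no fixed point after {max_trajectories} trajectories "
        f"(min dominant probability {p.max(axis=1).min():.3f}, "
        f"stable for {stable} trajectories)"
    )


def extract_cycles(matrix: TransitionMatrix, tie_tol: float = 1e-9) -> CycleResult:
    """Cycles and basins of the argmax (greedy) transition graph.

    Follows the dominant transition out of every state; in the resulting
    functional graph every state flows into exactly one cycle.  Basin
    probability of a cycle is the fraction of the 2^M states whose greedy
    trajectory enters it; the cycle's mean ON count averages the popcount
    of its member states.  Raises if any row's argmax is tied (the matrix
    has not converged).
    """
    p = matrix.probabilities
    n = matrix.n_states
    succ = p.argmax(axis=1)
    top = p[np.arange(n), succ]
    second = np.partition(p, -2, axis=1)[:, -2]
    if np.any(top - second < tie_tol):
        raise ValueError("argmax transition is tied for some state; matrix not converged")

    cycle_of = np.full(n, -1)  # cycle index each state drains into
    cycles: list[tuple[int, ...]] = []
    for s0 in range(n):
        if cycle_of[s0] >= 0:
            continue
        path, seen = [], {}
        s = s0
        while cycle_of[s] < 0 and s not in seen:
            seen[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if cycle_of[s] >= 0:
            idx = cycle_of[s]
        else:  # new cycle discovered at path[seen[s]:]
            cyc = tuple(path[seen[s]:])
            cycles.append(cyc)
            idx = len(cycles) - 1
        for t in path:
            cycle_of[t] = idx

    basins = np.bincount(cycle_of, minlength=len(cycles)) / n
    mean_on = np.array([np.mean([_popcount(s) for s in cyc]) for cyc in cycles])
    return CycleResult(matrix.n_switches, cycles, basins, mean_on)


def run_campaign(
    m: int,
    n_runs: int,
    rng: np.random.Generator | int | None = None,
    **train_kwargs,
) -> list[CycleResult]:
    """Independent train-and-extract runs (one child RNG stream per run)."""
    seq = np.random.SeedSequence(rng) if isinstance(rng, int) or rng is None else None
    if seq is not None:
        streams = [np.random.default_rng(s) for s in seq.spawn(n_runs)]
    else:
        streams = [rng] * n_runs
    results = []
    for stream in streams:
        matrix = train_until_fixed_point(m, rng=stream, **train_kwargs)
        results.append(extract_cycles(matrix))
    return results


def balance_statistic(results: list[CycleResult], min_runs: int = 30) -> dict:
    """Distribution of basin-weighted mean ON counts over independent runs.

    The headline statistic of the reinforcement experiment: for M = 4 the
    per-run weighted means cluster around M/2 = 2.
    """
    if len(results) < min_runs:
        raise ValueError(f"need at least {min_runs} converged runs, got {len(results)}")
    values = np.array([r.weighted_mean_on for r in results])
    return {
        "n_runs": len(results),
        "weighted_mean_on": values,
        "grand_mean": float(values.mean()),
        "std": float(values.std(ddof=1)),
        "min": float(values.min()),
        "max": float(values.max()),
    }
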