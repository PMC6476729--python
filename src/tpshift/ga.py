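"""Genetic-algorithm search for the weight matrix that best fits a cds.

Organisms are normalized 3x16 weight matrices; the fitness of an organism
is the similarity Fmax of the global alignment of the analysed sequence
against it.  The initial population is built from independent nucleotide
shuffles of the sequence itself, so every organism starts with the
sequence's base composition but no periodic signal beyond chance.  One
iteration performs selection of two parents (probability increasing with
fitness), a uniform-mask crossover producing one descendant that replaces
a low-fitness victim, and single-cell mutations (replacement by a uniform
[-5, +5] draw).  Every modified matrix is re-normalized to (R0, K0) so
fitness stays comparable, and only modified organisms are re-aligned
(fitness caching).

Two refinements make the search converge at desk-scale populations within
roughly a thousand alignments instead of hundreds of thousands: mutations
are accepted only when they improve their organism (an elitist/memetic
acceptance rule), and a share of the mutation proposals is always spent on
the current best organism.  Both can be disabled (``greedy_mutation``,
``mutate_best``, ``tournament_k``) to recover plain
fitness-roulette dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .align import global_align
from .matrices import (
    K0_DEFAULT,
    R0_DEFAULT,
    NormalizedWeightMatrix,
    build_w2,
    derive_skip_matrices,
    normalize_to,
    renormalize,
)
from .sequence import CodingSequence, build_m16, shuffle_nucleotides

__all__ = ["GAConfig", "GAState", "init_population", "ga_step", "optimize"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the full-scale procedure (population 500, 10% mutation
    with uniform [-5, +5] replacement draws, stop after 50 iterations
    without improvement); ``max_iterations`` caps the run at roughly twice
    the typical full-scale convergence length.  ``tournament_k`` selects
    parents (and the death victim) by k-tournament; set it to ``None`` for
    fitness-roulette.  ``improvement_tol`` is the minimum best-fitness gain
    that resets the stagnation counter.
    """

    population_size: int = 500
    mutation_fraction: float = 0.10
    mutation_low: float = -5.0
    mutation_high: float = 5.0
    stagnation_window: int = 50
    max_iterations: int = 20_000
    seed: int = 0
    h: int = 50
    r0: float = R0_DEFAULT
    k0: float = K0_DEFAULT
    renormalize_after_change: bool = True
    greedy_mutation: bool = True
    mutate_best: int = 2
    tournament_k: int | None = 4
    improvement_tol: float = 0.5

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must lie in [0, 1]")


@dataclass
class GAState:
    population: np.ndarray  # (P, 3, 16)
    fitness: np.ndarray  # (P,)
    p2: np.ndarray  # (16,) pair probabilities shared by all organisms
    best_matrix: np.ndarray  # best-ever (3, 16)
    best_fitness: float
    iteration: int
    stagnant: int
    mfmax_trace: list = field(default_factory=list)
    rng: np.random.Generator = None


def _fitness(s_codes, weights, d, h):
    der = derive_skip_matrices(weights)
    return float(
        _dp.global_fmax(
            s_codes,
            np.ascontiguousarray(weights),
            np.ascontiguousarray(der.skip1),
            np.ascontiguousarray(der.skip2),
            np.ascontiguousarray(der.boundary),
            float(d),
            int(h),
        )
    )


def init_population(seq: CodingSequence, config: GAConfig, d: float) -> GAState:
    """Population of normalized matrices from nucleotide shuffles of ``seq``."""
    p = seq.base_probabilities()
    if np.count_nonzero(p) < 2:
        raise ValueError("degenerate sequence: a single base type cannot seed matrices")
    rng = np.random.default_rng(config.seed)
    pop = np.empty((config.population_size, 3, 16))
    fitness = np.empty(config.population_size)
    p2 = None
    for org in range(config.population_size):
        shuffled = shuffle_nucleotides(seq, int(rng.integers(0, 2**31 - 1)))
        w2 = build_w2(build_m16(shuffled), p, seq.N)
        nwm = normalize_to(w2, config.r0, config.k0)
        if p2 is None:
            p2 = w2.p2
        pop[org] = nwm.weights
        fitness[org] = _fitness(seq.codes, pop[org], d, config.h)
    best = int(np.argmax(fitness))
    return GAState(
        population=pop,
        fitness=fitness,
        p2=p2,
        best_matrix=pop[best].copy(),
        best_fitness=float(fitness[best]),
        iteration=0,
        stagnant=0,
        mfmax_trace=[float(fitness[best])],
        rng=rng,
    )


def _roulette(rng, weights):
    total = weights.sum()
    if total <= 0:
        return int(rng.integers(0, weights.size))
    return int(rng.choice(weights.size, p=weights / total))


def _pick_high(rng, f, k):
    """Index with fitness-increasing probability (tournament or roulette)."""
    if k is None:
        eps = 1e-9 + 1e-6 * (f.max() - f.min())
        return _roulette(rng, f - f.min() + eps)
    cand = rng.integers(0, f.size, k)
    return int(cand[np.argmax(f[cand])])


def _pick_low(rng, f, k):
    """Index with fitness-decreasing probability."""
    if k is None:
        eps = 1e-9 + 1e-6 * (f.max() - f.min())
        return _roulette(rng, f.max() - f + eps)
    cand = rng.integers(0, f.size, k)
    return int(cand[np.argmin(f[cand])])


def ga_step(state: GAState, seq: CodingSequence, config: GAConfig, d: float) -> GAState:
    """One GA iteration (in place); returns ``state``."""
    rng = state.rng
    f = state.fitness
    pop = state.population
    P = config.population_size
    # selection and crossover: one descendant replaces a low-fitness victim
    p1 = _pick_high(rng, f, config.tournament_k)
    p2_idx = _pick_high(rng, f, config.tournament_k)
    mask = rng.random((3, 16)) < 0.5
    child = np.where(mask, pop[p1], pop[p2_idx])
    if config.renormalize_after_change:
        child = renormalize(child, state.p2, config.r0, config.k0)
    child_f = _fitness(seq.codes, child, d, config.h)
    victim = _pick_low(rng, f, config.tournament_k)
    if victim != int(np.argmax(f)):  # never collapse the current best
        pop[victim] = child
        f[victim] = child_f
    # point mutations: a share forced onto the best organism, rest random
    n_mut = int(round(config.mutation_fraction * P))
    best_i = int(np.argmax(f))
    for r in range(n_mut):
        org = best_i if r < config.mutate_best else int(rng.integers(0, P))
        w = pop[org].copy()
        cell = int(rng.integers(0, 48))
        w[cell // 16, cell % 16] = rng.uniform(config.mutation_low, config.mutation_high)
        if config.renormalize_after_change:
            w = renormalize(w, state.p2, config.r0, config.k0)
        new_f = _fitness(seq.codes, w, d, config.h)
        if config.greedy_mutation and new_f <= f[org]:
            continue
        pop[org] = w
        f[org] = new_f
    state.iteration += 1
    mfmax = float(f.max())
    state.mfmax_trace.append(mfmax)
    if mfmax > state.best_fitness + config.improvement_tol:
        state.best_fitness = mfmax
        state.best_matrix = pop[int(np.argmax(f))].copy()
        state.stagnant = 0
    else:
        state.stagnant += 1
    return state


def write_trace(state: GAState, path) -> None:
    """Write the per-iteration fitness trace as TSV (iteration, mFmax, best)."""
    best = -np.inf
    with open(path, "w") as fh:
        fh.write("iteration\tmFmax\tbest_ever\n")
        for it, mf in enumerate(state.mfmax_trace):
            best = max(best, mf)
            fh.write(f"{it}\t{mf:.6f}\t{best:.6f}\n")


def checkpoint(state: GAState, path) -> None:
    """Serialize a GAState (population, fitness, best) for later restart.

    The RNG stream is snapshotted too, so a restored run continues the
    same realization.
    """
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(
            {
                "population": state.population,
                "fitness": state.fitness,
                "p2": state.p2,
                "best_matrix": state.best_matrix,
                "best_fitness": state.best_fitness,
                "iteration": state.iteration,
                "stagnant": state.stagnant,
                "mfmax_trace": state.mfmax_trace,
                "rng_state": state.rng.bit_generator.state,
            },
            fh,
        )


def restore(path) -> GAState:
    """Load a GAState written by :func:`checkpoint`."""
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    rng = np.random.default_rng()
    rng.bit_generator.state = payload.pop("rng_state")
    return GAState(rng=rng, **payload)


def optimize(seq: CodingSequence, config: GAConfig, d: float):
    """Run the GA to stagnation; returns (W1, AlignmentResult, GAState).

    W1 is the best-ever normalized matrix; the alignment is its full
    traceback against ``seq``.
    """
    state = init_population(seq, config, d)
    while state.stagnant < config.stagnation_window and state.iteration < config.max_iterations:
        ga_step(state, seq, config, d)
    w1 = NormalizedWeightMatrix(
        weights=state.best_matrix, p2=state.p2, r0=config.r0, k0=config.k0
    )
    alignment = global_align(seq, w1, derive_skip_matrices(w1), d, config.h)
    return w1, alignment, state
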