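"""Genetic search for the single highest-scoring module.

The search space — all subsets of the phenotype columns — is far too
large to enumerate, so a genetic algorithm with *offspring selection* is
used.  An individual is a binary membership vector over the ``m``
columns; its fitness is the entropy-based module score evaluated on the
current weight matrix.  Parents are drawn by linear-ranking selection,
recombined by single-point crossover and mutated; a child is *successful*
if it outperforms at least one of its parents, and each new generation
must fill a ``success_ratio`` share of its slots with successful
children.  The search stops when the best fitness has stagnated for a
fixed number of generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    GAParams,
    Module,
    ParameterError,
    WeightMatrix,
    module_score,
    module_scores_batch,
    weighted_module_score,
)

__all__ = [
    "Population",
    "initialize_population",
    "ranking_probabilities",
    "linear_ranking_select",
    "crossover_single_point",
    "mutate_bitflip",
    "evolve_module",
]

# Cap on child evaluations per generation while hunting for successful
# offspring; stands in for the maximum-selection-pressure bound of the
# self-adaptive operator and guarantees termination.
ATTEMPT_FACTOR = 10


@dataclass
class Population:
    """Fixed-size population of column-membership vectors."""

    individuals: np.ndarray  # (P, m) uint8
    fitness: np.ndarray  # (P,)
    generation: int = 0
    best_fitness_history: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.individuals.shape[0]


def initialize_population(m: int, pop_size: int, rng: np.random.Generator) -> Population:
    """Each individual starts as two distinct uniformly chosen phenotypes."""
    if m < 2:
        raise ParameterError(f"need at least 2 phenotypes, got {m}")
    if pop_size < 2:
        raise ParameterError("pop_size must be >= 2")
    members = np.zeros((pop_size, m), dtype=np.uint8)
    for i in range(pop_size):
        cols = rng.choice(m, size=2, replace=False)
        members[i, cols] = 1
    return Population(individuals=members, fitness=np.zeros(pop_size))


def ranking_probabilities(fitness: np.ndarray, selection_pressure: float) -> np.ndarray:
    """Linear-ranking selection probabilities, aligned with ``fitness``.

    With ranks r = 1 (worst) .. P (best), the rank-r individual is drawn
    with probability (1/P) * [(2-SP) + 2(SP-1)(r-1)/(P-1)].  SP=1 is
    uniform; SP=2 is maximal pressure.  Ties in fitness are ranked in
    stable index order.
    """
    if not 1.0 <= selection_pressure <= 2.0:
        raise ParameterError(
            f"selection_pressure must be in [1, 2], got {selection_pressure}"
        )
    fitness = np.asarray(fitness, dtype=np.float64)
    P = fitness.size
    if P < 2:
        return np.ones(P)
    order = np.argsort(fitness, kind="stable")  # worst first; ties by index
    ranks = np.empty(P, dtype=np.float64)
    ranks[order] = np.arange(1, P + 1)
    sp = selection_pressure
    probs = ((2.0 - sp) + 2.0 * (sp - 1.0) * (ranks - 1.0) / (P - 1.0)) / P
    return probs


def linear_ranking_select(
    fitness: np.ndarray,
    selection_pressure: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw parent indices (with replacement) by linear-ranking selection."""
    probs = ranking_probabilities(fitness, selection_pressure)
    idx = rng.choice(probs.size, size=size if size is not None else 1, p=probs)
    return int(idx[0]) if size is None else idx


def crossover_single_point(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Child = a[:c] ++ b[c:] for a uniform cut point c in {1, .., m-1}."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    m = a.size
    c = int(rng.integers(1, m))
    return np.concatenate([a[:c], b[c:]]).astype(a.dtype)


def mutate_bitflip(ind: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ParameterError("mutation rate must be a probability")
    ind = np.asarray(ind)
    flips = rng.random(ind.size) < rate
    return (ind.astype(np.uint8) ^ flips.astype(np.uint8)).astype(ind.dtype)


def _crossover_batch(A: np.ndarray, B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m = A.shape[1]
    cuts = rng.integers(1, m, size=A.shape[0])
    idx = np.arange(m)
    return np.where(idx[None, :] < cuts[:, None], A, B)


def _mutate_batch(children: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    # Offspring-selection convention: with probability `rate` a child is
    # mutated by flipping one uniformly chosen bit.
    mutate = rng.random(children.shape[0]) < rate
    if mutate.any():
        rows = np.flatnonzero(mutate)
        bits = rng.integers(0, children.shape[1], size=rows.size)
        children[rows, bits] ^= 1
    return children


class _FitnessCache:
    """Memo for module fitness keyed by the packed membership bitset."""

    def __init__(self, W32: np.ndarray, alpha: float):
        self._W = W32
        self._alpha = alpha
        self._memo: dict[bytes, float] = {}

    def __call__(self, members: np.ndarray) -> np.ndarray:
        packed = np.packbits(members, axis=1)
        keys = [row.tobytes() for row in packed]
        out = np.empty(members.shape[0], dtype=np.float64)
        miss = [i for i, key in enumerate(keys) if key not in self._memo]
        if miss:
            vals = module_scores_batch(self._W, members[miss], self._alpha)
            for j, i in enumerate(miss):
                self._memo[keys[i]] = float(vals[j])
        for i, key in enumerate(keys):
            out[i] = self._memo[key]
        return out


def evolve_module(
    weights: WeightMatrix,
    params: GAParams,
    rng: np.random.Generator,
    return_population: bool = False,
):
    """Run the GA on the current weight matrix and return the best module.

    The incumbent best individual is always carried forward (elitism), so
    the best-fitness trajectory is non-decreasing; the run terminates
    once it is unchanged for ``params.stagnation`` consecutive
    generations.  On an all-zero matrix the returned module has score 0.
    With ``return_population`` the final population (including the
    best-fitness history) is returned alongside the module.
    """
    W = weights.values
    n, m = W.shape
    P = params.pop_size
    evaluate = _FitnessCache(W, params.alpha)

    pop = initialize_population(m, P, rng)
    pop.fitness = evaluate(pop.individuals)

    best_idx = int(np.argmax(pop.fitness))
    best = pop.individuals[best_idx].copy()
    best_fit = float(pop.fitness[best_idx])
    pop.best_fitness_history.append(best_fit)

    target = max(1, int(round(params.success_ratio * P)))
    cap = ATTEMPT_FACTOR * P
    stagnant = 0

    while stagnant < params.stagnation:
        succ: list[np.ndarray] = []
        succ_fit: list[float] = []
        fail: list[np.ndarray] = []
        fail_fit: list[float] = []
        attempts = 0
        while len(succ) < target and attempts < cap:
            batch = min(P, cap - attempts)
            p1 = linear_ranking_select(pop.fitness, params.selection_pressure, rng, size=batch)
            p2 = linear_ranking_select(pop.fitness, params.selection_pressure, rng, size=batch)
            children = _crossover_batch(pop.individuals[p1], pop.individuals[p2], rng)
            children = _mutate_batch(children, params.mutation_rate, rng)
            child_fit = evaluate(children)
            parent_min = np.minimum(pop.fitness[p1], pop.fitness[p2])
            ok = child_fit > parent_min
            for i in np.flatnonzero(ok):
                succ.append(children[i])
                succ_fit.append(float(child_fit[i]))
            for i in np.flatnonzero(~ok):
                fail.append(children[i])
                fail_fit.append(float(child_fit[i]))
            attempts += batch

        # next generation: elite + successful children + best unsuccessful fill
        new_members = [best]
        new_fitness = [best_fit]
        take = min(len(succ), target, P - 1)
        new_members.extend(succ[:take])
        new_fitness.extend(succ_fit[:take])
        need = P - len(new_members)
        if need > 0 and fail:
            # fill with a random draw of the unsuccessful children: keeps
            # population diversity, which single-point crossover needs to
            # jump the multi-column barriers between partial-width optima
            order = rng.permutation(len(fail))[:need]
            new_members.extend(fail[i] for i in order)
            new_fitness.extend(fail_fit[i] for i in order)
        while len(new_members) < P:  # degenerate: not enough children at all
            new_members.append(best)
            new_fitness.append(best_fit)
        pop.individuals = np.array(new_members, dtype=np.uint8)
        pop.fitness = np.array(new_fitness, dtype=np.float64)
        pop.generation += 1

        gen_best = int(np.argmax(pop.fitness))
        if pop.fitness[gen_best] > best_fit:
            best_fit = float(pop.fitness[gen_best])
            best = pop.individuals[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        pop.best_fitness_history.append(best_fit)

    columns = np.flatnonzero(best)
    if columns.size < 2 or best_fit <= 0.0:
        module = Module(
            columns=columns,
            geneset_scores=np.zeros(n),
            geneset_members=np.zeros(n, dtype=bool),
            score=0.0,
            weighted_score=float("-inf"),
        )
    else:
        score, per_row = module_score(weights, columns, params.alpha)
        module = Module(
            columns=columns,
            geneset_scores=per_row,
            geneset_members=per_row > 0,
            score=score,
            weighted_score=weighted_module_score(score, columns.size, m),
        )
    return (module, pop) if return_population else module
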