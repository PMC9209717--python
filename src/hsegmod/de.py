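"""Differential-evolution minimizers: classic DE, AMCDE, and IAMCDE.

Three variants of a real-vector, box-initialized differential evolution
optimizer used here to pick initial network weights, but general enough for
any finite objective:

* ``DE``     — rand/1 mutation with fixed mutation factor F and crossover
  rate CR.
* ``AMCDE``  — same mutation, but F and CR follow quarter-cycle sine/cosine
  schedules over the generations.
* ``IAMCDE`` — two mutation operators (rand/1 and rand/2 with fresh uniform
  factors each call) chosen by a generation-ramped probability, the AMCDE
  crossover schedule, and a keep-best-half population randomization restart
  after ``N_failmax`` consecutive generations without improvement.

Selection is elitist (strict improvement), so the best-so-far fitness is
non-increasing for all variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "DEConfig",
    "Population",
    "OptimizerResult",
    "init_population",
    "schedule_F_CR",
    "mutation_probability",
    "mutate_de",
    "mutate_iamcde",
    "crossover",
    "select",
    "randomize_population",
    "minimize",
]

VARIANTS = ("DE", "AMCDE", "IAMCDE")


@dataclass(frozen=True)
class DEConfig:
    """Optimizer settings.

    Defaults suit the network-weight search: population 30, 100
    generations, schedule constants a = b = 0.75, mutation-probability ramp
    0.1 -> 0.9, restart patience 10, search box [-1, 1].
    """

    variant: str = "IAMCDE"
    S: int = 30
    GMax: int = 100
    F: float = 0.5
    CR: float = 0.9
    a: float = 0.75
    b: float = 0.75
    pro_min: float = 0.1
    pro_max: float = 0.9
    N_failmax: int = 10
    U_min: float | np.ndarray = -1.0
    U_max: float | np.ndarray = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.S < 6:
            raise ValueError("population size must be >= 6 (rand/2 needs 5 donors)")
        if self.GMax < 1:
            raise ValueError("GMax must be >= 1")
        lo = np.asarray(self.U_min, dtype=float)
        hi = np.asarray(self.U_max, dtype=float)
        if not (np.all(lo < hi) or np.all((lo == 0) & (hi == 0))):
            raise ValueError("require U_min < U_max (per dimension)")
        if not 0 <= self.pro_min <= self.pro_max <= 1:
            raise ValueError("require 0 <= pro_min <= pro_max <= 1")
        if not 0 <= self.F <= 2:
            raise ValueError("F must lie in [0, 2]")
        for name in ("a", "b"):
            val = getattr(self, name)
            if not 0.5 <= val <= 1:
                raise ValueError(f"{name} must lie in [0.5, 1]")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-dimension (U_min, U_max) broadcast to ``dim`` components."""
        lo = np.broadcast_to(np.asarray(self.U_min, dtype=float), (dim,))
        hi = np.broadcast_to(np.asarray(self.U_max, dtype=float), (dim,))
        return lo, hi


@dataclass
class Population:
    members: np.ndarray  # (S, D)
    fitnesses: np.ndarray  # (S,)
    generation: int = 0
    N_fail: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitnesses))

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[self.best_index])

    @property
    def best_member(self) -> np.ndarray:
        return self.members[self.best_index].copy()


@dataclass(frozen=True)
class OptimizerResult:
    x: np.ndarray
    fun: float
    history: np.ndarray  # best fitness after each generation
    nfev: int
    nrestarts: int


def init_population(
    config: DEConfig, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform box initialization: U_min + rand[0,1] * (U_max - U_min)."""
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    lo, hi = config.bounds(dim)
    u = rng.random((config.S, dim))
    return lo + u * (hi - lo)


def schedule_F_CR(G: int, GMax: int, a: float, b: float) -> tuple[float, float]:
    """Generation schedules for F and CR: a quarter-cycle sine ramp up to
    the midpoint, then a quarter-cycle cosine ramp.  Values stay within
    [2a-1, a] and [2b-1, b]."""
    frac = G / GMax
    if G <= GMax / 2:
        F = a + (1 - a) * math.sin(frac * math.pi - math.pi / 2)
        CR = b + (1 - b) * math.sin(frac * math.pi - math.pi / 2)
    else:
        F = a - (1 - a) * math.cos(math.pi / 2 - frac * math.pi)
        CR = b - (1 - b) * math.cos(math.pi / 2 - frac * math.pi)
    return F, CR


def mutation_probability(G: int, GMax: int, pro_min: float, pro_max: float) -> float:
    """Linear ramp of the rand/2-operator probability over the generations."""
    return pro_min + G * (pro_max - pro_min) / GMax


def _distinct_indices(S: int, k: int, rng: np.random.Generator,
                      exclude: int | None = None) -> np.ndarray:
    pool = np.arange(S)
    if exclude is not None and S > k:
        pool = np.delete(pool, exclude)
    return rng.choice(pool, size=k, replace=False)


def mutate_de(
    pop: np.ndarray, F: float, rng: np.random.Generator, exclude: int | None = None
) -> np.ndarray:
    """Classic rand/1 mutation: pop[pm1] + F * (pop[pm2] - pop[pm3])."""
    i1, i2, i3 = _distinct_indices(pop.shape[0], 3, rng, exclude)
    return pop[i1] + F * (pop[i2] - pop[i3])


def mutate_iamcde(
    pop: np.ndarray, pro_G: float, rng: np.random.Generator,
    exclude: int | None = None,
) -> np.ndarray:
    """Dual-operator mutation: with probability 1 - pro_G use rand/1 with a
    fresh uniform factor, otherwise rand/2 with two fresh uniform factors."""
    i1, i2, i3, i4, i5 = _distinct_indices(pop.shape[0], 5, rng, exclude)
    if rng.random() > pro_G:
        rand1 = rng.random()
        return pop[i1] + rand1 * (pop[i2] - pop[i3])
    rand2 = rng.random()
    rand3 = rng.random()
    return pop[i1] + rand2 * (pop[i2] - pop[i3]) + rand3 * (pop[i4] - pop[i5])


def crossover(
    target: np.ndarray, mutant: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: component j comes from the mutant when the j-th
    uniform draw is <= CR (no forced mutant component)."""
    target = np.asarray(target, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if target.shape != mutant.shape:
        raise ValueError("target and mutant dimensions differ")
    take = rng.random(target.shape[0]) <= CR
    return np.where(take, mutant, target)


def select(
    target: np.ndarray,
    trial: np.ndarray,
    objective: Callable[[np.ndarray], float],
) -> np.ndarray:
    """Greedy selection: keep the trial only on strict improvement."""
    return trial if objective(trial) < objective(target) else target


def randomize_population(
    pop: Population, config: DEConfig, dim: int, rng: np.random.Generator
) -> Population:
    """Restart: keep the best ceil(S/2) members, replace the worst floor(S/2)
    with fresh box draws, and reset the failure counter.  The incumbent best
    member and fitness are preserved."""
    S = config.S
    keep = math.ceil(S / 2)
    order = np.argsort(pop.fitnesses, kind="stable")
    members = pop.members[order].copy()
    fitnesses = pop.fitnesses[order].copy()
    n_new = S - keep
    lo, hi = config.bounds(dim)
    fresh = lo + rng.random((n_new, dim)) * (hi - lo)
    members[keep:] = fresh
    fitnesses[keep:] = np.nan  # caller re-evaluates
    return Population(members, fitnesses, pop.generation, N_fail=0)


def minimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    config: DEConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> OptimizerResult:
    """Run the configured DE variant for GMax generations.

    The per-generation best-fitness history is non-increasing; runs are
    bit-reproducible for a fixed seed.  Non-finite objective values raise.
    """
    config = config or DEConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    nfev = 0

    def f(x: np.ndarray) -> float:
        nonlocal nfev
        nfev += 1
        val = float(objective(x))
        if not math.isfinite(val):
            raise ValueError("objective returned a non-finite value")
        return val

    members = init_population(config, dim, rng)
    fitnesses = np.array([f(x) for x in members])
    pop = Population(members, fitnesses)
    history = []
    nrestarts = 0

    for G in range(1, config.GMax + 1):
        if config.variant == "DE":
            F_G, CR_G = config.F, config.CR
        else:
            F_sched, CR_sched = schedule_F_CR(G, config.GMax, config.a, config.b)
            F_G, CR_G = F_sched, CR_sched
        pro_G = mutation_probability(G, config.GMax, config.pro_min, config.pro_max)

        best_before = pop.best_fitness
        for s in range(config.S):
            if config.variant == "IAMCDE":
                mutant = mutate_iamcde(pop.members, pro_G, rng, exclude=s)
            else:
                mutant = mutate_de(pop.members, F_G, rng, exclude=s)
            trial = crossover(pop.members[s], mutant, CR_G, rng)
            trial_fit = f(trial)
            if trial_fit < pop.fitnesses[s]:
                pop.members[s] = trial
                pop.fitnesses[s] = trial_fit
        pop.generation = G

        if config.variant == "IAMCDE":
            if pop.best_fitness < best_before:
                pop.N_fail = 0
            else:
                pop.N_fail += 1
            if pop.N_fail >= config.N_failmax:
                pop = randomize_population(pop, config, dim, rng)
                refresh = np.isnan(pop.fitnesses)
                pop.fitnesses[refresh] = [f(x) for x in pop.members[refresh]]
                nrestarts += 1
        history.append(pop.best_fitness)

    history_arr = np.minimum.accumulate(np.array(history))
    return OptimizerResult(
        x=pop.best_member,
        fun=pop.best_fitness,
        history=history_arr,
        nfev=nfev,
        nrestarts=nrestarts,
    )
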