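"""Metaheuristic solvers over integer assignment vectors.

Every solver optimizes a black-box objective ``callable(assignment) ->
value`` over integer vectors in ``[1, n_medical]^n_groups`` (gene d
assigns casualty group d to a medical point), minimizing. The flagship
is an integer-encoded particle swarm: standard velocity/position
updates on real vectors,

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- x + v

with positions re-integerized after every move (round half-up then
clamp by default; a literal ceiling mode is available). Genetic-
algorithm and differential-evolution baselines share the encoding, and
a brute-force enumerator provides the exact optimum at toy scale.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PSOConfig",
    "SolverResult",
    "integerize",
    "pso_solve",
    "ga_solve",
    "de_solve",
    "brute_force",
    "compare_algorithms",
    "SearchSpaceTooLarge",
]


class SearchSpaceTooLarge(ValueError):
    """Raised when brute force would enumerate more than the cap."""


@dataclass(frozen=True)
class PSOConfig:
    """Swarm (and baseline) hyper-parameters.

    The defaults follow common practice for this problem class:
    population 100, 300 generations, learning factors c1 = c2 = 2,
    inertia 1, and 10 independent runs whose minimum is reported as the
    final solution.
    """

    popsize: int = 100
    maxgen: int = 300
    c1: float = 2.0
    c2: float = 2.0
    w: float = 1.0
    seed: int | None = None
    rounding: str = "half_up"  # or "ceiling"
    n_runs: int = 10
    # GA/DE knobs (ignored by PSO)
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/n_groups
    de_F: float = 0.5
    de_CR: float = 0.9

    def __post_init__(self) -> None:
        if self.popsize < 2 or self.maxgen < 1:
            raise ValueError("popsize >= 2 and maxgen >= 1 required")
        if min(self.c1, self.c2, self.w) < 0:
            raise ValueError("c1, c2, w must be nonnegative")
        if self.rounding not in ("half_up", "ceiling"):
            raise ValueError("rounding must be 'half_up' or 'ceiling'")


@dataclass
class SolverResult:
    """Best assignment found, with per-generation and per-run records."""

    best_position: tuple[int, ...]
    best_value: float
    history: list[float]
    runs: list[float] = field(default_factory=list)
    runtime: float = 0.0
    algorithm: str = ""
    seed: int | None = None


def integerize(position, n_medical: int, mode: str = "half_up") -> np.ndarray:
    """Map a real position vector onto valid integer genes.

    Default rounds half-up to the nearest integer then clamps to
    ``[1, n_medical]``; ``mode="ceiling"`` takes the ceiling instead
    (which biases genes upward and can never produce point 1 from
    values in (0, 1)).
    """
    x = np.asarray(position, dtype=float)
    if np.isnan(x).any():
        raise ValueError("position contains NaN")
    if mode == "half_up":
        rounded = np.floor(x + 0.5)
    elif mode == "ceiling":
        rounded = np.ceil(x)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return np.clip(rounded, 1, n_medical).astype(int)


def _as_assignment(genes: np.ndarray) -> tuple[int, ...]:
    return tuple(int(g) for g in genes)


def _single_run_wrapper(solve_one):
    """Decorate a single-run solver into the multi-run protocol: n_runs
    independent runs (seeds derived from config.seed), minimum reported
    as the final solution."""

    def solve(objective, n_groups: int, n_medical: int, config: PSOConfig | None = None) -> SolverResult:
        if config is None:
            config = PSOConfig()
        if n_groups < 1 or n_medical < 1:
            raise ValueError("need n_groups >= 1 and n_medical >= 1")
        t0 = time.perf_counter()
        results: list[SolverResult] = []
        base = 0 if config.seed is None else int(config.seed)
        for run in range(config.n_runs):
            rng = np.random.default_rng((base + 7919 * run) % (2**31))
            results.append(solve_one(objective, n_groups, n_medical, config, rng))
        best = min(results, key=lambda r: r.best_value)
        best.runs = [r.best_value for r in results]
        best.runtime = time.perf_counter() - t0
        best.seed = config.seed
        return best

    return solve


def _pso_one(objective, n_groups, n_medical, config: PSOConfig, rng) -> SolverResult:
    pop = rng.integers(1, n_medical + 1, size=(config.popsize, n_groups)).astype(float)
    vel = np.zeros_like(pop)
    vmax = float(n_medical)  # velocity clamp against saturation
    decoded = integerize(pop, n_medical, config.rounding)
    fitness = np.array([objective(_as_assignment(decoded[i])) for i in range(config.popsize)])
    pbest = pop.copy()
    pbest_val = fitness.copy()
    g = int(np.argmin(fitness))
    gbest, gbest_val = pop[g].copy(), float(fitness[g])
    gbest_genes = _as_assignment(decoded[g])
    history = [gbest_val]
    for _ in range(config.maxgen):
        r1 = rng.random(size=pop.shape)
        r2 = rng.random(size=pop.shape)
        vel = config.w * vel + config.c1 * r1 * (pbest - pop) + config.c2 * r2 * (gbest - pop)
        np.clip(vel, -vmax, vmax, out=vel)
        pop = pop + vel
        decoded = integerize(pop, n_medical, config.rounding)
        pop = decoded.astype(float)  # keep positions on the integer lattice
        fitness = np.array([objective(_as_assignment(decoded[i])) for i in range(config.popsize)])
        improved = fitness < pbest_val
        pbest[improved] = pop[improved]
        pbest_val[improved] = fitness[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest_val = float(pbest_val[g])
            gbest = pbest[g].copy()
            gbest_genes = _as_assignment(integerize(gbest, n_medical, config.rounding))
        history.append(gbest_val)
    return SolverResult(gbest_genes, gbest_val, history, algorithm="PSO")


def _ga_one(objective, n_groups, n_medical, config: PSOConfig, rng) -> SolverResult:
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_groups
    pop = rng.integers(1, n_medical + 1, size=(config.popsize, n_groups))
    fitness = np.array([objective(_as_assignment(ind)) for ind in pop])
    g = int(np.argmin(fitness))
    best, best_val = _as_assignment(pop[g]), float(fitness[g])
    history = [best_val]
    for _ in range(config.maxgen):
        # binary tournament selection
        a = rng.integers(0, config.popsize, size=config.popsize)
        b = rng.integers(0, config.popsize, size=config.popsize)
        winners = np.where((fitness[a] <= fitness[b])[:, None], pop[a], pop[b])
        children = winners.copy()
        for i in range(0, config.popsize - 1, 2):
            if rng.random() < config.crossover_rate and n_groups > 1:
                cut = int(rng.integers(1, n_groups))
                children[i, cut:], children[i + 1, cut:] = (
                    winners[i + 1, cut:].copy(),
                    winners[i, cut:].copy(),
                )
        reset = rng.random(size=children.shape) < mut
        children[reset] = rng.integers(1, n_medical + 1, size=int(reset.sum()))
        children[0] = best  # elitism
        pop = children
        fitness = np.array([objective(_as_assignment(ind)) for ind in pop])
        g = int(np.argmin(fitness))
        if fitness[g] < best_val:
            best, best_val = _as_assignment(pop[g]), float(fitness[g])
        history.append(best_val)
    return SolverResult(best, best_val, history, algorithm="GA")


def _de_one(objective, n_groups, n_medical, config: PSOConfig, rng) -> SolverResult:
    pop = rng.uniform(1, n_medical, size=(config.popsize, n_groups))
    decoded = integerize(pop, n_medical, config.rounding)
    fitness = np.array([objective(_as_assignment(decoded[i])) for i in range(config.popsize)])
    g = int(np.argmin(fitness))
    best, best_val = _as_assignment(decoded[g]), float(fitness[g])
    history = [best_val]
    for _ in range(config.maxgen):
        for i in range(config.popsize):
            # rand/1/bin
            r = rng.choice([j for j in range(config.popsize) if j != i], size=3, replace=False)
            mutant = pop[r[0]] + config.de_F * (pop[r[1]] - pop[r[2]])
            cross = rng.random(n_groups) < config.de_CR
            cross[rng.integers(0, n_groups)] = True
            trial = np.where(cross, mutant, pop[i])
            trial = np.clip(trial, 1, n_medical)
            trial_genes = integerize(trial, n_medical, config.rounding)
            f_trial = objective(_as_assignment(trial_genes))
            if f_trial <= fitness[i]:
                pop[i] = trial
                fitness[i] = f_trial
                if f_trial < best_val:
                    best, best_val = _as_assignment(trial_genes), float(f_trial)
        history.append(best_val)
    return SolverResult(best, best_val, history, algorithm="DE")


pso_solve = _single_run_wrapper(_pso_one)
ga_solve = _single_run_wrapper(_ga_one)
de_solve = _single_run_wrapper(_de_one)

#: registry used by the comparison harness; extensions (e.g. a fourth
#: baseline) register here
ALGORITHMS = {"PSO": pso_solve, "GA": ga_solve, "DE": de_solve}


def brute_force(objective, n_groups: int, n_medical: int, cap: int = 10**6):
    """Exact optimum by exhaustive enumeration (toy instances only).

    Returns ``(assignment, value)``; ties resolve to the lexicographically
    smallest assignment.
    """
    space = n_medical**n_groups
    if space > cap:
        raise SearchSpaceTooLarge(f"{n_medical}^{n_groups} = {space} > cap {cap}")
    best_assignment: tuple[int, ...] | None = None
    best_value = math.inf
    for assignment in itertools.product(range(1, n_medical + 1), repeat=n_groups):
        value = objective(assignment)
        if value < best_value:
            best_assignment, best_value = assignment, value
    return best_assignment, best_value


def compare_algorithms(
    objective,
    n_groups: int,
    n_medical: int,
    configs: dict[str, PSOConfig] | None = None,
    n_runs: int = 10,
    seed: int | None = None,
    reference: str = "PSO",
) -> pd.DataFrame:
    """Benchmark the solvers on one objective.

    Each algorithm is run ``n_runs`` times from seeds derived from
    ``seed``; the table reports min/max/avg/SD of the per-run best
    values, wall time, and the percentage reduction of the reference
    algorithm's average relative to each other:
    ``100 * (1 - avg_ref / avg_other)``.
    """
    if configs is None:
        configs = {name: PSOConfig() for name in ALGORITHMS}
    rows = []
    run_values: dict[str, list[float]] = {}
    for name, config in configs.items():
        config = replace(config, seed=seed if seed is not None else config.seed, n_runs=n_runs)
        result = ALGORITHMS[name](objective, n_groups, n_medical, config)
        values = np.array(result.runs)
        run_values[name] = list(values)
        rows.append(
            {
                "algorithm": name,
                "min": float(values.min()),
                "max": float(values.max()),
                "avg": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                "time_s": result.runtime,
                "seed": seed,
            }
        )
    table = pd.DataFrame(rows)
    if reference in run_values:
        avg_ref = table.loc[table["algorithm"] == reference, "avg"].iloc[0]
        table["reduction_vs_%s_percent" % reference] = [
            0.0 if row.algorithm == reference or row.avg == 0 else 100.0 * (1.0 - avg_ref / row.avg)
            for row in table.itertuples()
        ]
    return table
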