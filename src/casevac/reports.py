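"""Report builders: scheme comparison, budget sensitivity, solver benchmark.

These functions reproduce the standard experiment tables for this
problem class at whatever scale the supplied instance has:

* *scheme comparison* — a failure-aware plan (optimized against the
  worst case over, or the mean of, the failure scenarios) against a
  failure-blind plan (optimized on the no-failure scenario only),
  both re-evaluated under every scenario with backup reassignment;
* *budget sensitivity* — a fresh solve of the robust objective per
  uncertainty budget, with the percentage gap to the nominal model;
* *algorithm comparison* — the PSO/GA/DE benchmark over a grid of
  generated instance sizes, with per-run values for box plots.

All outputs are plain DataFrames (CSV-ready) and fully determined by
the seeds they are given.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .evaluator import evaluate_under_all_scenarios, expand_groups
from .injury import DeathModel
from .network import Instance
from .robust import gamma_sensitivity, robust_objective
from .solvers import ALGORITHMS, PSOConfig, pso_solve
from .synth import GeneratorSpec, generate

__all__ = [
    "gap_percent",
    "SchemeComparison",
    "run_scheme_comparison",
    "run_gamma_sensitivity",
    "run_algorithm_comparison",
]


def gap_percent(z_new: float, z_ref: float) -> float:
    """Relative objective gap ``100 * (z_new - z_ref) / z_ref`` in
    percent, rounded half-up to two decimals."""
    if z_ref <= 0:
        raise ValueError("reference objective must be positive")
    raw = 100.0 * (z_new - z_ref) / z_ref
    return float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SchemeComparison:
    """Per-scenario objectives of the two planning schemes."""

    table: pd.DataFrame  # rows: scheme 1, scheme 2, gap%
    scheme1_assignment: tuple[int, ...]
    scheme2_assignment: tuple[int, ...]


def run_scheme_comparison(
    instance: Instance,
    config: PSOConfig | None = None,
    death_model: DeathModel | None = None,
    *,
    aggregate: str = "worst",
    solver=pso_solve,
) -> SchemeComparison:
    """Failure-aware vs. failure-blind planning.

    Scheme 1 optimizes the worst case (or, with ``aggregate="mean"``,
    the scenario mean) of the expected-death objective over all failure
    scenarios. Scheme 2 optimizes the no-failure scenario only. Both
    plans are then re-evaluated under every scenario (failed facilities
    redirect to the nearest open backup), and the gap row reports how
    much worse the failure-blind plan is, per scenario.
    """
    if config is None:
        config = PSOConfig()
    if len(instance.scenarios) < 2:
        raise ValueError("scheme comparison needs at least two scenarios")
    groups = expand_groups(instance)
    n, k = len(groups), len(instance.medical)
    medical_ids = sorted(m.id for m in instance.medical)

    def decode(assignment):
        return tuple(medical_ids[g - 1] for g in assignment)

    def aware(assignment) -> float:
        sweep = evaluate_under_all_scenarios(decode(assignment), instance, death_model, groups=groups)
        return sweep.worst_case if aggregate == "worst" else sweep.mean

    no_failure = instance.scenarios[0]

    def blind(assignment) -> float:
        from .evaluator import evaluate

        return evaluate(decode(assignment), instance, no_failure, death_model, groups=groups).objective

    res1 = solver(aware, n, k, config)
    res2 = solver(blind, n, k, config)
    a1, a2 = decode(res1.best_position), decode(res2.best_position)
    sweep1 = evaluate_under_all_scenarios(a1, instance, death_model, groups=groups)
    sweep2 = evaluate_under_all_scenarios(a2, instance, death_model, groups=groups)
    scenarios = sorted(sweep1.per_scenario)
    table = pd.DataFrame(
        {
            "scenario": scenarios,
            "scheme1_objective": [sweep1.per_scenario[s] for s in scenarios],
            "scheme2_objective": [sweep2.per_scenario[s] for s in scenarios],
        }
    )
    table["gap_percent"] = [
        gap_percent(z2, z1)
        for z1, z2 in zip(table["scheme1_objective"], table["scheme2_objective"])
    ]
    return SchemeComparison(table=table, scheme1_assignment=a1, scheme2_assignment=a2)


def run_gamma_sensitivity(
    instance: Instance,
    budgets,
    config: PSOConfig | None = None,
    death_model: DeathModel | None = None,
    *,
    solver=pso_solve,
    **robust_kwargs,
) -> pd.DataFrame:
    """Budget-sensitivity table with a fresh solve per budget."""
    if config is None:
        config = PSOConfig()
    groups = expand_groups(instance)
    n, k = len(groups), len(instance.medical)
    medical_ids = sorted(m.id for m in instance.medical)

    def solve(objective) -> float:
        def wrapped(assignment):
            return objective(tuple(medical_ids[g - 1] for g in assignment))

        return solver(wrapped, n, k, config).best_value

    table = gamma_sensitivity(solve, instance, budgets, death_model, groups=groups, **robust_kwargs)
    table["seed"] = config.seed
    return table


def run_algorithm_comparison(
    sizes=((9, 7),),
    configs: dict[str, PSOConfig] | None = None,
    n_runs: int = 10,
    seed: int | None = None,
    death_model: DeathModel | None = None,
    spec: GeneratorSpec | None = None,
    instance: Instance | None = None,
    reference: str = "PSO",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Solver benchmark across a grid of generated instance sizes.

    Each ``(n_affected, n_medical)`` size draws one instance (seeded
    from ``seed``), whose nominal no-failure objective all algorithms
    minimize. Passing ``instance`` benchmarks that single instance
    instead. Returns the statistics table and the per-run values
    (box-plot data).
    """
    rows = []
    box_rows = []
    grid: list[tuple[str, Instance]] = []
    if instance is not None:
        grid.append((f"{len(instance.affected)}*{len(instance.medical)}", instance))
    else:
        base = spec if spec is not None else GeneratorSpec()
        for idx, (n_a, n_m) in enumerate(sizes):
            inst_seed = None if seed is None else (seed + 1009 * idx) % (2**31)
            drawn = generate(replace(base, n_affected=n_a, n_medical=n_m, seed=inst_seed))
            grid.append((f"{n_a}*{n_m}", drawn))
    cfgs = configs if configs is not None else {name: PSOConfig() for name in ALGORITHMS}
    for label, inst in grid:
        groups = expand_groups(inst)
        medical_ids = sorted(m.id for m in inst.medical)
        scenario = inst.scenarios[0]

        def objective(assignment, _inst=inst, _groups=groups, _ids=medical_ids, _s=scenario):
            from .evaluator import evaluate

            decoded = tuple(_ids[g - 1] for g in assignment)
            return evaluate(decoded, _inst, _s, death_model, groups=_groups).objective

        stats = []
        for name, cfg in cfgs.items():
            cfg = replace(cfg, seed=seed if seed is not None else cfg.seed, n_runs=n_runs)
            result = ALGORITHMS[name](objective, len(groups), len(medical_ids), cfg)
            values = pd.Series(result.runs, dtype=float)
            stats.append(
                {
                    "nodes": label,
                    "algorithm": name,
                    "min": values.min(),
                    "max": values.max(),
                    "avg": values.mean(),
                    "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
                    "time_s": result.runtime,
                    "seed": seed,
                }
            )
            for run, value in enumerate(result.runs):
                box_rows.append({"nodes": label, "algorithm": name, "run": run, "value": value})
        table = pd.DataFrame(stats)
        if reference in set(table["algorithm"]):
            avg_ref = table.loc[table["algorithm"] == reference, "avg"].iloc[0]
            table[f"reduction_vs_{reference}_percent"] = [
                0.0 if row.algorithm == reference or row.avg == 0 else 100.0 * (1.0 - avg_ref / row.avg)
                for row in table.itertuples()
            ]
        rows.append(table)
    return pd.concat(rows, ignore_index=True), pd.DataFrame(box_rows)
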