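"""Schedule evaluation: from an assignment to expected deaths.

An :class:`~casevac.network.Instance` is expanded into casualty groups
(one per affected point and live injury state by default). An
*assignment* maps each group to a medical point. Evaluation then

1. redirects groups whose assigned facility failed in the scenario to
   the nearest open backup,
2. allocates the global ambulance and helicopter pools to groups —
   severe groups first, then shortest trip time — one vehicle per group
   at a time, cycling until every group has one vehicle per required
   trip or the pool is exhausted,
3. dispatches each group in vehicle-capacity batches, the a-th arrival
   of a vehicle delivering its batch after ``(2a - 1)`` one-way trip
   times (the vehicle shuttles back and forth),
4. charges each arriving casualty its treatment cost against the
   medical point's resource stock, severe casualties first; casualties
   arriving after the stock is exhausted are unserved and counted as
   deaths (big-M waiting time),
5. sums ``batch_size * death_probability(state, wait)`` over all
   batches into the expected-death objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .injury import DeathModel, InjuryState, death_probability
from .network import (
    AMBULANCE,
    FailureScenario,
    Instance,
    Route,
    reassign_backup,
    transport_mode,
    travel_time,
)

__all__ = [
    "CasualtyGroup",
    "DispatchPlan",
    "EvaluationResult",
    "ScenarioSweep",
    "expand_groups",
    "dispatch_batches",
    "consume_resources",
    "evaluate",
    "evaluate_under_all_scenarios",
    "dispatch_table",
]

_STATE_PRIORITY = {InjuryState.R: 0, InjuryState.G: 1}  # severe first


@dataclass(frozen=True)
class CasualtyGroup:
    """A set of casualties at one affected point sharing one severity."""

    id: int
    affected_point: int
    state: InjuryState
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if InjuryState(self.state) is InjuryState.D:
            raise ValueError("dead casualties are not scheduled")


@dataclass
class DispatchPlan:
    """Per-group transport record produced by an evaluation."""

    group: CasualtyGroup
    medical_point: int
    reassigned_from: int | None
    mode: str
    trip_time: float
    batches: list[tuple[int, float]]  # (batch size, waiting time)
    unserved: int = 0

    @property
    def served(self) -> int:
        return sum(size for size, _ in self.batches)


@dataclass
class EvaluationResult:
    """Expected-death objective with its full dispatch breakdown."""

    objective: float
    plans: list[DispatchPlan]
    per_group: list[dict]
    resource_ledger: dict[int, list[tuple[float, float]]]
    feasible: bool
    unserved: int
    scenario_id: int

    @property
    def total_casualties(self) -> int:
        return sum(p.group.size for p in self.plans)

    @property
    def served(self) -> int:
        return self.total_casualties - self.unserved


@dataclass
class ScenarioSweep:
    """Objectives of one assignment across every failure scenario."""

    per_scenario: dict[int, float]
    results: dict[int, EvaluationResult]

    @property
    def worst_case(self) -> float:
        return max(self.per_scenario.values())

    @property
    def mean(self) -> float:
        return sum(self.per_scenario.values()) / len(self.per_scenario)


def expand_groups(instance: Instance) -> list[CasualtyGroup]:
    """One casualty group per (affected point, live state) with size > 0.

    Groups are ordered by affected point id with severe (R) before minor
    (G); their index in the list is the group id and the position in any
    assignment vector.
    """
    groups: list[CasualtyGroup] = []
    for point in sorted(instance.affected, key=lambda a: a.id):
        for state in (InjuryState.R, InjuryState.G):
            size = int(point.f.get(state.value, 0))
            if size > 0:
                groups.append(CasualtyGroup(len(groups), point.id, state, size))
    return groups


def dispatch_batches(
    size: int,
    vehicles_assigned: int,
    trip_time: float,
    capacity_per_trip: int,
    bigM: float = 1e6,
) -> list[tuple[int, float]]:
    """Split a group into vehicle loads and compute each load's wait.

    Vehicles shuttle between the affected point and the medical point;
    the a-th arrival of any one vehicle happens after ``(2a - 1)`` trip
    times (out, back, out ...). Loads are filled to capacity with the
    remainder on the last trip. With no vehicle every person waits big-M.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if capacity_per_trip < 1:
        raise ValueError("capacity must be >= 1")
    if trip_time <= 0:
        raise ValueError("trip time must be positive")
    if vehicles_assigned <= 0:
        return [(size, bigM)]
    n_trips = math.ceil(size / capacity_per_trip)
    batches: list[tuple[int, float]] = []
    remaining = size
    for trip in range(n_trips):
        load = min(capacity_per_trip, remaining)
        remaining -= load
        arrival_no = trip // vehicles_assigned + 1  # a-th arrival of its vehicle
        wait = min((2 * arrival_no - 1) * trip_time, bigM)
        batches.append((load, wait))
    return batches


def consume_resources(
    ledger: dict[int, float],
    medical_id: int,
    state: InjuryState,
    batches: list[tuple[int, float]],
    C: dict[str, float],
) -> tuple[list[tuple[int, float]], int, list[tuple[float, float]]]:
    """Charge arriving casualties against a medical point's stock.

    Each served casualty deducts its treatment cost ``C[state]`` at its
    arrival time; once the remaining stock cannot cover another
    casualty, the rest of the arrivals are unserved. Returns the served
    batches, the unserved head-count, and the (time, remaining-stock)
    trace. The ledger is updated in place and never goes negative.
    """
    cost = C[InjuryState(state).value]
    served: list[tuple[int, float]] = []
    trace: list[tuple[float, float]] = []
    unserved = 0
    for size, wait in batches:
        n_served = min(size, int(ledger[medical_id] // cost))
        if n_served > 0:
            ledger[medical_id] -= n_served * cost
            served.append((n_served, wait))
            trace.append((wait, ledger[medical_id]))
        unserved += size - n_served
    return served, unserved, trace


def _group_trip(
    group: CasualtyGroup,
    medical_id: int,
    scenario: FailureScenario,
    instance: Instance,
    reassignment_time: str,
) -> tuple[int, int | None, Route, float]:
    """Resolve backup reassignment and the effective one-way trip time."""
    reassigned_from: int | None = None
    target = medical_id
    if not scenario.is_open(target):
        reassigned_from = target
        target = reassign_backup(group.affected_point, target, scenario, instance)
    route = instance.route(group.affected_point, target)
    t = travel_time(route, instance.fleet, instance.bigM)
    if reassigned_from is not None and reassignment_time == "additive":
        # literal two-leg reading: the original leg is paid before rerouting
        original = instance.route(group.affected_point, reassigned_from)
        t = min(t + travel_time(original, instance.fleet, instance.bigM), instance.bigM)
    return target, reassigned_from, route, t


def _allocate_fleet(
    order: list[int],
    needs: dict[int, int],
    pool: int,
) -> dict[int, int]:
    """Round-robin allocation of a vehicle pool.

    Cycles through groups in priority order, handing one vehicle at a
    time to any group still short of one vehicle per required trip.
    """
    assigned = {g: 0 for g in order}
    while pool > 0:
        progressed = False
        for g in order:
            if pool == 0:
                break
            if assigned[g] < needs[g]:
                assigned[g] += 1
                pool -= 1
                progressed = True
        if not progressed:
            break
    return assigned


def evaluate(
    assignment,
    instance: Instance,
    scenario: FailureScenario,
    death_model: DeathModel | None = None,
    *,
    groups: list[CasualtyGroup] | None = None,
    reassignment_time: str = "direct",
    group_wait: str = "per_batch",
) -> EvaluationResult:
    """Expected-death objective of one assignment under one scenario.

    Parameters
    ----------
    assignment:
        Sequence of medical-point ids, one per casualty group.
    reassignment_time:
        ``"direct"`` (default) prices a redirected group's trip at the
        backup leg only; ``"additive"`` adds the original leg as well.
    group_wait:
        ``"per_batch"`` (default) gives each batch its own waiting time;
        ``"last_batch"`` charges the whole group the final arrival time.
    """
    if death_model is None:
        death_model = DeathModel()
    if groups is None:
        groups = expand_groups(instance)
    assignment = list(assignment)
    if len(assignment) != len(groups):
        raise ValueError(f"assignment length {len(assignment)} != number of groups {len(groups)}")
    medical_ids = {m.id for m in instance.medical}
    for j in assignment:
        if j not in medical_ids:
            raise ValueError(f"unknown medical point id {j} in assignment")

    fleet = instance.fleet
    # resolve targets, routes and trip times
    resolved: dict[int, tuple[int, int | None, Route, float]] = {
        g.id: _group_trip(g, assignment[g.id], scenario, instance, reassignment_time)
        for g in groups
    }
    # dispatch priority: severe first, then shortest trip, then group id
    priority = sorted(
        groups,
        key=lambda g: (_STATE_PRIORITY[g.state], resolved[g.id][3], g.id),
    )
    # per-mode vehicle needs; blocked groups (big-M trips) get no vehicle
    caps = {AMBULANCE: fleet.q_h, "helicopter": fleet.q_n}
    pools = {AMBULANCE: fleet.Q_h, "helicopter": fleet.Q_n}
    modes = {g.id: transport_mode(resolved[g.id][2].epsilon) for g in groups}
    allocation: dict[int, int] = {}
    for mode, pool in pools.items():
        order = [
            g.id
            for g in priority
            if modes[g.id] == mode and resolved[g.id][3] < instance.bigM
        ]
        needs = {gid: math.ceil(_size(groups, gid) / caps[mode]) for gid in order}
        allocation.update(_allocate_fleet(order, needs, pool))

    # dispatch and consume resources, severe casualties first per medical point
    ledger = {m.id: float(m.Q) for m in instance.medical}
    plans: dict[int, DispatchPlan] = {}
    raw_batches: dict[int, list[tuple[int, float]]] = {}
    for g in priority:
        target, reassigned_from, route, t = resolved[g.id]
        vehicles = allocation.get(g.id, 0)
        if t >= instance.bigM or vehicles == 0:
            batches = [(g.size, instance.bigM)]
        elif t == 0:  # co-located: delivery is instantaneous
            batches = [(g.size, 0.0)]
        else:
            batches = dispatch_batches(g.size, vehicles, t, caps[modes[g.id]], instance.bigM)
        if group_wait == "last_batch":
            final = batches[-1][1]
            batches = [(size, final) for size, _ in batches]
        raw_batches[g.id] = batches
        plans[g.id] = DispatchPlan(
            group=g,
            medical_point=target,
            reassigned_from=reassigned_from,
            mode=modes[g.id],
            trip_time=t,
            batches=[],
        )
    resource_trace: dict[int, list[tuple[float, float]]] = {m.id: [] for m in instance.medical}
    severe_starved: set[int] = set()  # medical points with an unserved severe casualty
    for g in priority:  # severe groups consume stock before minor ones
        plan = plans[g.id]
        if g.state is InjuryState.G and plan.medical_point in severe_starved:
            # severe-first: leftover stock must not go to minors while a
            # severe casualty at this medical point went unserved
            served, unserved, trace = [], g.size, []
        else:
            served, unserved, trace = consume_resources(
                ledger, plan.medical_point, g.state, raw_batches[g.id], instance.C
            )
        if g.state is InjuryState.R and unserved > 0:
            severe_starved.add(plan.medical_point)
        plan.batches = served
        plan.unserved = unserved
        resource_trace[plan.medical_point].extend(trace)

    # objective
    objective = 0.0
    per_group: list[dict] = []
    total_unserved = 0
    for g in groups:
        plan = plans[g.id]
        expected = sum(
            size * death_probability(g.state, wait, death_model) for size, wait in plan.batches
        )
        expected += plan.unserved * 1.0  # unserved casualties wait big-M
        objective += expected
        total_unserved += plan.unserved
        per_group.append(
            {
                "group": g.id,
                "affected_point": g.affected_point,
                "state": g.state.value,
                "size": g.size,
                "medical_point": plan.medical_point,
                "mode": plan.mode,
                "expected_deaths": expected,
                "death_probability": expected / g.size,
                "unserved": plan.unserved,
            }
        )
    return EvaluationResult(
        objective=objective,
        plans=[plans[g.id] for g in groups],
        per_group=per_group,
        resource_ledger=resource_trace,
        feasible=total_unserved == 0,
        unserved=total_unserved,
        scenario_id=scenario.id,
    )


def _size(groups: list[CasualtyGroup], gid: int) -> int:
    return groups[gid].size


def evaluate_under_all_scenarios(
    assignment,
    instance: Instance,
    death_model: DeathModel | None = None,
    **kwargs,
) -> ScenarioSweep:
    """Evaluate one assignment under every failure scenario."""
    if not instance.scenarios:
        raise ValueError("instance has no scenarios")
    results = {
        s.id: evaluate(assignment, instance, s, death_model, **kwargs)
        for s in instance.scenarios
    }
    return ScenarioSweep(
        per_scenario={sid: r.objective for sid, r in results.items()},
        results=results,
    )


def dispatch_table(result: EvaluationResult, death_model: DeathModel | None = None) -> pd.DataFrame:
    """Per-batch dispatch table (CSV-ready)."""
    if death_model is None:
        death_model = DeathModel()
    rows = []
    for plan in result.plans:
        for trip, (size, wait) in enumerate(plan.batches, start=1):
            rows.append(
                {
                    "group": plan.group.id,
                    "affected_point": plan.group.affected_point,
                    "state": plan.group.state.value,
                    "medical_point": plan.medical_point,
                    "mode": plan.mode,
                    "trip": trip,
                    "batch_size": size,
                    "wait": wait,
                    "death_probability": death_probability(plan.group.state, wait, death_model),
                }
            )
        if plan.unserved:
            rows.append(
                {
                    "group": plan.group.id,
                    "affected_point": plan.group.affected_point,
                    "state": plan.group.state.value,
                    "medical_point": plan.medical_point,
                    "mode": plan.mode,
                    "trip": 0,
                    "batch_size": plan.unserved,
                    "wait": float("inf"),
                    "death_probability": 1.0,
                }
            )
    return pd.DataFrame(rows)
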