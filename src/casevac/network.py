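"""Problem-instance data model for the damaged transport network.

The relief network is bipartite: affected points (where casualties wait)
and medical points (where they are treated), connected by point-to-point
routes. Each route carries a distance and a damage degree ``eps`` in
[0, 1]: damage up to 0.5 slows ground transport, inflating the distance
to the generalized distance ``d * (1 + eps)``; damage above 0.5 blocks
ambulances entirely and forces helicopter transport over the raw
distance. Medical points can fail wholesale in discrete scenarios, in
which case casualties are redirected to the nearest open backup.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .injury import InjuryState

__all__ = [
    "AMBULANCE",
    "HELICOPTER",
    "AffectedPoint",
    "MedicalPoint",
    "Route",
    "FailureScenario",
    "Fleet",
    "Instance",
    "InfeasibleScenarioError",
    "generalized_distance",
    "transport_mode",
    "travel_time",
    "reassign_backup",
    "load_instance",
    "save_instance",
    "read_matrix_csv",
    "write_matrix_csv",
]

AMBULANCE = "ambulance"
HELICOPTER = "helicopter"

#: ground transport is possible up to this damage degree
DISRUPTION_THRESHOLD = 0.5

DEFAULT_BIG_M = 1e6


class InfeasibleScenarioError(RuntimeError):
    """Raised when a failure scenario leaves no open medical point."""


@dataclass(frozen=True)
class AffectedPoint:
    """Affected point with nominal casualty counts and their deviations.

    ``f`` maps injury state ("R"/"G") to the nominal casualty count;
    ``f_hat`` maps state to the maximum deviation of that count from the
    nominal value (the half-width of the uncertainty interval).
    """

    id: int
    f: dict[str, int]
    f_hat: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, count in self.f.items():
            if count < 0:
                raise ValueError(f"casualty count f[{w}] must be >= 0")
            dev = self.f_hat.get(w, 0)
            if not 0 <= dev <= count:
                raise ValueError(f"deviation f_hat[{w}]={dev} outside [0, f={count}]")

    def deviation(self, state: str) -> int:
        return self.f_hat.get(str(InjuryState(state).value), 0)


@dataclass(frozen=True)
class MedicalPoint:
    """Medical point with a finite treatment-resource stock ``Q``."""

    id: int
    Q: float

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("resource stock Q must be >= 0")


@dataclass(frozen=True)
class Route:
    """Directed route from an affected point to a medical point."""

    from_affected: int
    to_medical: int
    d: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("distance must be >= 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("damage degree must lie in [0, 1]")


@dataclass(frozen=True)
class FailureScenario:
    """Open/failed indicator per medical point (1 open, 0 failed)."""

    id: int
    beta: dict[int, int]

    def __post_init__(self) -> None:
        if not any(self.beta.values()):
            raise ValueError("a scenario must keep at least one medical point open")

    def is_open(self, medical_id: int) -> bool:
        return bool(self.beta.get(medical_id, 1))


@dataclass(frozen=True)
class Fleet:
    """Transport fleet: counts, per-trip capacities and speeds."""

    Q_h: int = 165  # ambulances
    Q_n: int = 15  # helicopters
    q_h: int = 2  # persons per ambulance trip
    q_n: int = 4  # persons per helicopter trip
    v_h: float = 40.0  # km/h
    v_n: float = 120.0  # km/h

    def __post_init__(self) -> None:
        if min(self.Q_h, self.Q_n) < 0 or min(self.q_h, self.q_n) <= 0:
            raise ValueError("fleet counts must be >= 0 and capacities > 0")
        if min(self.v_h, self.v_n) <= 0:
            raise ValueError("speeds must be positive")


@dataclass
class Instance:
    """A complete scheduling problem datum."""

    affected: list[AffectedPoint]
    medical: list[MedicalPoint]
    routes: dict[tuple[int, int], Route]
    scenarios: list[FailureScenario]
    fleet: Fleet = field(default_factory=Fleet)
    C: dict[str, float] = field(default_factory=lambda: {"R": 3.0, "G": 2.0})
    horizon: float = 30.0
    bigM: float = DEFAULT_BIG_M

    def __post_init__(self) -> None:
        for a in self.affected:
            for m in self.medical:
                if (a.id, m.id) not in self.routes:
                    raise ValueError(f"missing route ({a.id}, {m.id}): routes must cover I x J")
        if not self.C["R"] > self.C["G"] > 0:
            raise ValueError("treatment costs must satisfy C_r > C_g > 0")
        finite_times = [
            travel_time(r, self.fleet, self.bigM)
            for r in self.routes.values()
            if r.epsilon <= DISRUPTION_THRESHOLD
        ]
        if finite_times and self.bigM < max(finite_times) * 1e3:
            raise ValueError("bigM must exceed every finite travel time by >= 10^3")

    def route(self, affected_id: int, medical_id: int) -> Route:
        return self.routes[(affected_id, medical_id)]

    def medical_by_id(self, medical_id: int) -> MedicalPoint:
        for m in self.medical:
            if m.id == medical_id:
                return m
        raise KeyError(medical_id)

    def total_casualties(self) -> int:
        return sum(sum(a.f.values()) for a in self.affected)


def generalized_distance(d: float, epsilon: float, bigM: float = DEFAULT_BIG_M) -> float:
    """Damage-inflated route length: ``d * (1 + eps)`` while ground
    transport is possible (``eps <= 0.5``), big-M once the route is
    disrupted."""
    if d < 0 or not 0.0 <= epsilon <= 1.0:
        raise ValueError("need d >= 0 and eps in [0, 1]")
    if epsilon <= DISRUPTION_THRESHOLD:
        return d * (1.0 + epsilon)
    return bigM


def transport_mode(epsilon: float) -> str:
    """Ambulance while the route is passable (``eps <= 0.5``), helicopter
    once it is disrupted."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("damage degree must lie in [0, 1]")
    return AMBULANCE if epsilon <= DISRUPTION_THRESHOLD else HELICOPTER


def travel_time(route: Route, fleet: Fleet, bigM: float = DEFAULT_BIG_M) -> float:
    """One-way trip time on a route.

    Passable routes are driven at ambulance speed over the generalized
    distance; disrupted routes are flown at helicopter speed over the raw
    distance (helicopters are unaffected by road damage). Times are
    capped at big-M.
    """
    if transport_mode(route.epsilon) == AMBULANCE:
        t = generalized_distance(route.d, route.epsilon, bigM) / fleet.v_h
    else:
        t = route.d / fleet.v_n
    return min(t, bigM)


def reassign_backup(
    affected_id: int,
    failed_medical_id: int,
    scenario: FailureScenario,
    instance: Instance,
) -> int:
    """Nearest open backup medical point for an affected point whose
    assigned facility failed.

    Nearest means minimum one-way travel time from the affected point;
    ties break to the lowest medical-point id.
    """
    if scenario.is_open(failed_medical_id):
        raise ValueError(f"medical point {failed_medical_id} is open in scenario {scenario.id}")
    candidates = [m for m in instance.medical if scenario.is_open(m.id)]
    if not candidates:
        raise InfeasibleScenarioError(f"no open medical point in scenario {scenario.id}")
    return min(
        candidates,
        key=lambda m: (travel_time(instance.route(affected_id, m.id), instance.fleet, instance.bigM), m.id),
    ).id


# ---------------------------------------------------------------------------
# Serialization: a single JSON document plus CSV matrices for d and eps.


def _instance_to_dict(instance: Instance) -> dict:
    return {
        "affected": [
            {"id": a.id, "f": dict(a.f), "f_hat": dict(a.f_hat)} for a in instance.affected
        ],
        "medical": [{"id": m.id, "Q": m.Q} for m in instance.medical],
        "routes": [
            {
                "from_affected": r.from_affected,
                "to_medical": r.to_medical,
                "d": r.d,
                "epsilon": r.epsilon,
            }
            for r in sorted(instance.routes.values(), key=lambda r: (r.from_affected, r.to_medical))
        ],
        "scenarios": [
            {"id": s.id, "beta": {str(k): v for k, v in s.beta.items()}} for s in instance.scenarios
        ],
        "fleet": {
            "Q_h": instance.fleet.Q_h,
            "Q_n": instance.fleet.Q_n,
            "q_h": instance.fleet.q_h,
            "q_n": instance.fleet.q_n,
            "v_h": instance.fleet.v_h,
            "v_n": instance.fleet.v_n,
        },
        "costs": dict(instance.C),
        "horizon": instance.horizon,
        "bigM": instance.bigM,
    }


def _instance_from_dict(doc: dict) -> Instance:
    return Instance(
        affected=[
            AffectedPoint(id=a["id"], f=dict(a["f"]), f_hat=dict(a.get("f_hat", {})))
            for a in doc["affected"]
        ],
        medical=[MedicalPoint(id=m["id"], Q=m["Q"]) for m in doc["medical"]],
        routes={
            (r["from_affected"], r["to_medical"]): Route(
                from_affected=r["from_affected"],
                to_medical=r["to_medical"],
                d=r["d"],
                epsilon=r["epsilon"],
            )
            for r in doc["routes"]
        },
        scenarios=[
            FailureScenario(id=s["id"], beta={int(k): v for k, v in s["beta"].items()})
            for s in doc["scenarios"]
        ],
        fleet=Fleet(**doc["fleet"]),
        C=dict(doc.get("costs", {"R": 3.0, "G": 2.0})),
        horizon=doc.get("horizon", 30.0),
        bigM=doc.get("bigM", DEFAULT_BIG_M),
    )


def save_instance(instance: Instance, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_instance_to_dict(instance), indent=1, sort_keys=True) + "\n")


def load_instance(path: str | Path) -> Instance:
    return _instance_from_dict(json.loads(Path(path).read_text()))


def write_matrix_csv(instance: Instance, attr: str, path: str | Path) -> None:
    """Write the distance (``attr='d'``) or damage (``attr='epsilon'``)
    matrix as CSV: rows = affected points, columns = medical points."""
    rows = sorted(a.id for a in instance.affected)
    cols = sorted(m.id for m in instance.medical)
    frame = pd.DataFrame(
        [[getattr(instance.route(i, j), attr) for j in cols] for i in rows],
        index=pd.Index(rows, name="affected"),
        columns=cols,
    )
    frame.to_csv(path)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a distance or damage matrix CSV (ids in header row/column)."""
    frame = pd.read_csv(path, index_col=0)
    frame.columns = frame.columns.astype(int)
    frame.index = frame.index.astype(int)
    return frame


def routes_from_matrices(d: pd.DataFrame, eps: pd.DataFrame) -> dict[tuple[int, int], Route]:
    """Assemble the route dictionary from aligned distance/damage matrices."""
    if not d.index.equals(eps.index) or not d.columns.equals(eps.columns):
        raise ValueError("distance and damage matrices must share ids")
    return {
        (int(i), int(j)): Route(int(i), int(j), float(d.at[i, j]), float(eps.at[i, j]))
        for i in d.index
        for j in d.columns
    }
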