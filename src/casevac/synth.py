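"""Synthetic problem instances.

Real post-earthquake casualty tables are rarely shareable, so this
module generates instances that mimic the envelope of the Lushan (2013,
Sichuan) emergency-rescue case: 9 affected points, 7 medical points,
165 ambulances (50% of Ya'an's ~30 plus 50% of Chengdu's ~300), 15
helicopters, 2/4-person vehicle capacities, 40/120 km/h speeds,
treatment costs of 3 (severe) and 2 (minor) resource units, a 30-hour
horizon, casualty deviations of 20% of nominal, and four failure
scenarios (no failure, then distinct single-facility failures). Damage
degrees follow a mixture: a point mass of intact routes, a uniform
component of passable damage (0, 0.5], and a point mass of disrupted
routes (> 0.5) that force helicopter transport.

``lushan_like_fixture`` returns one fixed instance at the case's scale
(total casualties 2,333 across states); its casualty counts, distances
and damage degrees are synthetic stand-ins, not the real case tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    AffectedPoint,
    FailureScenario,
    Fleet,
    Instance,
    MedicalPoint,
    Route,
)

__all__ = ["GeneratorSpec", "generate", "lushan_like_fixture"]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-instance distribution.

    Casualty-count ranges are uniform-integer per injury state; the
    defaults put the per-point means near the case study's scale
    (~86 severe / ~173 minor per point). ``eps_zero_mass`` /
    ``eps_disrupted_mass`` are the probabilities of an intact route
    (eps = 0) and a disrupted one (eps > 0.5); the remainder is uniform
    on (0, 0.5].
    """

    n_affected: int = 9
    n_medical: int = 7
    casualty_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"R": (20, 150), "G": (40, 300)}
    )
    resource_range: tuple[int, int] = (400, 1200)
    distance_range: tuple[float, float] = (5.0, 60.0)
    eps_zero_mass: float = 0.5
    eps_disrupted_mass: float = 0.1
    n_scenarios: int = 4
    failures_per_scenario: int = 1
    deviation_fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_affected < 1 or self.n_medical < 1:
            raise ValueError("need at least one affected and one medical point")
        if not 0.0 <= self.eps_disrupted_mass < 1.0 or self.eps_zero_mass < 0:
            raise ValueError("mixture masses must be valid probabilities")
        if self.eps_zero_mass + self.eps_disrupted_mass > 1.0:
            raise ValueError("mixture masses sum above 1")
        if self.n_scenarios < 1:
            raise ValueError("need at least one (no-failure) scenario")
        if (self.n_scenarios - 1) * self.failures_per_scenario > 0 and self.n_medical <= self.failures_per_scenario:
            raise ValueError("failures per scenario must leave medical points open")
        for lo, hi in self.casualty_range.values():
            if lo > hi or lo < 0:
                raise ValueError("casualty ranges must be nonempty and nonnegative")


def _draw_epsilon(rng: np.random.Generator, spec: GeneratorSpec) -> float:
    u = rng.random()
    if u < spec.eps_zero_mass:
        return 0.0
    if u < spec.eps_zero_mass + spec.eps_disrupted_mass:
        return float(rng.uniform(0.51, 1.0))  # disrupted: stays > 0.5 after rounding
    return float(rng.uniform(0.0, 0.5))


def generate(spec: GeneratorSpec) -> Instance:
    """Draw a reproducible random instance from ``spec``.

    Scenario 1 never fails anything; each later scenario fails a
    distinct set of ``failures_per_scenario`` medical points.
    """
    rng = np.random.default_rng(spec.seed)
    affected = []
    for i in range(1, spec.n_affected + 1):
        f = {
            w: int(rng.integers(lo, hi + 1))
            for w, (lo, hi) in sorted(spec.casualty_range.items())
        }
        f_hat = {w: min(_round_half_up(spec.deviation_fraction * c), c) for w, c in f.items()}
        affected.append(AffectedPoint(id=i, f=f, f_hat=f_hat))
    lo_q, hi_q = spec.resource_range
    medical = [
        MedicalPoint(id=j, Q=float(rng.integers(lo_q, hi_q + 1)))
        for j in range(1, spec.n_medical + 1)
    ]
    lo_d, hi_d = spec.distance_range
    routes = {
        (a.id, m.id): Route(
            a.id,
            m.id,
            d=float(np.round(rng.uniform(lo_d, hi_d), 2)),
            epsilon=float(np.round(min(_draw_epsilon(rng, spec), 1.0), 3)),
        )
        for a in affected
        for m in medical
    }
    scenarios = [FailureScenario(id=1, beta={m.id: 1 for m in medical})]
    # distinct failure sets, cycling through medical ids
    medical_ids = [m.id for m in medical]
    cursor = 1  # skip failing point 1 first so scenario ids echo failed ids at defaults
    for s in range(2, spec.n_scenarios + 1):
        failed = set()
        for _ in range(spec.failures_per_scenario):
            failed.add(medical_ids[cursor % len(medical_ids)])
            cursor += 1
        scenarios.append(
            FailureScenario(id=s, beta={m.id: 0 if m.id in failed else 1 for m in medical})
        )
    return Instance(
        affected=affected,
        medical=medical,
        routes=routes,
        scenarios=scenarios,
        fleet=Fleet(),
    )


# Fixed Lushan-scale fixture -------------------------------------------------

# synthetic per-point casualty counts; columns R, G. Totals 773 and 1,560
# match the case study's treated head-counts, the split is invented.
_FIXTURE_CASUALTIES = [
    (95, 180),
    (96, 270),
    (100, 142),
    (90, 210),
    (64, 160),
    (78, 270),
    (120, 111),
    (70, 177),
    (60, 40),
]

# synthetic resource stocks; total 5,639 vs. 5,439 units required
_FIXTURE_RESOURCES = [950, 900, 820, 800, 780, 720, 669]


def _fixture_distance(i: int, j: int) -> float:
    return 8.0 + float((13 * i + 7 * j) % 40) + 0.5 * float((i + j) % 3)


def _fixture_epsilon(i: int, j: int) -> float:
    r = (3 * i + 5 * j) % 12
    if r < 5:
        return 0.0
    if r <= 9:
        return 0.1 * (r - 4)  # 0.1 .. 0.5, passable
    return 0.7 if r == 10 else 0.9  # disrupted: helicopters only


def lushan_like_fixture() -> Instance:
    """Deterministic synthetic instance at the Lushan case's scale.

    9 affected points, 7 medical points, 165 ambulances, 15 helicopters,
    capacities 2/4, speeds 40/120 km/h, costs 3/2, 30 h horizon, 20%
    casualty deviations, and four scenarios failing nothing, then
    medical points 2, 4 and 7 respectively. Every number never published
    for the real case — per-point casualty counts, distances, damage
    degrees, stocks — is a synthetic stand-in.
    """
    affected = []
    for i, (r, g) in enumerate(_FIXTURE_CASUALTIES, start=1):
        f = {"G": g, "R": r}
        f_hat = {w: _round_half_up(0.2 * c) for w, c in f.items()}
        affected.append(AffectedPoint(id=i, f=f, f_hat=f_hat))
    medical = [MedicalPoint(id=j, Q=float(q)) for j, q in enumerate(_FIXTURE_RESOURCES, start=1)]
    routes = {
        (i, j): Route(i, j, d=_fixture_distance(i, j), epsilon=_fixture_epsilon(i, j))
        for i in range(1, 10)
        for j in range(1, 8)
    }
    all_open = {j: 1 for j in range(1, 8)}
    scenarios = [FailureScenario(id=1, beta=dict(all_open))]
    for sid, failed in ((2, 2), (3, 4), (4, 7)):
        beta = dict(all_open)
        beta[failed] = 0
        scenarios.append(FailureScenario(id=sid, beta=beta))
    return Instance(
        affected=affected,
        medical=medical,
        routes=routes,
        scenarios=scenarios,
        fleet=Fleet(Q_h=165, Q_n=15, q_h=2, q_n=4, v_h=40.0, v_n=120.0),
        C={"R": 3.0, "G": 2.0},
        horizon=30.0,
    )
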