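"""Budget-of-uncertainty robust counterpart for uncertain casualty counts.

Casualty counts at each affected point are interval-uncertain:
``f_iw`` nominal with maximum deviation ``f_hat_iw`` (0.2 * f by
default). The adversary may push at most ``Gamma`` of the deviating
terms to their worst case (the last one fractionally), and the
*protection function* phi is the worst-case extra expected deaths this
can cause given the realized per-group death probabilities of a
candidate schedule:

    phi(Gamma) = max over S, t { sum_{i in S} fhat_i P_i
                                 + (Gamma - floor(Gamma)) fhat_t P_t }

with |S| = floor(Gamma) and t outside S. Gamma = 0 recovers the nominal
model; a full budget recovers the fully conservative (Soyster) model.
The maximization is a continuous knapsack, solved by sorting; the
accompanying dual certificate (z, p) with z + p_i >= fhat_i P_i proves
optimality through strong LP duality:

    phi = Gamma * z + sum_i p_i,   z = the (floor(Gamma)+1)-th largest
    contribution, p_i = max(0, fhat_i P_i - z).

The robust objective of a schedule is nominal expected deaths plus the
summed protection, with the budget indexed per injury state (as in the
sensitivity experiments) or per (point, state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .injury import DeathModel
from .network import FailureScenario, Instance
from .evaluator import EvaluationResult, evaluate

__all__ = [
    "ProtectionResult",
    "RobustObjective",
    "protection_value",
    "deviation_contributions",
    "robust_objective",
    "gamma_sensitivity",
]


@dataclass
class ProtectionResult:
    """Protection value with its maximizing set and dual certificate."""

    phi: float
    chosen_set: list[int]  # indices deviating fully
    fractional_index: int | None  # index deviating by the fractional budget
    dual_z: float
    dual_p: list[float]
    gamma: float

    def dual_value(self) -> float:
        return self.gamma * self.dual_z + sum(self.dual_p)


@dataclass
class RobustObjective:
    """Robust objective = nominal expected deaths + total protection."""

    f: float
    nominal: float
    phi_total: float
    protections: dict = field(default_factory=dict)
    evaluation: EvaluationResult | None = None


def protection_value(dev_contributions, gamma: float) -> ProtectionResult:
    """Worst-case extra objective from at most ``gamma`` deviations.

    ``dev_contributions`` are the per-term worst-case increments
    ``fhat_i * P_i`` (nonnegative). The floor(gamma) largest terms
    deviate fully and the next largest deviates by the fractional part;
    ties break by index order (stable sort). The returned dual
    certificate attains phi exactly.
    """
    c = [float(x) for x in dev_contributions]
    if any(x < 0 for x in c):
        raise ValueError("deviation contributions must be nonnegative")
    if gamma < 0:
        raise ValueError("budget must be nonnegative")
    n = len(c)
    if gamma > n:
        warnings.warn(
            f"budget {gamma} exceeds the {n} deviating terms; clamped (Soyster limit)",
            stacklevel=2,
        )
        gamma = float(n)
    k = int(gamma)
    frac = gamma - k
    order = sorted(range(n), key=lambda i: (-c[i], i))
    chosen = order[:k]
    fractional = order[k] if frac > 0 and k < n else None
    phi = sum(c[i] for i in chosen)
    if fractional is not None:
        phi += frac * c[fractional]
    # dual certificate: z = (k+1)-th largest contribution (0 past the end)
    z = c[order[k]] if k < n else 0.0
    p = [max(0.0, ci - z) for ci in c]
    return ProtectionResult(
        phi=phi,
        chosen_set=sorted(chosen),
        fractional_index=fractional,
        dual_z=z,
        dual_p=p,
        gamma=gamma,
    )


def deviation_contributions(
    instance: Instance, result: EvaluationResult
) -> dict[tuple[int, str], float]:
    """Per-(affected point, state) worst-case increments fhat * P.

    ``P`` is the realized per-group death probability of the evaluated
    schedule (expected deaths / group size). Points without a stated
    deviation contribute 0.
    """
    contributions: dict[tuple[int, str], float] = {}
    missing = False
    by_id = {a.id: a for a in instance.affected}
    for row in result.per_group:
        point = by_id[row["affected_point"]]
        fhat = point.deviation(row["state"])
        if fhat == 0 and not point.f_hat:
            missing = True
        key = (row["affected_point"], row["state"])
        contributions[key] = contributions.get(key, 0.0) + fhat * row["death_probability"]
    if missing:
        warnings.warn("some affected points carry no deviation f_hat; treated as 0", stacklevel=2)
    return dict(sorted(contributions.items()))


def robust_objective(
    assignment,
    instance: Instance,
    scenario: FailureScenario,
    budget,
    death_model: DeathModel | None = None,
    *,
    per_point: bool = False,
    **evaluate_kwargs,
) -> RobustObjective:
    """Robust expected-death objective of one assignment.

    ``budget`` is either a scalar or a mapping per injury state
    ("R"/"G") when ``per_point`` is False (default, matching the
    state-wise sensitivity experiments), or a mapping per
    (point id, state) when ``per_point`` is True.
    """
    result = evaluate(assignment, instance, scenario, death_model, **evaluate_kwargs)
    contributions = deviation_contributions(instance, result)
    protections: dict = {}
    phi_total = 0.0
    if per_point:
        for key, value in contributions.items():
            gamma = budget[key] if isinstance(budget, dict) else float(budget)
            prot = protection_value([value], min(gamma, 1.0))
            protections[key] = prot
            phi_total += prot.phi
    else:
        states = sorted({w for _, w in contributions})
        for w in states:
            values = [v for (i, s), v in contributions.items() if s == w]
            gamma = budget[w] if isinstance(budget, dict) else float(budget)
            gamma = min(gamma, len(values))
            prot = protection_value(values, gamma)
            protections[w] = prot
            phi_total += prot.phi
    return RobustObjective(
        f=result.objective + phi_total,
        nominal=result.objective,
        phi_total=phi_total,
        protections=protections,
        evaluation=result,
    )


def gamma_sensitivity(
    solve,
    instance: Instance,
    budgets,
    death_model: DeathModel | None = None,
    **robust_kwargs,
) -> pd.DataFrame:
    """Objective vs. budget table with the gap to the nominal model.

    ``solve`` maps an objective callable ``Assignment -> value`` to an
    optimized objective value (a solver closure); passing a fixed
    assignment instead evaluates that assignment at each budget.
    gap% = 100 * (objective(Gamma) - objective(0)) / objective(0),
    reported half-up to 2 decimals.
    """
    from .reports import gap_percent  # local import to avoid a cycle

    budgets = list(budgets)
    if budgets != sorted(budgets) or budgets[0] != 0:
        raise ValueError("budgets must be ascending and start at 0")
    scenario = instance.scenarios[0]

    def value_at(gamma) -> float:
        def objective(assignment) -> float:
            return robust_objective(
                assignment, instance, scenario, gamma, death_model, **robust_kwargs
            ).f

        if callable(solve):
            return float(solve(objective))
        return float(objective(solve))

    rows = []
    baseline: float | None = None
    for gamma in budgets:
        obj = value_at(gamma)
        if baseline is None:
            baseline = obj
        rows.append(
            {
                "gamma": gamma,
                "objective": obj,
                "gap_percent": gap_percent(obj, baseline) if baseline > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
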