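"""Three-state injury-deterioration model.

Casualties waiting for evacuation occupy one of three states: minor
injury (G, "green"), severe injury (R, "red") and death (D). While
untreated, a minor casualty worsens to severe with probability ``p_gr``
per time unit and a severe casualty dies with probability ``p_rd`` per
time unit; death is absorbing. Two views of the chain are provided:

* a linear death-probability function of waiting time (the scheduling
  objective's building block), in which the per-unit hazard accumulates
  additively and is capped at 1; and
* an exact per-step Monte-Carlo simulator of the chain itself.

Under the linear rule a minor casualty takes ``1 / p_gr`` time units to
fully evolve into the severe state; only beyond that threshold does it
accumulate death probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "InjuryState",
    "TransitionParams",
    "DeathModel",
    "evolution_threshold",
    "death_probability",
    "simulate_trajectory",
]


class InjuryState(str, Enum):
    """Injury severity: G (minor), R (severe), D (dead, absorbing)."""

    G = "G"
    R = "R"
    D = "D"


@dataclass(frozen=True)
class TransitionParams:
    """Per-time-unit deterioration probabilities.

    Parameters
    ----------
    p_rd:
        Probability that a severe casualty dies in one time unit.
    p_gr:
        Probability that a minor casualty becomes severe in one time unit.
    time_unit:
        Label for the evolution period. All waiting times passed to this
        module are expressed in this unit; the default of one hour keeps
        the deterioration rates commensurate with travel times measured
        from km distances and km/h speeds.
    """

    p_rd: float = 0.1
    p_gr: float = 0.05
    time_unit: str = "hour"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_rd <= 1.0:
            raise ValueError(f"p_rd must be in (0, 1], got {self.p_rd}")
        if not 0.0 <= self.p_gr <= 1.0:
            raise ValueError(f"p_gr must be in [0, 1], got {self.p_gr}")


def evolution_threshold(params: TransitionParams) -> float:
    """Time for a minor casualty to fully evolve into the severe state.

    Under the linear accumulation rule the G->R transition probability
    times the elapsed time reaches 1 at ``T = 1 / p_gr``; with the
    default ``p_gr = 0.05`` this is 20 time units. A zero transition
    probability means the minor state never evolves (infinite threshold).
    """
    if params.p_gr == 0.0:
        return math.inf
    return 1.0 / params.p_gr


@dataclass(frozen=True)
class DeathModel:
    """Linear death-probability model with its derived G->R threshold."""

    params: TransitionParams = field(default_factory=TransitionParams)

    @property
    def evolution_threshold(self) -> float:
        return evolution_threshold(self.params)


def death_probability(state: InjuryState, wait: float, model: DeathModel | None = None) -> float:
    """Death probability of a casualty after ``wait`` time units untreated.

    Severe casualties accumulate ``p_rd`` per unit, capped at 1:
    ``min(1, p_rd * wait)``. Minor casualties are safe until the
    evolution threshold ``T = 1/p_gr`` and accumulate ``p_rd`` per unit
    beyond it: ``0`` for ``wait <= T`` and ``min(1, p_rd * (wait - T))``
    after. An infinite wait (a blocked route, big-M) maps to exactly 1.

    Raises
    ------
    ValueError
        If ``state`` is D (death admits no further probability) or
        ``wait`` is negative.
    """
    if model is None:
        model = DeathModel()
    state = InjuryState(state)
    if state is InjuryState.D:
        raise ValueError("death probability is defined for live states G and R only")
    if wait < 0:
        raise ValueError(f"waiting time must be nonnegative, got {wait}")
    if math.isinf(wait):
        return 1.0
    p_rd = model.params.p_rd
    if state is InjuryState.R:
        return min(1.0, p_rd * wait)
    threshold = model.evolution_threshold
    if wait <= threshold:
        return 0.0
    return min(1.0, p_rd * (wait - threshold))


def simulate_trajectory(
    state: InjuryState,
    horizon: int,
    params: TransitionParams | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[InjuryState, int | None]:
    """Simulate the injury chain for ``horizon`` steps without treatment.

    Each step a minor casualty becomes severe with probability ``p_gr``
    and a severe casualty dies with probability ``p_rd``; otherwise the
    state is kept. Death is absorbing.

    Returns the terminal state and the step index (1-based) at which
    death occurred, or ``None`` if the casualty survived the horizon.
    """
    if params is None:
        params = TransitionParams()
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    current = InjuryState(state)
    for step in range(1, horizon + 1):
        if current is InjuryState.D:
            break
        u = rng.random()
        if current is InjuryState.G:
            if u < params.p_gr:
                current = InjuryState.R
        else:  # R
            if u < params.p_rd:
                return InjuryState.D, step
    return current, None
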