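import pytest

from casevac.network import (
    AffectedPoint,
    FailureScenario,
    Fleet,
    Instance,
    MedicalPoint,
    Route,
)


def build_instance(
    casualties,
    stocks,
    distances,
    epsilons=None,
    fleet=None,
    scenarios=None,
    **kwargs,
):
    """Assemble a small Instance from plain nested lists.

    ``casualties``: list of (R, G) per affected point; ``stocks``: Q per
    medical point; ``distances``/``epsilons``: row-per-affected matrices.
    Scenario 1 (all open) is always included.
    """
    n_a, n_m = len(casualties), len(stocks)
    if epsilons is None:
        epsilons = [[0.0] * n_m for _ in range(n_a)]
    f_hat_map = kwargs.pop("f_hat", {})
    affected = [
        AffectedPoint(id=i + 1, f={"R": r, "G": g}, f_hat=f_hat_map.get(i + 1, {}))
        for i, (r, g) in enumerate(casualties)
    ]
    medical = [MedicalPoint(id=j + 1, Q=float(q)) for j, q in enumerate(stocks)]
    routes = {
        (i + 1, j + 1): Route(i + 1, j + 1, float(distances[i][j]), float(epsilons[i][j]))
        for i in range(n_a)
        for j in range(n_m)
    }
    all_open = FailureScenario(id=1, beta={m.id: 1 for m in medical})
    scen = [all_open] + (scenarios or [])
    return Instance(
        affected=affected,
        medical=medical,
        routes=routes,
        scenarios=scen,
        fleet=fleet or Fleet(),
        **kwargs,
    )


@pytest.fixture
def single_route_instance():
    """One affected point (5 severe), one medical point 40 km away on an
    intact road, one ambulance: the canonical three-trip dispatch."""
    return build_instance(
        casualties=[(5, 0)],
        stocks=[100],
        distances=[[40.0]],
        fleet=Fleet(Q_h=1, Q_n=0),
    )


@pytest.fixture
def two_by_two_instance():
    """Two affected points, two medical points, a failure scenario for
    each medical point."""
    scenarios = [
        FailureScenario(id=2, beta={1: 0, 2: 1}),
        FailureScenario(id=3, beta={1: 1, 2: 0}),
    ]
    return build_instance(
        casualties=[(6, 8), (4, 10)],
        stocks=[60, 60],
        distances=[[20.0, 60.0], [60.0, 20.0]],
        epsilons=[[0.0, 0.2], [0.2, 0.0]],
        fleet=Fleet(Q_h=6, Q_n=2),
        scenarios=scenarios,
    )
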