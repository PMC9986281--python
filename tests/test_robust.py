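"""Budget-of-uncertainty protection: sorting solution vs. brute-force
subset enumeration, dual certificate, and budget monotonicity."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casevac.robust import protection_value, robust_objective, gamma_sensitivity
from casevac.synth import GeneratorSpec, generate
from casevac.evaluator import expand_groups


def protection_by_enumeration(c, gamma):
    """Independent oracle: maximize over every subset S of size
    floor(gamma) and every fractional term t outside S."""
    n = len(c)
    k = int(min(gamma, n))
    frac = gamma - k
    best = 0.0
    for S in itertools.combinations(range(n), k):
        base = sum(c[i] for i in S)
        rest = [c[i] for i in range(n) if i not in S]
        extra = frac * max(rest) if (frac > 0 and rest) else 0.0
        best = max(best, base + extra)
    return best


class TestProtectionValue:
    @pytest.mark.parametrize(
        "c, gamma, expected",
        [
            ([0.4, 0.3, 0.1], 1.5, 0.55),  # 0.4 + 0.5 * 0.3
            ([0.4, 0.3, 0.1], 0.0, 0.0),  # nominal model
            ([0.4, 0.3, 0.1], 3.0, 0.8),  # Soyster (fully conservative) limit
            ([0.4, 0.3, 0.1], 2.0, 0.7),
        ],
    )
    def test_knapsack_values(self, c, gamma, expected):
        assert protection_value(c, gamma).phi == pytest.approx(expected)

    def test_budget_above_length_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="Soyster"):
            result = protection_value([0.2, 0.1], 5.0)
        assert result.phi == pytest.approx(0.3)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            protection_value([-0.1], 1)
        with pytest.raises(ValueError):
            protection_value([0.1], -1)

    @given(
        c=st.lists(st.floats(0, 10), min_size=1, max_size=10),
        gamma=st.floats(0, 10),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_enumeration(self, c, gamma):
        gamma = min(gamma, len(c))
        result = protection_value(c, gamma)
        assert result.phi == pytest.approx(protection_by_enumeration(c, gamma), abs=1e-9)

    @given(
        c=st.lists(st.floats(0, 10), min_size=1, max_size=12),
        gamma=st.floats(0, 12),
    )
    @settings(max_examples=200, derandomize=True)
    def test_dual_certificate_is_feasible_and_tight(self, c, gamma):
        gamma = min(gamma, len(c))
        result = protection_value(c, gamma)
        assert result.dual_z >= 0
        assert all(p >= 0 for p in result.dual_p)
        for ci, pi in zip(c, result.dual_p):
            assert result.dual_z + pi >= ci - 1e-12
        assert result.dual_value() == pytest.approx(result.phi, abs=1e-9)

    def test_dual_matches_lp_solution(self):
        """The closed-form dual certificate agrees with an LP solve of
        min gamma*z + sum p s.t. z + p_i >= c_i, z, p >= 0."""
        from scipy.optimize import linprog

        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 9))
            c = rng.uniform(0, 5, size=n)
            gamma = float(rng.uniform(0, n))
            result = protection_value(list(c), gamma)
            # variables [z, p_1..p_n]
            res = linprog(
                c=[gamma] + [1.0] * n,
                A_ub=np.hstack([-np.ones((n, 1)), -np.eye(n)]),
                b_ub=-c,
                bounds=[(0, None)] * (n + 1),
                method="highs",
            )
            assert res.success
            assert res.fun == pytest.approx(result.phi, abs=1e-9)

    def test_monotone_and_concave_in_gamma(self):
        rng = np.random.default_rng(3)
        c = list(rng.uniform(0, 4, size=9))
        grid = np.linspace(0, 9, 37)
        phis = [protection_value(c, g).phi for g in grid]
        assert all(a <= b + 1e-12 for a, b in zip(phis, phis[1:]))
        increments = np.diff(phis)
        assert all(b <= a + 1e-9 for a, b in zip(increments, increments[1:]))
        assert phis[-1] == pytest.approx(sum(c))


class TestRobustObjective:
    @pytest.fixture
    def instance(self):
        return generate(
            GeneratorSpec(
                n_affected=3,
                n_medical=2,
                casualty_range={"R": (5, 30), "G": (5, 40)},
                resource_range=(100, 300),
                seed=11,
            )
        )

    def test_zero_budget_equals_nominal_exactly(self, instance):
        groups = expand_groups(instance)
        assignment = [(g.id % 2) + 1 for g in groups]
        ro = robust_objective(assignment, instance, instance.scenarios[0], 0)
        assert ro.f == ro.nominal
        assert ro.phi_total == 0.0

    def test_zero_deviation_equals_nominal_for_any_budget(self):
        import dataclasses

        from casevac.network import AffectedPoint

        inst = generate(
            GeneratorSpec(n_affected=3, n_medical=2, casualty_range={"R": (5, 30), "G": (5, 40)}, seed=4)
        )
        no_dev = dataclasses.replace(
            inst,
            affected=[AffectedPoint(a.id, dict(a.f), {w: 0 for w in a.f}) for a in inst.affected],
        )
        groups = expand_groups(no_dev)
        assignment = [(g.id % 2) + 1 for g in groups]
        ro = robust_objective(assignment, no_dev, no_dev.scenarios[0], 3)
        assert ro.f == pytest.approx(ro.nominal)

    @pytest.mark.parametrize("seed", range(20))
    def test_nondecreasing_in_budget(self, seed):
        inst = generate(
            GeneratorSpec(
                n_affected=3,
                n_medical=2,
                casualty_range={"R": (3, 20), "G": (3, 25)},
                resource_range=(50, 200),
                seed=seed,
            )
        )
        groups = expand_groups(inst)
        assignment = [(g.id % 2) + 1 for g in groups]
        values = [
            robust_objective(assignment, inst, inst.scenarios[0], gamma).f
            for gamma in (0, 1, 2, 3)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_per_point_budget_mode(self, instance):
        groups = expand_groups(instance)
        assignment = [(g.id % 2) + 1 for g in groups]
        global_mode = robust_objective(assignment, instance, instance.scenarios[0], 1.0)
        per_point = robust_objective(
            assignment, instance, instance.scenarios[0], 1.0, per_point=True
        )
        # per-point with full unit budgets is the Soyster limit, at least
        # as conservative as one deviation per state
        assert per_point.phi_total >= global_mode.phi_total - 1e-12


class TestGammaSensitivity:
    def test_gap_table_on_a_fixed_assignment(self):
        inst = generate(
            GeneratorSpec(
                n_affected=3,
                n_medical=2,
                casualty_range={"R": (5, 30), "G": (5, 40)},
                resource_range=(100, 300),
                seed=2,
            )
        )
        groups = expand_groups(inst)
        assignment = tuple((g.id % 2) + 1 for g in groups)
        table = gamma_sensitivity(assignment, inst, [0, 1, 2, 3])
        assert list(table["gamma"]) == [0, 1, 2, 3]
        assert table["objective"].is_monotonic_increasing
        assert table.loc[0, "gap_percent"] == 0.0
        assert table["gap_percent"].is_monotonic_increasing

    def test_budgets_must_start_at_zero(self):
        inst = generate(GeneratorSpec(n_affected=2, n_medical=2, seed=1))
        with pytest.raises(ValueError):
            gamma_sensitivity((1, 1, 1, 1), inst, [1, 2])
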