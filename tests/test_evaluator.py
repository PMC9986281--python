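"""Schedule evaluation: batch dispatch, resource consumption, the
expected-death objective and its structural invariants."""

import math

import pytest

from casevac.evaluator import (
    consume_resources,
    dispatch_batches,
    evaluate,
    evaluate_under_all_scenarios,
    expand_groups,
    dispatch_table,
)
from casevac.injury import InjuryState
from casevac.network import FailureScenario, Fleet
from casevac.synth import GeneratorSpec, generate

from conftest import build_instance


class TestDispatchBatches:
    @pytest.mark.parametrize(
        "size, vehicles, t, cap, expected",
        [
            (5, 1, 1.0, 2, [(2, 1.0), (2, 3.0), (1, 5.0)]),  # one shuttle, 3 trips
            (2, 1, 1.0, 2, [(2, 1.0)]),
            (8, 2, 0.5, 4, [(4, 0.5), (4, 0.5)]),  # two vehicles, first arrivals
            (6, 2, 1.0, 2, [(2, 1.0), (2, 1.0), (2, 3.0)]),
        ],
    )
    def test_odd_multiple_shuttle_waits(self, size, vehicles, t, cap, expected):
        assert dispatch_batches(size, vehicles, t, cap) == expected

    def test_no_vehicle_means_big_m_wait(self):
        assert dispatch_batches(7, 0, 1.0, 2, bigM=1e6) == [(7, 1e6)]

    def test_batches_conserve_the_group(self):
        batches = dispatch_batches(23, 3, 0.7, 4)
        assert sum(size for size, _ in batches) == 23
        assert all(size <= 4 for size, _ in batches)
        waits = [w for _, w in batches]
        assert waits == sorted(waits)


class TestConsumeResources:
    def test_full_service_deducts_costs(self):
        ledger = {1: 10.0}
        served, unserved, _ = consume_resources(ledger, 1, InjuryState.R, [(3, 1.0)], {"R": 3.0, "G": 2.0})
        assert served == [(3, 1.0)] and unserved == 0
        assert ledger[1] == pytest.approx(1.0)

    def test_stock_exhaustion_splits_the_batch(self):
        ledger = {1: 10.0}
        served, unserved, _ = consume_resources(ledger, 1, InjuryState.R, [(4, 1.0)], {"R": 3.0, "G": 2.0})
        assert sum(s for s, _ in served) == 3 and unserved == 1

    def test_empty_stock_serves_nobody(self):
        ledger = {1: 0.0}
        served, unserved, _ = consume_resources(ledger, 1, InjuryState.G, [(5, 1.0)], {"R": 3.0, "G": 2.0})
        assert served == [] and unserved == 5
        assert ledger[1] == 0.0


class TestEvaluate:
    def test_single_group_shuttle_objective(self, single_route_instance):
        # 5 severe, 1 ambulance, 1 h trip: waits 1,1,3,3,5 h -> 1.3 deaths
        result = evaluate([1], single_route_instance, single_route_instance.scenarios[0])
        assert result.objective == pytest.approx(1.3)
        assert result.feasible and result.unserved == 0

    def test_zero_distance_gives_zero_objective(self):
        inst = build_instance(
            casualties=[(4, 6)], stocks=[100], distances=[[0.0]], fleet=Fleet(Q_h=5, Q_n=0)
        )
        result = evaluate([1, 1], inst, inst.scenarios[0])
        assert result.objective == 0.0

    def test_all_disrupted_without_helicopters_kills_everyone(self):
        inst = build_instance(
            casualties=[(3, 7)],
            stocks=[100],
            distances=[[30.0]],
            epsilons=[[0.9]],
            fleet=Fleet(Q_h=10, Q_n=0),
        )
        result = evaluate([1, 1], inst, inst.scenarios[0])
        assert result.objective == pytest.approx(10.0)  # total casualties

    def test_failed_point_redirects_to_backup(self, two_by_two_instance):
        scen = two_by_two_instance.scenarios[1]  # medical point 1 failed
        result = evaluate([1, 1, 1, 1], two_by_two_instance, scen)
        assert all(p.medical_point == 2 for p in result.plans)
        assert all(p.reassigned_from == 1 for p in result.plans)

    def test_additive_reassignment_pays_both_legs(self, two_by_two_instance):
        scen = two_by_two_instance.scenarios[1]
        direct = evaluate([1, 1, 1, 1], two_by_two_instance, scen)
        additive = evaluate(
            [1, 1, 1, 1], two_by_two_instance, scen, reassignment_time="additive"
        )
        assert additive.objective >= direct.objective

    def test_last_batch_wait_dominates_per_batch(self, single_route_instance):
        per_batch = evaluate([1], single_route_instance, single_route_instance.scenarios[0])
        grouped = evaluate(
            [1], single_route_instance, single_route_instance.scenarios[0], group_wait="last_batch"
        )
        # whole group charged the final 5 h arrival: 5 * 0.5
        assert grouped.objective == pytest.approx(2.5)
        assert grouped.objective >= per_batch.objective

    def test_rejects_bad_assignments(self, two_by_two_instance):
        scen = two_by_two_instance.scenarios[0]
        with pytest.raises(ValueError, match="length"):
            evaluate([1], two_by_two_instance, scen)
        with pytest.raises(ValueError, match="unknown medical"):
            evaluate([1, 9, 1, 1], two_by_two_instance, scen)


class TestStructuralInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_and_bounds(self, seed):
        inst = generate(
            GeneratorSpec(
                n_affected=4,
                n_medical=3,
                casualty_range={"R": (5, 40), "G": (5, 60)},
                resource_range=(30, 200),
                seed=seed,
            )
        )
        groups = expand_groups(inst)
        assignment = [(g.id % 3) + 1 for g in groups]
        result = evaluate(assignment, inst, inst.scenarios[0])
        total = inst.total_casualties()
        assert result.served + result.unserved == total
        assert 0.0 <= result.objective <= total

    @pytest.mark.parametrize("seed", range(8))
    def test_severe_first_service(self, seed):
        """No minor casualty is served at a medical point where a severe
        casualty went unserved."""
        inst = generate(
            GeneratorSpec(
                n_affected=4,
                n_medical=2,
                casualty_range={"R": (10, 60), "G": (10, 80)},
                resource_range=(20, 120),  # scarce: forces unserved casualties
                seed=seed,
            )
        )
        groups = expand_groups(inst)
        assignment = [(g.id % 2) + 1 for g in groups]
        result = evaluate(assignment, inst, inst.scenarios[0])
        starved = {
            p.medical_point
            for p in result.plans
            if p.group.state is InjuryState.R and p.unserved > 0
        }
        for plan in result.plans:
            if plan.group.state is InjuryState.G and plan.medical_point in starved:
                assert plan.served == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_in_damage_fleet_and_resources(self, seed):
        """Halving route damage, shrinking the fleet, or cutting stocks
        never improves the objective."""
        spec = GeneratorSpec(
            n_affected=3,
            n_medical=2,
            casualty_range={"R": (3, 15), "G": (3, 20)},
            resource_range=(400, 600),
            eps_zero_mass=0.3,
            eps_disrupted_mass=0.0,  # stay in the passable regime
            seed=seed,
        )
        inst = generate(spec)
        groups = expand_groups(inst)
        assignment = [(g.id % 2) + 1 for g in groups]
        base = evaluate(assignment, inst, inst.scenarios[0]).objective

        import dataclasses

        from casevac.network import Route

        softer = dataclasses.replace(
            inst,
            routes={
                k: Route(r.from_affected, r.to_medical, r.d, r.epsilon / 2)
                for k, r in inst.routes.items()
            },
        )
        assert evaluate(assignment, softer, softer.scenarios[0]).objective <= base

        small_fleet = dataclasses.replace(inst, fleet=Fleet(Q_h=2, Q_n=1))
        assert evaluate(assignment, small_fleet, inst.scenarios[0]).objective >= base

        from casevac.network import MedicalPoint

        poor = dataclasses.replace(
            inst, medical=[MedicalPoint(m.id, m.Q / 20) for m in inst.medical]
        )
        assert evaluate(assignment, poor, inst.scenarios[0]).objective >= base


class TestScenarioSweep:
    def test_single_scenario_matches_evaluate(self, single_route_instance):
        sweep = evaluate_under_all_scenarios([1], single_route_instance)
        direct = evaluate([1], single_route_instance, single_route_instance.scenarios[0])
        assert sweep.per_scenario == {1: direct.objective}
        assert sweep.worst_case == sweep.mean == direct.objective

    def test_failure_scenario_is_never_better(self, two_by_two_instance):
        assignment = [1, 1, 2, 2]
        sweep = evaluate_under_all_scenarios(assignment, two_by_two_instance)
        assert sweep.per_scenario[2] >= sweep.per_scenario[1]
        assert sweep.per_scenario[3] >= sweep.per_scenario[1]
        assert sweep.worst_case == max(sweep.per_scenario.values())

    def test_dispatch_table_covers_all_casualties(self, two_by_two_instance):
        result = evaluate([1, 1, 2, 2], two_by_two_instance, two_by_two_instance.scenarios[0])
        table = dispatch_table(result)
        assert table["batch_size"].sum() == two_by_two_instance.total_casualties()
        assert set(table.columns) >= {"group", "medical_point", "mode", "trip", "batch_size", "wait", "death_probability"}
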