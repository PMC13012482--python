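"""MILP formulation, solver contract, oracle equivalence, evaluation."""

import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from milkpool import (
    BottleRecord,
    PoolingConfig,
    brute_force_oracle,
    build_model,
    evaluate_assignment,
    solve,
    suggest_n_pools,
)
from milkpool.exceptions import (
    EnumerationBoundError,
    InfeasibleError,
    ReferentialError,
    ValidationError,
)
from tests.conftest import make_random_instance


def _bottle(bid, donor, volume, protein=1.0, energy=70.0, arrival_day=5):
    return BottleRecord(
        bottle_id=bid, donor_id=donor, expression_date=date(2023, 1, 1),
        arrival_date=date(2023, 1, 1) + timedelta(days=arrival_day),
        volume_ml=volume, days_postpartum=30,
        crude_protein=protein, energy=energy,
    )


class TestBuildAndSolve:
    def test_on_target_bottles_reach_zero_deviation(self, zero_deviation_bottles, config):
        model = build_model(zero_deviation_bottles, config)
        assignment = solve(model)
        assert assignment.status == "optimal"
        assert assignment.objective_total == pytest.approx(0.0, abs=1e-9)
        pool = assignment.pools[0]
        assert 2000.0 <= pool.total_volume_ml <= 2050.0
        assert 3 <= len(pool.donor_ids) <= 5

    def test_unit_deviation_of_ten_percent_protein_excess(self):
        """A 2000 mL pool at 1.1 g/100 mL resolves to 2 g protein-mass
        deviation, i.e. a normalised deviation of 0.10."""
        bottles = [_bottle(f"B{i}", f"D{i}", 500.0, protein=1.1) for i in range(4)]
        model = build_model(bottles, PoolingConfig(n_pools=1, max_donors=4))
        assignment = solve(model)
        assert assignment.dev_protein["P000"] == pytest.approx(0.10, abs=1e-9)
        assert assignment.linear_objective == pytest.approx(0.10, abs=1e-9)

    def test_missing_composition_rejected(self, config):
        bottles = [
            BottleRecord(
                "B1", "D1", date(2023, 1, 1), date(2023, 1, 2), 600.0, days_postpartum=20
            )
        ]
        with pytest.raises(ValidationError):
            build_model(bottles, config)

    def test_undersupplied_model_warns_then_reports_volume_infeasibility(self, config):
        bottles = [_bottle(f"B{i}", f"D{i}", 300.0) for i in range(4)]  # 1200 mL
        with pytest.warns(UserWarning, match="likely infeasible"):
            model = build_model(bottles, config)
        assignment = solve(model)
        assert assignment.status == "infeasible"
        assert assignment.infeasible_reason == "volume"

    def test_too_few_donors_reports_donor_count_infeasibility(self):
        bottles = [_bottle(f"B{i}", f"D{i % 2}", 510.0) for i in range(4)]
        model = build_model(bottles, PoolingConfig(n_pools=1, min_donors=3))
        assignment = solve(model)
        assert assignment.status == "infeasible"
        assert assignment.infeasible_reason == "donor-count"
        with pytest.raises(InfeasibleError, match="donor-count"):
            solve(model, raise_on_infeasible=True)

    def test_relaxing_max_donors_never_hurts(self):
        bottles = make_random_instance(21, n_bottles=12, n_donors=5)
        cfg4 = PoolingConfig(n_pools=1, min_donors=3, max_donors=4, priority_weight=0.0)
        cfg5 = cfg4.replace(max_donors=5)
        a4 = solve(build_model(bottles, cfg4))
        a5 = solve(build_model(bottles, cfg5))
        assert a5.linear_objective <= a4.linear_objective + 1e-9

    def test_expiry_priority_breaks_deviation_ties_toward_urgent_bottles(self):
        """Two interchangeable donor triples at the target; the one closer
        to expiry must be chosen."""
        urgent = [_bottle(f"U{i}", f"DU{i}", 680.0, arrival_day=0) for i in range(3)]
        fresh = [_bottle(f"F{i}", f"DF{i}", 680.0, arrival_day=80) for i in range(3)]
        model = build_model(urgent + fresh, PoolingConfig(n_pools=1))
        assignment = solve(model)
        chosen = {b.bottle_id for b in assignment.members["P000"]}
        assert chosen == {"U0", "U1", "U2"}

    def test_suggest_n_pools_floor_rule(self, config):
        bottles = [_bottle(f"B{i}", f"D{i}", 700.0) for i in range(6)]  # 4200 mL
        assert suggest_n_pools(bottles, config) == 2


class TestOracle:
    def test_bound_refusal(self, config):
        bottles = [_bottle(f"B{i}", f"D{i}", 300.0) for i in range(15)]
        with pytest.raises(EnumerationBoundError):
            brute_force_oracle(bottles, config)

    def test_unique_feasible_assignment_is_returned(self):
        bottles = [_bottle(f"B{i}", f"D{i}", 505.0, protein=1.2) for i in range(4)]
        cfg = PoolingConfig(n_pools=1, min_donors=4, max_donors=4, priority_weight=0.0)
        obj, members = brute_force_oracle(bottles, cfg)
        assert {b.bottle_id for b in members["P000"]} == {f"B{i}" for i in range(4)}
        # 2020 mL at +0.2 g/100 mL -> 4.04 g over; normalised by 20 g
        assert obj == pytest.approx(4.04 / 20.0 + abs(70 - 70), abs=1e-9)

    def test_zero_deviation_instance(self, zero_deviation_bottles, config):
        obj, _ = brute_force_oracle(zero_deviation_bottles, config)
        assert obj == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_solver_matches_enumeration(self, seed):
        bottles = make_random_instance(seed, n_bottles=10, n_donors=4)
        cfg = PoolingConfig(n_pools=1, min_donors=2, max_donors=4, priority_weight=0.0)
        oracle_obj, _ = brute_force_oracle(bottles, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignment = solve(build_model(bottles, cfg))
        if oracle_obj is None:
            assert assignment.status == "infeasible"
        else:
            assert assignment.linear_objective == pytest.approx(oracle_obj, abs=1e-6)


class TestEvaluation:
    def test_pool_exactly_at_targets_has_zero_deviations(self):
        members = {"P0": [_bottle("B1", "D1", 2000.0, 1.0, 70.0)]}
        a = evaluate_assignment(members, None, PoolingConfig(min_donors=1))
        assert a.dev_protein["P0"] == 0.0 and a.dev_energy["P0"] == 0.0

    def test_known_deviations_ten_percent_each(self):
        members = {"P0": [_bottle("B1", "D1", 2000.0, 1.1, 63.0)]}
        a = evaluate_assignment(members, None, PoolingConfig(min_donors=1))
        assert a.dev_protein["P0"] == pytest.approx(0.10)
        assert a.dev_energy["P0"] == pytest.approx(0.10)
        assert a.objective_total == pytest.approx(0.20)

    def test_reevaluation_reproduces_solver_objective(self):
        bottles = make_random_instance(8, n_bottles=10, n_donors=4)
        cfg = PoolingConfig(n_pools=1, min_donors=2, max_donors=4, priority_weight=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignment = solve(build_model(bottles, cfg))
        again = evaluate_assignment(assignment, None, cfg)
        assert again.linear_objective == pytest.approx(
            assignment.linear_objective, abs=1e-6
        )

    def test_unknown_bottle_in_contents_is_referential_error(self):
        members = {"P0": [_bottle("B1", "D1", 2000.0)]}
        contents = pd.DataFrame(
            {"bottle_id": ["other"], "protein": [1.0], "energy": [70.0]}
        )
        with pytest.raises(ReferentialError, match="B1"):
            evaluate_assignment(members, contents, PoolingConfig(min_donors=1))

    def test_mass_and_concentration_normalisations_agree(self):
        """|pooled mass - T V| / (T V) equals |c_pool - T| / T for any pool."""
        rng = np.random.default_rng(14)
        for _ in range(20):
            vols = rng.uniform(100, 600, size=5)
            prot = rng.uniform(0.6, 1.4, size=5)
            V = vols.sum()
            c_pool = np.dot(vols, prot) / V
            mass = np.dot(vols / 100.0, prot)
            lhs = abs(mass - 1.0 * V / 100.0) / (1.0 * V / 100.0)
            rhs = abs(c_pool - 1.0) / 1.0
            assert lhs == pytest.approx(rhs, rel=1e-12)
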