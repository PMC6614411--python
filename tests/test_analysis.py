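"""FBA, FVA, doubling time and function tasks against independent oracles."""

import math

import numpy as np
import pytest

from conftest import make_model
from fluxcondition.analysis import (
    FLUX_EPS,
    FunctionTask,
    doubling_time,
    fba,
    fva,
    run_function_task,
)
from oracles import lp_max_by_vertex_enumeration


class TestFBA:
    def test_bottleneck_sets_optimum(self, linear_chain):
        sol = fba(linear_chain)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0)

    def test_internal_bound_can_be_the_bottleneck(self, linear_chain):
        model = linear_chain.with_bounds({"R_ab": (0, 4)})
        assert fba(model).objective_value == pytest.approx(4.0)

    def test_steady_state_and_bounds_hold(self, toy_model):
        sol = fba(toy_model, minimize_l1=True)
        S = toy_model.stoichiometric_matrix()
        v = np.array([sol[r.id] for r in toy_model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-7
        lb, ub = toy_model.bounds()
        assert np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)

    def test_matches_vertex_enumeration_oracle(self):
        """FBA optimum equals brute-force vertex enumeration on a small
        network with a branch and a reversible step."""
        model = make_model(
            [
                ("R_in", {"A": 1}, 0, 7),
                ("R_ab", {"A": -1, "B": 1}, -5, 20),
                ("R_ac", {"A": -1, "C": 1}, 0, 4),
                ("R_cb", {"C": -1, "B": 1}, 0, 3),
                ("R_out", {"B": -1}, 0, 6),
                ("R_alt", {"C": -1}, 0, 2),
            ],
            objective="R_out",
        )
        sol = fba(model)
        c = np.zeros(len(model.reactions))
        c[model.reaction_index("R_out")] = 1.0
        lb, ub = model.bounds()
        expected = lp_max_by_vertex_enumeration(c, model.stoichiometric_matrix(), lb, ub)
        assert sol.objective_value == pytest.approx(expected, abs=1e-8)

    def test_matches_independent_glpk_solver(self, toy_model, tmp_path):
        """Cross-check the toy model optimum against cobra + GLPK."""
        cobra = pytest.importorskip("cobra")
        from fluxcondition.sbml_io import write_sbml

        path = tmp_path / "toy.xml"
        write_sbml(toy_model, str(path))
        cmodel = cobra.io.read_sbml_model(str(path))
        cmodel.solver = "glpk"
        ours = fba(toy_model).objective_value
        assert cmodel.optimize().objective_value == pytest.approx(ours, rel=1e-7)

    def test_infeasible_returned_not_raised(self, linear_chain):
        model = linear_chain.with_bounds({"R_in": (0, 1), "R_out": (5, 10)})
        sol = fba(model)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_optimum_invariant_under_reaction_reordering(self, toy_model):
        from fluxcondition.model import MetabolicModel

        shuffled = MetabolicModel(
            id=toy_model.id,
            metabolites=list(toy_model.metabolites),
            reactions=list(reversed(toy_model.reactions)),
            compartments=list(toy_model.compartments),
            objective_reaction_id=toy_model.objective_reaction_id,
        )
        assert fba(shuffled).objective_value == pytest.approx(
            fba(toy_model).objective_value, rel=1e-9
        )

    def test_min_l1_reaches_same_optimum_with_smaller_total_flux(self, toy_model):
        plain = fba(toy_model)
        sparse = fba(toy_model, minimize_l1=True)
        assert sparse.objective_value == pytest.approx(plain.objective_value, rel=1e-7)
        total = lambda s: sum(abs(v) for v in s.fluxes.values())
        assert total(sparse) <= total(plain) + 1e-6


class TestDoublingTime:
    def test_ln2_growth_gives_one_hour(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_hepatocyte_scale_growth_rate(self):
        assert doubling_time(0.0425) == pytest.approx(16.31, abs=0.01)

    @pytest.mark.parametrize("mu", [0.0, -1.0])
    def test_nonpositive_growth_rejected(self, mu):
        with pytest.raises(ValueError):
            doubling_time(mu)

    def test_monotone_in_substrate_uptake(self, toy_model):
        """Growth accelerates (doubling time falls) as glucose uptake rises."""
        times = []
        for uptake in [2.0, 5.0, 10.0]:
            model = toy_model.with_bounds({"EX_glc_e": (-uptake, 1000.0)})
            times.append(doubling_time(fba(model).objective_value))
        assert times[0] > times[1] > times[2]


class TestFVA:
    def test_parallel_routes_fully_interchangeable(self, diamond_model):
        result = fva(diamond_model, optimality_fraction=1.0)
        assert result["R2a"] == (pytest.approx(0.0, abs=1e-7), pytest.approx(10.0))
        assert result["R2b"] == (pytest.approx(0.0, abs=1e-7), pytest.approx(10.0))

    def test_linear_chain_fully_determined(self, linear_chain):
        result = fva(linear_chain, optimality_fraction=1.0)
        for rxn_id, (lo, hi) in result.ranges.items():
            assert hi - lo < 1e-6

    def test_released_objective_gives_zero_range_for_blocked(self):
        model = make_model(
            [
                ("R_in", {"A": 1}, 0, 10),
                ("R_out", {"A": -1}, 0, 10),
                ("R_blocked", {"B": -1, "C": 1}, 0, 10),
            ],
            objective="R_out",
        )
        result = fva(model, optimality_fraction=0.0)
        assert result["R_blocked"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))

    def test_ranges_nest_monotonically_in_fraction(self, toy_model):
        loose = fva(toy_model, optimality_fraction=0.0)
        tight = fva(toy_model, optimality_fraction=1.0)
        for rxn_id in loose.ranges:
            lo0, hi0 = loose[rxn_id]
            lo1, hi1 = tight[rxn_id]
            assert lo0 <= lo1 + 1e-6 and hi1 <= hi0 + 1e-6

    def test_fba_flux_lies_inside_full_optimality_ranges(self, toy_model):
        sol = fba(toy_model, minimize_l1=True)
        result = fva(toy_model, optimality_fraction=1.0)
        for rxn_id, (lo, hi) in result.ranges.items():
            assert lo - 1e-6 <= sol[rxn_id] <= hi + 1e-6

    def test_invalid_fraction_rejected(self, toy_model):
        with pytest.raises(ValueError):
            fva(toy_model, optimality_fraction=1.5)


class TestFunctionTasks:
    def _gluconeogenesis_task(self):
        # force lactate uptake, shut glucose and fat import, demand export
        return FunctionTask(
            name="gluconeogenesis",
            forced_exchanges={
                "EX_glc_e": (0.0, 1000.0),
                "EX_lac_e": (-10.0, -1.0),
                "EX_fa_e": (0.0, 0.0),
            },
            target_reaction="EX_glc_e",
            min_target_flux=FLUX_EPS,
        )

    def test_gluconeogenesis_feasible_on_toy_model(self, toy_model):
        result = run_function_task(toy_model, self._gluconeogenesis_task())
        assert result.passed
        assert result.achieved_flux > 0

    def test_removing_pepck_breaks_gluconeogenesis(self, toy_model):
        crippled = toy_model.with_bounds({"PEPCK": (0.0, 0.0)})
        result = run_function_task(crippled, self._gluconeogenesis_task())
        assert not result.passed

    def test_zero_threshold_always_passes_on_feasible_model(self, toy_model):
        task = FunctionTask(name="trivial", target_reaction="DM_biomass", min_target_flux=0.0)
        assert run_function_task(toy_model, task).passed

    def test_original_bounds_restored(self, toy_model):
        before = toy_model.reaction("EX_lac_e").lower_bound
        run_function_task(toy_model, self._gluconeogenesis_task())
        assert toy_model.reaction("EX_lac_e").lower_bound == before

    def test_unknown_reaction_rejected(self, toy_model):
        task = FunctionTask(name="bad", target_reaction="NOPE")
        with pytest.raises(ValueError, match="NOPE"):
            run_function_task(toy_model, task)
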