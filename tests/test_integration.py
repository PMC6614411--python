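"""Expression-to-reaction mapping, GIMME and E-flux."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_model
from fluxcondition.analysis import fba
from fluxcondition.integration import (
    ExpressionMatrix,
    eflux,
    gimme,
    gimme_threshold,
    reaction_expression,
)


@pytest.fixture()
def chain_gpr():
    """in -> A -(gMid)-> B -(gBio)-> C -> drain, uptake cap 10."""
    return make_model(
        [
            ("R_in", {"A": 1}, 0, 10),
            ("R_mid", {"A": -1, "B": 1}, 0, 1000, "gMid"),
            ("R_fin", {"B": -1, "C": 1}, 0, 1000, "gBio"),
            ("R_bio", {"C": -1}, 0, 1000),
        ],
        objective="R_bio",
    )


class TestReactionExpression:
    def test_and_or_rules(self, toy_model):
        scores = {g: 1.0 for g in toy_model.genes}
        scores["SYNG0101"], scores["SYNG0102"] = 4.0, 10.0  # HEX: OR
        scores["SYNG0201"], scores["SYNG0202"], scores["SYNG0203"] = 4.0, 10.0, 6.0  # PDH: AND
        rx = reaction_expression(toy_model, scores)
        assert rx["HEX"] == 10.0
        assert rx["PDH"] == 4.0

    def test_no_gpr_maps_to_absent(self, toy_model):
        rx = reaction_expression(toy_model, {g: 1.0 for g in toy_model.genes})
        assert rx["EX_glc_e"] is None
        assert rx["ATPM"] is None

    def test_unmeasured_genes(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gBio": 5.0})
        assert rx["R_mid"] is None
        assert rx["R_fin"] == 5.0

    def test_negative_scores_rejected(self, chain_gpr):
        with pytest.raises(ValueError):
            reaction_expression(chain_gpr, {"gMid": -1.0})


class TestGimme:
    def test_all_above_threshold_gives_zero_inconsistency(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gMid": 10.0, "gBio": 10.0})
        cond, dist = gimme(chain_gpr, rx, threshold=5.0, required_fraction=0.9)
        assert cond.inconsistency == pytest.approx(0.0, abs=1e-9)
        assert dist.objective_value >= 0.9 * fba(chain_gpr).objective_value - 1e-6

    def test_worked_chain_example(self, chain_gpr):
        """Sole route scored 2 against threshold 5 at 90% of optimum 10:
        inconsistency (5-2) x 9 = 27."""
        rx = reaction_expression(chain_gpr, {"gMid": 2.0, "gBio": 10.0})
        cond, dist = gimme(chain_gpr, rx, threshold=5.0, required_fraction=0.9)
        assert cond.inconsistency == pytest.approx(27.0, rel=1e-6)
        assert dist["R_mid"] == pytest.approx(9.0, rel=1e-6)

    def test_penalized_bypassable_route_avoided(self):
        """With a penalty-free bypass available, the lowly expressed
        reaction carries zero flux."""
        model = make_model(
            [
                ("R_in", {"A": 1}, 0, 10),
                ("R_low", {"A": -1, "B": 1}, 0, 1000, "gLow"),
                ("R_alt", {"A": -1, "B": 1}, 0, 1000, "gAlt"),
                ("R_bio", {"B": -1}, 0, 1000),
            ],
            objective="R_bio",
        )
        rx = reaction_expression(model, {"gLow": 1.0, "gAlt": 9.0})
        _, dist = gimme(model, rx, threshold=5.0, required_fraction=1.0)
        assert dist["R_low"] == pytest.approx(0.0, abs=1e-7)
        assert dist["R_alt"] == pytest.approx(10.0, rel=1e-6)

    def test_absent_reactions_carry_no_penalty(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gBio": 10.0})  # gMid unmeasured
        cond, _ = gimme(chain_gpr, rx, threshold=5.0, required_fraction=0.9)
        assert cond.inconsistency == pytest.approx(0.0, abs=1e-9)

    def test_inconsistency_monotone_in_required_fraction(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gMid": 2.0, "gBio": 10.0})
        values = [
            gimme(chain_gpr, rx, 5.0, frac)[0].inconsistency
            for frac in (0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_inconsistency_monotone_in_threshold(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gMid": 2.0, "gBio": 10.0})
        values = [
            gimme(chain_gpr, rx, thr, 0.9)[0].inconsistency
            for thr in (1.0, 3.0, 5.0, 8.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(0.0, abs=1e-9)  # threshold below every score

    def test_infeasible_required_fraction_reported(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gMid": 2.0, "gBio": 10.0})
        constrained = chain_gpr.with_bounds({"R_bio": (0, 0)})
        with pytest.raises(RuntimeError):
            gimme(constrained, rx, 5.0, 0.9)

    def test_threshold_percentile_helper(self, toy_model, toy_expression):
        expr, _ = toy_expression
        rx = reaction_expression(toy_model, expr.condition_mean(2))
        thr = gimme_threshold(rx, 25.0)
        scores = sorted(v for v in rx.values() if v is not None)
        below = sum(s < thr for s in scores)
        assert below <= 0.25 * len(scores) + 1


class TestEflux:
    def test_zero_expression_closes_reaction(self, chain_gpr):
        rx = reaction_expression(chain_gpr, {"gMid": 0.0, "gBio": 10.0})
        cond = eflux(chain_gpr, rx)
        assert cond.bounds["R_mid"] == (0.0, 0.0)
        sol = fba(cond.apply(chain_gpr))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_uniform_expression_is_identity(self, toy_model):
        rx = reaction_expression(toy_model, {g: 7.0 for g in toy_model.genes})
        cond = eflux(toy_model, rx)
        for rxn_id, (lb, ub) in cond.bounds.items():
            rxn = toy_model.reaction(rxn_id)
            assert (lb, ub) == (rxn.lower_bound, rxn.upper_bound)
        assert fba(cond.apply(toy_model)).objective_value == pytest.approx(
            fba(toy_model).objective_value, rel=1e-9
        )

    def test_scaled_bound_halves_optimum_only_when_binding(self, chain_gpr):
        # scaled bound 0.5*1000 = 500 > bottleneck 10: optimum unchanged
        rx = reaction_expression(chain_gpr, {"gMid": 5.0, "gBio": 10.0})
        sol = fba(eflux(chain_gpr, rx).apply(chain_gpr))
        assert sol.objective_value == pytest.approx(10.0, rel=1e-9)
        # with capacity 16 the scaled bound 8 < 10 binds and halves... to 8
        tight = chain_gpr.with_bounds({"R_mid": (0, 16)})
        sol2 = fba(eflux(tight, rx).apply(tight))
        assert sol2.objective_value == pytest.approx(8.0, rel=1e-9)

    def test_optimum_never_exceeds_base(self, toy_model, toy_expression):
        expr, _ = toy_expression
        base = fba(toy_model).objective_value
        for group, day in [(1, 4), (2, None), (5, 14)]:
            rx = reaction_expression(toy_model, expr.condition_mean(group, day))
            sol = fba(eflux(toy_model, rx).apply(toy_model))
            assert sol.objective_value <= base + 1e-8

    def test_exchanges_keep_original_bounds(self, toy_model, toy_expression):
        expr, _ = toy_expression
        rx = reaction_expression(toy_model, expr.condition_mean(5, 14))
        cond = eflux(toy_model, rx)
        for rxn in toy_model.reactions:
            if rxn.boundary:
                assert rxn.id not in cond.bounds

    def test_stoichiometry_untouched_by_both_methods(self, toy_model, toy_expression):
        expr, _ = toy_expression
        rx = reaction_expression(toy_model, expr.condition_mean(3, 4))
        scaled = eflux(toy_model, rx).apply(toy_model)
        assert np.array_equal(
            scaled.stoichiometric_matrix(), toy_model.stoichiometric_matrix()
        )

    def test_all_absent_rejected(self, toy_model):
        with pytest.raises(ValueError):
            eflux(toy_model, {r.id: None for r in toy_model.reactions})


class TestExpressionMatrix:
    def test_duplicate_genes_rejected(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["g1", "g1"], columns=["s1"])
        meta = pd.DataFrame({"sample": ["s1"], "group": [1], "day": [4], "replicate": [1]})
        with pytest.raises(ValueError):
            ExpressionMatrix(values, meta)

    def test_missing_metadata_rejected(self):
        values = pd.DataFrame([[1.0]], index=["g1"], columns=["s1"])
        meta = pd.DataFrame({"sample": ["s1"], "group": [1]})
        with pytest.raises(ValueError):
            ExpressionMatrix(values, meta)

    def test_condition_mean_unlogs_before_averaging(self):
        values = pd.DataFrame(
            {"s1": [2.0], "s2": [4.0]}, index=["g1"]
        )
        meta = pd.DataFrame(
            {"sample": ["s1", "s2"], "group": [1, 1], "day": [4, 4], "replicate": [1, 2]}
        )
        expr = ExpressionMatrix(values, meta)
        # linear mean of 2^2 and 2^4, not 2^(mean of logs)
        assert expr.condition_mean(1, 4)["g1"] == pytest.approx((4 + 16) / 2)

    def test_tsv_roundtrip(self, toy_expression, tmp_path):
        expr, _ = toy_expression
        vp, mp = tmp_path / "v.tsv", tmp_path / "m.tsv"
        expr.write_tsv(vp, mp)
        back = ExpressionMatrix.read_tsv(vp, mp)
        assert np.allclose(back.values.to_numpy(), expr.values.to_numpy())
        assert list(back.sample_meta["group"]) == list(expr.sample_meta["group"])
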