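"""Consensus sets, subsystem flux tables, projective decomposition,
clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_model
from fluxcondition.comparison import (
    active_reactions,
    cluster_subsystems,
    consensus_active_set,
    projective_decompose,
    subsystem_flux_table,
)


class TestActiveReactions:
    def test_threshold_rule(self):
        table = pd.DataFrame(
            {"c1": [1e-7, 0.0], "c2": [1e-5, 0.0], "c3": [0.3, 0.0], "c4": [0.0, 0.0]},
            index=["r1", "r2"],
        )
        counts = active_reactions(table, eps=1e-6)
        assert counts["r1"] == 2
        assert counts["r2"] == 0

    def test_matches_hand_enumeration_on_planted_pattern(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            rng.choice([0.0, 1e-9, 0.5, -2.0], size=(10, 8)),
            index=[f"r{i}" for i in range(10)],
            columns=[f"c{j}" for j in range(8)],
        )
        counts = active_reactions(table, eps=1e-6)
        for rxn_id in table.index:
            expected = sum(abs(v) >= 1e-6 for v in table.loc[rxn_id])
            assert counts[rxn_id] == expected

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError):
            active_reactions(pd.DataFrame({"c": [1.0]}), eps=0)


class TestConsensus:
    def _counts(self, mapping):
        return pd.Series(mapping)

    def test_majority_in_both_methods_included(self):
        cons = consensus_active_set(
            self._counts({"r": 5}), self._counts({"r": 5}), n_conditions=8
        )
        assert "r" in cons

    def test_majority_in_one_method_only_excluded(self):
        cons = consensus_active_set(
            self._counts({"r": 8}), self._counts({"r": 3}), n_conditions=8
        )
        assert "r" not in cons

    def test_strict_majority_boundary(self):
        cons = consensus_active_set(
            self._counts({"r": 4}), self._counts({"r": 4}), n_conditions=8
        )
        assert "r" not in cons  # 4 of 8 is not a strict majority

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            consensus_active_set(
                self._counts({"r1": 5}), self._counts({"r2": 5}), n_conditions=8
            )

    def test_monotone_in_eps(self, toy_model, toy_expression):
        """Raising the activity threshold never adds consensus members."""
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.normal(scale=1e-4, size=(20, 9)),
            index=[f"r{i}" for i in range(20)],
        )
        previous = None
        for eps in (1e-6, 1e-5, 1e-4):
            counts = active_reactions(table, eps)
            members = set(
                consensus_active_set(counts, counts, table.shape[1], eps).reactions
            )
            if previous is not None:
                assert members <= previous
            previous = members


class TestSubsystemTable:
    def _two_condition_setup(self):
        model = make_model(
            [
                ("r1", {"A": -1, "B": 1}, -10, 10, "", "S1"),
                ("r2", {"B": -1, "A": 1}, -10, 10, "", "S1"),
                ("r3", {"A": -1}, 0, 10, "", "S2"),
            ]
        )
        table = pd.DataFrame(
            {"control": [1.0, 1.0, 2.0], "cond": [2.0, -4.0, 2.0]},
            index=["r1", "r2", "r3"],
        )
        counts = active_reactions(table, 1e-6)
        cons = consensus_active_set(counts, counts, 2, 1e-6)
        return model, cons, table

    def test_mean_absolute_flux_minus_control(self):
        model, cons, table = self._two_condition_setup()
        out = subsystem_flux_table(model, cons, table, control="control")
        # S1: mean(|2|, |-4|) = 3, control mean(1,1) = 1 -> 2
        assert out.loc["S1", "cond"] == pytest.approx(2.0)
        assert "control" not in out.columns

    def test_condition_equal_to_control_gives_zero_column(self):
        model, cons, _ = self._two_condition_setup()
        table = pd.DataFrame(
            {"control": [1.0, -2.0, 3.0], "same": [-1.0, 2.0, 3.0]},
            index=["r1", "r2", "r3"],
        )
        out = subsystem_flux_table(model, cons, table, control="control")
        assert np.allclose(out["same"], 0.0)

    def test_reaction_order_permutation_invariant(self):
        model, cons, table = self._two_condition_setup()
        out1 = subsystem_flux_table(model, cons, table, control="control")
        out2 = subsystem_flux_table(
            model, cons, table.iloc[::-1], control="control"
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_control_rejected(self):
        model, cons, table = self._two_condition_setup()
        with pytest.raises(ValueError):
            subsystem_flux_table(model, cons, table, control="nope")


class TestProjectiveDecomposition:
    def test_all_ones_is_fixed_point(self):
        X = pd.DataFrame(np.ones((3, 4)))
        res = projective_decompose(X)
        assert res.converged
        assert np.allclose(res.core.to_numpy(), 1.0)
        assert np.allclose(res.row_factors, 1.0)
        assert np.allclose(res.col_factors, 1.0)

    def test_rank_one_matrix_recovers_outer_product(self):
        X = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]])
        res = projective_decompose(X)
        assert res.converged
        assert np.allclose(res.core.to_numpy(), 1.0, atol=1e-8)
        assert res.row_factors.iloc[1] / res.row_factors.iloc[0] == pytest.approx(2.0)
        assert res.col_factors.iloc[1] / res.col_factors.iloc[0] == pytest.approx(2.0)

    def test_unit_rms_rows_and_columns(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.uniform(0.1, 5.0, size=(5, 8)))
        res = projective_decompose(X)
        assert res.converged
        core = res.core.to_numpy()
        assert np.allclose(np.sqrt(np.mean(core**2, axis=1)), 1.0, atol=1e-6)
        assert np.allclose(np.sqrt(np.mean(core**2, axis=0)), 1.0, atol=1e-6)

    def test_factorization_reproduces_input(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        X[X.abs() < 0.1] += 0.5  # keep entries comfortably nonzero
        res = projective_decompose(X)
        rebuilt = (
            np.diag(res.row_factors) @ res.core.to_numpy() @ np.diag(res.col_factors)
        )
        assert np.allclose(rebuilt, X.to_numpy(), rtol=1e-6)

    def test_signs_reattached(self):
        X = pd.DataFrame([[1.0, -2.0], [-3.0, 4.0]])
        res = projective_decompose(X)
        assert np.array_equal(np.sign(res.core.to_numpy()), np.sign(X.to_numpy()))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_positive_rescaling(self, seed):
        """The core is unchanged (up to tolerance) when rows/columns of the
        input are rescaled by arbitrary positive factors — the
        scale-invariance that motivates the method."""
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.uniform(0.5, 3.0, size=(4, 6)))
        r = rng.uniform(0.1, 10.0, size=4)
        c = rng.uniform(0.1, 10.0, size=6)
        Y = pd.DataFrame(np.diag(r) @ X.to_numpy() @ np.diag(c))
        res_x = projective_decompose(X)
        res_y = projective_decompose(Y)
        assert np.allclose(res_x.core.to_numpy(), res_y.core.to_numpy(), atol=1e-5)

    def test_core_entries_bounded(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.uniform(0.01, 100.0, size=(7, 9)))
        res = projective_decompose(X)
        bound = np.sqrt(min(X.shape))
        assert np.all(np.abs(res.core.to_numpy()) <= bound + 1e-6)

    def test_zero_row_rejected(self):
        X = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            projective_decompose(X)

    def test_nonconvergence_flagged(self):
        X = pd.DataFrame(np.random.default_rng(5).uniform(0.5, 2.0, size=(4, 4)))
        res = projective_decompose(X, tol=1e-15, max_iter=1)
        assert not res.converged


class TestClustering:
    def test_identical_rows_merge_first(self):
        X = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [50.0, 60.0]], index=["a", "b", "z"]
        )
        res = cluster_subsystems(X)
        assert res.linkage[0, 2] == pytest.approx(0.0)  # first merge at distance 0
        order = res.order
        assert abs(order.index("a") - order.index("b")) == 1

    def test_clear_pair_against_outlier_topology(self):
        X = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=["r1", "r2", "r3"]
        )
        res = cluster_subsystems(X)
        # ((r1,r2),r3): the close pair merges first, the outlier joins last
        assert set(res.linkage[0, :2]) == {0, 1}
        assert set(res.order) == {"r1", "r2", "r3"}
        assert res.order.index("r3") in (0, 2)
        assert "r1" in res.newick and res.newick.endswith(";")

    def test_single_row_trivial_tree(self):
        X = pd.DataFrame([[1.0, 2.0]], index=["only"])
        res = cluster_subsystems(X)
        assert res.order == ["only"]
        assert res.newick == "only;"

    def test_order_independent_of_input_row_order(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        res1 = cluster_subsystems(X)
        res2 = cluster_subsystems(X.iloc[::-1])
        assert res1.order == res2.order
        assert res1.newick == res2.newick

    def test_newick_parses_with_standard_tools(self):
        """The emitted tree is valid Newick (read back with scikit-bio)."""
        skbio = pytest.importorskip("skbio")
        X = pd.DataFrame(
            np.random.default_rng(4).normal(size=(5, 3)),
            index=["s1", "s2", "s3", "s4", "s5"],
        )
        res = cluster_subsystems(X)
        import io

        tree = skbio.TreeNode.read(io.StringIO(res.newick))
        assert {tip.name for tip in tree.tips()} == set(X.index)
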