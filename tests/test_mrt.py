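"""Multivariate regression tree: split search, growth, pruning, CV."""

import numpy as np
import pandas as pd
import pytest

from genecol.mrt import (
    TreeControl,
    best_categorical_split,
    best_numeric_split,
    cross_validate,
    grow_tree,
    leaf_profiles,
    prune_to_leaves,
    total_ss,
)
from oracles import brute_categorical_split, brute_numeric_split, group_ss


class TestTotalSS:
    def test_identical_rows_zero(self):
        assert total_ss(np.ones((5, 3))) == 0.0

    def test_two_point_example(self):
        assert total_ss(np.array([[0.0, 0.0], [2.0, 0.0]])) == pytest.approx(2.0)

    def test_equals_sum_of_column_centered_ss(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 4))
        percol = sum(((Y[:, j] - Y[:, j].mean()) ** 2).sum() for j in range(4))
        assert total_ss(Y) == pytest.approx(percol, rel=1e-12)


class TestNumericSplit:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(size=n)
        Y = rng.normal(size=(n, 3))
        rule = best_numeric_split(x, Y, min_leaf=1)
        oracle = brute_numeric_split(x, Y, min_leaf=1)
        assert rule is not None and oracle is not None
        assert rule.threshold == pytest.approx(oracle[0])
        assert rule.ss_reduction == pytest.approx(oracle[1], rel=1e-9)

    def test_perfect_separation_by_sign(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        Y = np.where(x[:, None] < 0, [0.0, 0.0], [5.0, 5.0])
        rule = best_numeric_split(x, Y, min_leaf=1)
        assert -1.0 < rule.threshold < 1.0
        between = group_ss(Y) - group_ss(Y[x < 0]) - group_ss(Y[x > 0])
        assert rule.ss_reduction == pytest.approx(between, rel=1e-12)

    def test_constant_response_returns_none(self):
        assert best_numeric_split(np.arange(6.0), np.ones((6, 2)), min_leaf=1) is None

    def test_single_predictor_value_returns_none(self):
        Y = np.random.default_rng(1).normal(size=(6, 2))
        assert best_numeric_split(np.ones(6), Y, min_leaf=1) is None

    def test_min_leaf_respected(self):
        x = np.arange(6.0)
        Y = np.diag(np.arange(6.0))  # pulls toward singleton splits
        rule = best_numeric_split(x, Y, min_leaf=3)
        assert rule is None or rule.threshold == pytest.approx(2.5)


class TestCategoricalSplit:
    def test_two_levels_single_partition(self):
        Y = np.array([[0.0], [0.1], [5.0], [5.2]])
        rule = best_categorical_split(["a", "a", "b", "b"], Y, min_leaf=1)
        assert rule.left_levels == frozenset({"a"})

    def test_outlier_level_singled_out(self):
        Y = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        rule = best_categorical_split(["u", "v", "w"], Y, min_leaf=1)
        # canonical form keeps the lexicographically smallest level left
        assert rule.left_levels == frozenset({"u", "v"})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(3, 7))
        levels = rng.choice([f"L{i}" for i in range(m)], size=14)
        while len(set(levels)) < 2:
            levels = rng.choice([f"L{i}" for i in range(m)], size=14)
        Y = rng.normal(size=(14, 3))
        rule = best_categorical_split(levels, Y, min_leaf=1)
        oracle = brute_categorical_split(levels, Y, min_leaf=1)
        assert rule.ss_reduction == pytest.approx(oracle[1], rel=1e-9)
        assert rule.left_levels == oracle[0]

    def test_heuristic_matches_exhaustive_on_most_8_level_fixtures(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            levels = rng.choice([f"L{i}" for i in range(8)], size=24)
            if len(set(levels)) < 8:
                hits += 1  # fixture degenerates to an easier case
                continue
            Y = rng.normal(size=(24, 3)) + 1.5 * rng.normal(size=(8, 3))[
                [int(l[1]) for l in levels]
            ]
            exact = best_categorical_split(levels, Y, min_leaf=1, max_exhaustive=12)
            heur = best_categorical_split(levels, Y, min_leaf=1, max_exhaustive=4)
            if heur is not None and np.isclose(
                heur.ss_reduction, exact.ss_reduction, rtol=1e-9
            ):
                hits += 1
        assert hits >= 95

    def test_single_level_returns_none(self):
        assert best_categorical_split(["a"] * 5, np.random.default_rng(0).normal(size=(5, 2))) is None


def _two_group_fixture(seed=0, n=30):
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n // 2)
    Y = pd.DataFrame(rng.normal(size=(n, 3)) + 4.0 * group[:, None])
    preds = pd.DataFrame({"clim": rng.normal(size=n) + 10.0 * group, "noise": rng.normal(size=n)})
    return Y, preds, group


class TestGrowTree:
    def test_two_groups_recovered_by_one_split(self):
        Y, preds, group = _two_group_fixture()
        tree = grow_tree(Y, preds, control=TreeControl(max_leaves=2))
        assert tree.n_leaves == 2
        assert tree.root.rule.predictor == "clim"
        a = tree.assignments().to_numpy()
        assert len(set(zip(a, group))) == 2  # perfect recovery

    def test_max_leaves_one_is_a_stump(self):
        Y, preds, _ = _two_group_fixture()
        tree = grow_tree(Y, preds, control=TreeControl(max_leaves=1))
        assert tree.n_leaves == 1
        assert tree.r_squared == 0.0

    def test_ss_conservation_at_every_split(self, pooled_matrix, climate_predictors):
        tree = grow_tree(pooled_matrix, climate_predictors, control=TreeControl(max_leaves=8))
        for nd in tree.split_order:
            assert nd.left.ss + nd.right.ss + nd.rule.ss_reduction == pytest.approx(
                nd.ss, abs=1e-9 * max(tree.total_ss, 1.0)
            )
        leaf_ss = sum(l.ss for l in tree.leaves())
        explained = sum(nd.rule.ss_reduction for nd in tree.split_order)
        assert leaf_ss + explained == pytest.approx(tree.total_ss, rel=1e-12)

    def test_r_squared_is_sum_of_split_fractions(self, pooled_matrix, climate_predictors):
        tree = grow_tree(pooled_matrix, climate_predictors, control=TreeControl(max_leaves=6))
        assert tree.r_squared == pytest.approx(
            sum(nd.rule.ss_fraction for nd in tree.split_order), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_univariate_tree_matches_sklearn_greedy_cart(self, seed):
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(seed)
        n = 30
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.DataFrame({"t": rng.normal(size=n) + 2.0 * (X["a"] > 0)})
        control = TreeControl(min_leaf=2, min_improvement_fraction=0.0, max_leaves=4)
        mine = grow_tree(y, X, control=control)
        sk = DecisionTreeRegressor(
            max_leaf_nodes=4, min_samples_leaf=2, random_state=0
        ).fit(X, y["t"])
        sk_leaves = sk.apply(X)
        my_leaves = mine.assignments().to_numpy()
        # identical partitions (leaf labels may differ)
        pairs = set(zip(my_leaves, sk_leaves))
        assert len(pairs) == len(set(my_leaves)) == len(set(sk_leaves))

    def test_multivariate_tree_matches_sklearn_multioutput(self):
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(42)
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        Y = pd.DataFrame(rng.normal(size=(n, 3)) + 2.0 * (X[["a"]].to_numpy() > 0))
        control = TreeControl(min_leaf=2, min_improvement_fraction=0.0, max_leaves=5)
        mine = grow_tree(Y, X, control=control)
        sk = DecisionTreeRegressor(
            max_leaf_nodes=5, min_samples_leaf=2, random_state=0
        ).fit(X, Y)
        pairs = set(zip(mine.assignments().to_numpy(), sk.apply(X)))
        assert len(pairs) == mine.n_leaves

    def test_misaligned_tables_rejected(self):
        Y, preds, _ = _two_group_fixture()
        with pytest.raises(ValueError, match="misaligned"):
            grow_tree(Y, preds.iloc[:-1])

    def test_categorical_predictor_on_ecosystem_variants(self, small_trial, pooled_matrix):
        origins, truth, *_ = small_trial
        preds = origins.set_index("seedlot_id")[["ecosystem_variant"]].reindex(
            pooled_matrix.values.index
        )
        tree = grow_tree(
            pooled_matrix, preds, categorical=["ecosystem_variant"],
            control=TreeControl(max_leaves=3, max_exhaustive=8),
        )
        assert tree.n_leaves == 3
        assert all(nd.rule.kind == "categorical" for nd in tree.split_order)


@pytest.fixture(scope="module")
def grown_tree(pooled_matrix, climate_predictors):
    return grow_tree(
        pooled_matrix, climate_predictors,
        control=TreeControl(max_leaves=7, min_improvement_fraction=0.0),
    )


class TestPrune:
    @pytest.fixture
    def tree(self, grown_tree):
        return grown_tree

    def test_identity_at_current_size(self, tree):
        same = prune_to_leaves(tree, tree.n_leaves)
        assert same.n_leaves == tree.n_leaves
        assert same.r_squared == pytest.approx(tree.r_squared, rel=1e-12)
        pd.testing.assert_series_equal(same.assignments(), tree.assignments())

    def test_prune_to_root(self, tree):
        stump = prune_to_leaves(tree, 1)
        assert stump.n_leaves == 1
        assert stump.r_squared == 0.0

    def test_prune_equals_regrow(self, tree, pooled_matrix, climate_predictors):
        for size in (2, 4, 6):
            pruned = prune_to_leaves(tree, size)
            regrown = grow_tree(
                pooled_matrix, climate_predictors,
                control=TreeControl(max_leaves=size, min_improvement_fraction=0.0),
            )
            pd.testing.assert_series_equal(pruned.assignments(), regrown.assignments())
            assert pruned.r_squared == pytest.approx(regrown.r_squared, rel=1e-12)

    def test_out_of_range_rejected(self, tree):
        with pytest.raises(ValueError):
            prune_to_leaves(tree, 0)
        with pytest.raises(ValueError):
            prune_to_leaves(tree, tree.n_leaves + 1)


class TestLeafProfiles:
    def test_single_leaf_zero_profile_on_normalized_input(self, pooled_matrix, climate_predictors):
        tree = grow_tree(pooled_matrix, climate_predictors, control=TreeControl(max_leaves=1))
        prof = leaf_profiles(tree)
        assert np.allclose(prof.drop(columns="n_members"), 0.0, atol=1e-9)

    def test_two_equal_leaves_mirror(self):
        Y = pd.DataFrame({"t1": [-1.0, -1, 1, 1], "t2": [2.0, 2, -2, -2]})
        preds = pd.DataFrame({"x": [0.0, 0, 1, 1]})
        tree = grow_tree(Y, preds, control=TreeControl(min_leaf=1, max_leaves=2))
        prof = leaf_profiles(tree).drop(columns="n_members")
        assert np.allclose(prof.iloc[0], -prof.iloc[1])

    def test_weighted_mean_of_profiles_is_zero(self, pooled_matrix, climate_predictors):
        tree = grow_tree(pooled_matrix, climate_predictors, control=TreeControl(max_leaves=6))
        prof = leaf_profiles(tree)
        w = prof["n_members"].to_numpy()
        mean = (prof.drop(columns="n_members").to_numpy() * w[:, None]).sum(0) / w.sum()
        assert np.allclose(mean, 0.0, atol=1e-9)

    def test_planted_montane_syndrome_signs(self):
        # group "m" planted with late budbreak (+) and early budset (-)
        rng = np.random.default_rng(9)
        group = np.array(["m"] * 10 + ["o"] * 20)
        Y = pd.DataFrame(
            {
                "budbreak": rng.normal(0, 0.3, 30) + np.where(group == "m", 1.5, -0.75),
                "budset": rng.normal(0, 0.3, 30) + np.where(group == "m", -1.5, 0.75),
            }
        )
        preds = pd.DataFrame({"elev": np.where(group == "m", 1700.0, 600.0) + rng.normal(0, 50, 30)})
        tree = grow_tree(Y, preds, control=TreeControl(max_leaves=2))
        prof = leaf_profiles(tree)
        montane = prof[prof["n_members"] == 10].iloc[0]
        assert montane["budbreak"] > 0 and montane["budset"] < 0


class TestCrossValidate:
    def test_pure_noise_shows_no_spurious_gain(self):
        rng = np.random.default_rng(2)
        Y = pd.DataFrame(rng.normal(size=(40, 3)))
        preds = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        table = cross_validate(Y, preds, sizes=(1, 2, 3, 4), folds=5, reps=3, seed=1)
        for _, row in table[table["size"] > 1].iterrows():
            assert row["cv_error"] > 1.0 - 2 * row["se"]

    def test_planted_four_group_structure_selects_four(self):
        found = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            group = np.repeat([0, 1, 2, 3], 12)
            centers = np.array([[3, 0, -3], [-3, 3, 0], [0, -3, 3], [3, 3, 3]], float)
            Y = pd.DataFrame(rng.normal(size=(48, 3)) * 0.5 + centers[group])
            preds = pd.DataFrame({"x": group * 2.0 + rng.normal(0, 0.2, 48)})
            table = cross_validate(Y, preds, sizes=(1, 2, 3, 4, 5, 6), folds=6, reps=2, seed=seed)
            found.append(table.attrs["best_size"])
        assert sum(s == 4 for s in found) >= 4

    def test_leave_one_out_runs_and_agrees_in_direction(self):
        Y, preds, _ = _two_group_fixture(seed=5, n=16)
        loo = cross_validate(Y, preds, sizes=(1, 2, 3), folds=len(Y), reps=1, seed=0)
        kfold = cross_validate(Y, preds, sizes=(1, 2, 3), folds=4, reps=2, seed=0)
        assert loo.attrs["best_size"] == kfold.attrs["best_size"] == 2

    def test_unreachable_sizes_skipped_with_warning(self):
        Y = pd.DataFrame(np.random.default_rng(3).normal(size=(8, 2)))
        preds = pd.DataFrame({"x": np.arange(8.0)})
        with pytest.warns(UserWarning, match="exceed"):
            table = cross_validate(Y, preds, sizes=(1, 2, 30), folds=4, reps=1, seed=0)
        assert 30 not in set(table["size"])

    def test_rejects_single_fold(self):
        Y, preds, _ = _two_group_fixture()
        with pytest.raises(ValueError):
            cross_validate(Y, preds, folds=1)


def test_json_export_round_trips_structure(pooled_matrix, climate_predictors):
    import json

    tree = grow_tree(pooled_matrix, climate_predictors, control=TreeControl(max_leaves=4))
    payload = json.loads(tree.to_json())
    assert payload["n_leaves"] == tree.n_leaves
    assert payload["r_squared"] == pytest.approx(tree.r_squared)
    members = []

    def rec(node):
        if node["kind"] == "leaf":
            members.extend(node["members"])
        else:
            rec(node["left"])
            rec(node["right"])

    rec(payload["root"])
    assert sorted(members) == sorted(str(i) for i in pooled_matrix.values.index)
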