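"""Multivariate regression trees: fitting, CV sizing, Newick, sign reports."""

import numpy as np
import pandas as pd
import pytest

from snailheat.mrt import (
    cross_validate,
    first_split_r2,
    fit_mrt,
    newick_topology,
    primary_split_correlations,
    standardize_columns,
)

POPS = [str(i + 1) for i in range(7)]


def _frame(values, columns=None, index=None):
    values = np.asarray(values, dtype=float)
    index = index or [str(i + 1) for i in range(values.shape[0])]
    columns = columns or [f"v{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=index, columns=columns)


def exhaustive_best_split(X, Y, min_node_size=2):
    """Independent oracle: enumerate every (variable, midpoint) split."""
    Ymat = Y.to_numpy(dtype=float)

    def ss(rows):
        sub = Ymat[rows]
        return ((sub - sub.mean(axis=0)) ** 2).sum()

    total = ss(list(range(len(X))))
    best = None
    for var in X.columns:
        vals = np.sort(np.unique(X[var]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            cut = (lo + hi) / 2
            left = [i for i in range(len(X)) if X[var].iloc[i] <= cut]
            right = [i for i in range(len(X)) if X[var].iloc[i] > cut]
            if len(left) < min_node_size or len(right) < min_node_size:
                continue
            red = total - ss(left) - ss(right)
            if best is None or red > best[0] + 1e-12:
                best = (red, var, cut, tuple(left))
    return best


class TestFit:
    def test_constant_response_root_only(self):
        X = _frame(np.arange(14).reshape(7, 2), index=POPS)
        Y = _frame(np.ones((7, 3)), index=POPS)
        tree = fit_mrt(X, Y)
        assert tree.root.is_leaf
        assert tree.root.ss_reduction == 0.0

    def test_constant_explanatory_root_only(self):
        X = _frame(np.ones((7, 2)), index=POPS)
        Y = _frame(np.random.default_rng(0).normal(size=(7, 3)), index=POPS)
        assert fit_mrt(X, Y).root.is_leaf

    def test_planted_two_clusters_found_at_midpoint(self):
        X = _frame([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]], columns=["g"])
        Y = _frame(np.vstack([np.zeros((3, 2)), np.full((3, 2), 5.0)]))
        tree = fit_mrt(X, Y, standardize=False)
        assert tree.root.split_variable == "g"
        assert tree.root.split_value == pytest.approx(0.6)
        assert sorted(tree.leaf_partition()[0]) == ["1", "2", "3"]
        red, var, cut, left = exhaustive_best_split(X, Y)
        assert (var, cut) == (tree.root.split_variable, tree.root.split_value)
        assert tree.root.ss_reduction == pytest.approx(red)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_first_split_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = _frame(rng.normal(size=(n, 3)))
        Y = _frame(rng.normal(size=(n, 4)))
        tree = fit_mrt(X, Y, standardize=False)
        oracle = exhaustive_best_split(X, Y)
        if oracle is None:
            assert tree.root.is_leaf
        else:
            red, var, cut, left = oracle
            assert tree.root.split_variable == var
            assert tree.root.split_value == pytest.approx(cut)
            assert tuple(tree.root.left.members) == left

    def test_ss_conservation(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(7, 3)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        tree = fit_mrt(X, Y)
        leaf_ss = sum(lf.ss for lf in tree.leaves())
        reductions = sum(nd.ss_reduction for nd in tree.split_order)
        assert tree.root.ss == pytest.approx(leaf_ss + reductions)

    def test_invariance_to_row_order_and_rescaling(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(7, 3)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        base = fit_mrt(X, Y)

        perm = rng.permutation(7)
        t_perm = fit_mrt(X.iloc[perm], Y.iloc[perm])
        part = lambda t: frozenset(frozenset(g) for g in t.leaf_partition())
        assert part(base) == part(t_perm)

        X2 = X.copy()
        X2["v1"] = 100.0 * X2["v1"] + 3.0  # positive affine rescale
        t_scaled = fit_mrt(X2, Y)
        assert part(base) == part(t_scaled)
        assert t_scaled.root.split_variable == base.root.split_variable

    def test_min_node_size_respected(self):
        rng = np.random.default_rng(9)
        X = _frame(rng.normal(size=(7, 2)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        tree = fit_mrt(X, Y, min_node_size=2)
        assert all(len(lf.members) >= 2 for lf in tree.leaves())

    def test_standardization_gives_unit_variance_columns(self):
        rng = np.random.default_rng(1)
        Y = _frame(rng.normal(size=(7, 4)) * [1, 10, 100, 1000], index=POPS)
        scaled = standardize_columns(Y)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1)


class TestCrossValidation:
    def test_leave_one_out_is_seed_invariant(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(7, 3)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        a = cross_validate(X, Y, folds=10, reps=1000, seed=1)
        b = cross_validate(X, Y, folds=10, reps=1000, seed=99)
        assert a.cv_errors == b.cv_errors
        assert a.selected_size == b.selected_size
        assert a.folds_used == 7 and a.reps_used == 1

    def test_strong_signal_selects_multi_leaf_tree(self):
        rng = np.random.default_rng(0)
        X = _frame([[0.0], [0.1], [0.2], [0.3], [1.0], [1.1], [1.2]],
                   columns=["g"], index=POPS)
        Y = _frame(rng.normal(scale=0.3, size=(7, 4)), index=POPS)
        Y.iloc[4:] += 3.0
        cv = cross_validate(X, Y, seed=0)
        assert cv.selected_size >= 2
        assert cv.error_for(2) < cv.error_for(1)

    def test_pure_noise_selects_root(self):
        rng = np.random.default_rng(17)
        X = _frame(rng.normal(size=(7, 3)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        cv = cross_validate(X, Y, seed=0)
        assert cv.selected_size == 1

    def test_smaller_folds_use_randomized_partitions(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.normal(size=(8, 2)))
        Y = _frame(rng.normal(size=(8, 3)))
        cv = cross_validate(X, Y, folds=4, reps=5, seed=3)
        assert cv.folds_used == 4 and cv.reps_used == 5
        assert all(e >= 0 for e in cv.cv_errors)


class TestReports:
    def test_first_split_r2_perfect_separation(self):
        X = _frame([[0.0], [0.1], [1.0], [1.1]], columns=["g"])
        Y = _frame([[0, 0], [0, 0], [5, 5], [5, 5]])
        tree = fit_mrt(X, Y, standardize=False)
        assert first_split_r2(tree) == pytest.approx(1.0)

    def test_first_split_r2_hand_computed(self):
        X = _frame([[0.0], [0.1], [1.0], [1.1]], columns=["g"])
        Y = _frame([[0.0], [1.0], [4.0], [6.0]])
        tree = fit_mrt(X, Y, standardize=False)
        # SS_root = sum (y - 2.75)^2 = 22.75; SS_left = 0.5; SS_right = 2
        assert first_split_r2(tree) == pytest.approx((22.75 - 2.5) / 22.75)

    def test_first_split_r2_root_only_zero(self):
        X = _frame(np.ones((4, 1)))
        Y = _frame(np.ones((4, 2)))
        assert first_split_r2(fit_mrt(X, Y)) == 0.0

    def test_newick_root_only(self):
        X = _frame(np.ones((7, 1)), index=POPS)
        Y = _frame(np.ones((7, 2)), index=POPS)
        tree = fit_mrt(X, Y)
        assert newick_topology(tree) == "(1,2,3,4,5,6,7);"

    def test_newick_single_split_low_side_first(self):
        X = _frame([[0], [5], [0], [5], [5], [5], [5]], columns=["g"],
                   index=POPS)
        Y = _frame(np.vstack([[0, 0], [9, 9], [0, 0], [9, 9], [9, 9],
                              [9, 9], [9, 9]]), index=POPS)
        tree = fit_mrt(X, Y, standardize=False)
        assert newick_topology(tree) == "((1,3),(2,4,5,6,7));"
        assert newick_topology(tree, paper_style=True) == "(1,3),(2,4,5,6,7)"

    def test_newick_round_trips_to_same_partition(self):
        from skbio import TreeNode
        import io

        rng = np.random.default_rng(8)
        X = _frame(rng.normal(size=(7, 3)), index=POPS)
        Y = _frame(rng.normal(size=(7, 4)), index=POPS)
        tree = fit_mrt(X, Y)
        parsed = TreeNode.read(io.StringIO(newick_topology(tree)))
        assert {t.name for t in parsed.tips()} == set(POPS)

    def test_sign_report_plus_for_identical_response(self):
        X = _frame([[0.0], [0.1], [1.0], [1.1]], columns=["g"])
        Y = pd.DataFrame({"hsp70_mean": X["g"], "mav_tubule": -X["g"]},
                         index=X.index)
        tree = fit_mrt(X, Y, standardize=False)
        report = primary_split_correlations(tree, X, Y).set_index("response")
        assert report.loc["hsp70_mean", "sign"] == "+"
        assert report.loc["mav_tubule", "annotation"] == "i"

    def test_sign_recovery_under_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = np.linspace(0, 1, 7)
            X = _frame(g[:, None], columns=["g"], index=POPS)
            Y = pd.DataFrame({
                "hsp70_mean": g + rng.normal(0, 0.2, 7),
                "mav_digestive": -g + rng.normal(0, 0.2, 7),
            }, index=POPS)
            tree = fit_mrt(X, Y, standardize=False)
            if tree.root.is_leaf:
                continue
            rep = primary_split_correlations(tree, X, Y).set_index("response")
            if (rep.loc["hsp70_mean", "sign"] == "+"
                    and rep.loc["mav_digestive", "annotation"] == "i"):
                hits += 1
        assert hits >= 95

    def test_zero_variance_response_flagged(self):
        X = _frame([[0.0], [0.1], [1.0], [1.1]], columns=["g"])
        Y = pd.DataFrame({"hsp70_mean": X["g"], "mav_calcium": 2.0},
                         index=X.index)
        tree = fit_mrt(X, Y, standardize=False)
        rep = primary_split_correlations(tree, X, Y).set_index("response")
        assert rep.loc["mav_calcium", "sign"] == "undefined"
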