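"""Multivariate regression trees (MRT) with cross-validated size selection.

An MRT recursively bisects populations by thresholds on explanatory
variables (here: nucleotide diversity and PCoA axes of the divergence
matrices) so as to maximize, at each split, the reduction in the total
within-node sum of squared Euclidean distances of the multivariate response
(here: mean Hsp70 level and the three histopathology MAVs, optionally
standardized to unit column variance since the responses are on
incommensurate scales).

Tree size is chosen by v-fold cross-validation: per candidate size, the tree
is regrown on each training fold, held-out populations are dropped down the
tree, and the relative error is the summed held-out squared distance to the
assigned leaf centroid over the total response sum of squares.  With as many
folds as populations the procedure is leave-one-out and fully deterministic.
The default selection is the conservative 1-SE rule (smallest tree within
one standard error of the minimum); plain minimum-CV is available.

Reported alongside the fitted tree: the proportion of variance explained by
the first split, the leaf-group topology in Newick form, and the sign of the
Pearson correlation between the primary split variable and each response
(histopathology responses annotated "i"/"d" for improved/deteriorated
condition at higher values of the split variable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclass
class MRTNode:
    members: list[int]            # row positions into X/Y
    ss: float
    depth: int
    split_variable: str | None = None
    split_value: float | None = None
    ss_reduction: float = 0.0
    left: "MRTNode | None" = None
    right: "MRTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class MRTree:
    root: MRTNode
    X: pd.DataFrame
    Y: pd.DataFrame                # response used for fitting (maybe scaled)
    standardized: bool
    population_ids: list[str]
    split_order: list[MRTNode] = field(default_factory=list)

    def leaves(self) -> list[MRTNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_partition(self) -> list[list[str]]:
        return [[self.population_ids[i] for i in lf.members] for lf in self.leaves()]

    def predict(self, x_row: pd.Series) -> np.ndarray:
        node = self.root
        while not node.is_leaf:
            node = node.left if x_row[node.split_variable] <= node.split_value else node.right
        return self.Y.iloc[node.members].mean(axis=0).to_numpy()


def _node_ss(Y: np.ndarray, members: list[int]) -> float:
    sub = Y[members]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def _best_split(
    X: pd.DataFrame, Y: np.ndarray, node: MRTNode, min_node_size: int
) -> tuple[float, str, float, list[int], list[int]] | None:
    """Best (reduction, variable, value, left, right) for one node, or None.

    Candidate split values are midpoints between consecutive sorted unique
    values of each explanatory variable; ties in reduction resolve to the
    lowest variable index, then the lowest split value.
    """
    best = None
    for var in X.columns:
        vals = X[var].to_numpy()[node.members]
        uniq = np.unique(vals)
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            cut = (lo + hi) / 2.0
            left = [i for i in node.members if X[var].to_numpy()[i] <= cut]
            right = [i for i in node.members if X[var].to_numpy()[i] > cut]
            if len(left) < min_node_size or len(right) < min_node_size:
                continue
            red = node.ss - _node_ss(Y, left) - _node_ss(Y, right)
            if best is None or red > best[0] + _TOL:
                best = (red, var, cut, left, right)
    if best is not None and best[0] <= _TOL:
        return None
    return best


def standardize_columns(Y: pd.DataFrame) -> pd.DataFrame:
    """Center each column and scale to unit variance (constant columns stay 0)."""
    out = Y - Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    for col in out.columns:
        if sd[col] > 0:
            out[col] = out[col] / sd[col]
    return out


def fit_mrt(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    min_node_size: int = 2,
    max_depth: int = 3,
    standardize: bool = True,
    max_leaves: int | None = None,
) -> MRTree:
    """Greedy best-first multivariate regression tree.

    ``X`` and ``Y`` are population-indexed DataFrames in the same row order.
    Splitting stops at ``min_node_size``, ``max_depth``, zero achievable SS
    reduction, or (if given) ``max_leaves``.
    """
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must share the same population index")
    n = len(X)
    if n < 2 * min_node_size:
        logger.warning("n=%d < 2*min_node_size: returning a root-only tree", n)
    if Y.isna().any().any() or X.isna().any().any():
        raise ValueError("missing cells are not allowed in X or Y")
    Yfit = standardize_columns(Y) if standardize else Y.copy()
    Ymat = Yfit.to_numpy(dtype=float)

    root = MRTNode(list(range(n)), _node_ss(Ymat, list(range(n))), depth=0)
    tree = MRTree(root, X, Yfit, standardize, [str(i) for i in X.index])

    # best-first growth: expand the open leaf with the largest SS reduction
    open_leaves = [root]
    while open_leaves:
        if max_leaves is not None and tree.n_leaves >= max_leaves:
            break
        candidates = []
        for node in open_leaves:
            if node.depth >= max_depth or len(node.members) < 2 * min_node_size:
                continue
            found = _best_split(X, Ymat, node, min_node_size)
            if found is not None:
                candidates.append((found[0], open_leaves.index(node), node, found))
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        _, _, node, (red, var, cut, left, right) = candidates[0]
        node.split_variable, node.split_value, node.ss_reduction = var, cut, red
        node.left = MRTNode(left, _node_ss(Ymat, left), node.depth + 1)
        node.right = MRTNode(right, _node_ss(Ymat, right), node.depth + 1)
        tree.split_order.append(node)
        open_leaves.remove(node)
        open_leaves.extend([node.left, node.right])

    if root.is_leaf and X.nunique().le(1).all() and Yfit.nunique().gt(1).any():
        logger.warning("constant explanatory variables: root-only tree")
    return tree


def _prune_to_size(tree: MRTree, size: int) -> MRTree:
    """Nested subtree with ``size`` leaves, undoing best-first splits in reverse."""
    import copy

    pruned = copy.deepcopy(tree)
    while pruned.n_leaves > size and pruned.split_order:
        node = pruned.split_order.pop()
        node.left = node.right = None
        node.split_variable = node.split_value = None
        node.ss_reduction = 0.0
    return pruned


@dataclass
class CVResult:
    sizes: list[int]
    cv_errors: list[float]
    cv_se: list[float]
    selected_size: int
    folds_used: int
    reps_used: int
    rule: str

    def error_for(self, size: int) -> float:
        return self.cv_errors[self.sizes.index(size)]


def cross_validate(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    folds: int = 10,
    reps: int = 1000,
    seed: int = 0,
    min_node_size: int = 2,
    max_depth: int = 3,
    standardize: bool = True,
    rule: str = "1se",
) -> CVResult:
    """Cross-validated relative error per candidate tree size.

    Folds are clamped to the number of populations; at the clamp the scheme
    is leave-one-out, which is deterministic, so repetitions collapse to one.
    ``rule`` is ``"1se"`` (default) or ``"min"``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if rule not in ("1se", "min"):
        raise ValueError(f"unknown selection rule {rule!r}")
    n = len(X)
    folds_eff = min(folds, n)
    reps_eff = reps
    if folds_eff >= n:
        if folds > n:
            logger.info("folds clamped from %d to n=%d (leave-one-out)", folds, n)
        if reps != 1:
            logger.info("leave-one-out is deterministic: reps collapsed to 1")
        reps_eff = 1

    Yfit = standardize_columns(Y) if standardize else Y.copy()
    Ymat = Yfit.to_numpy(dtype=float)
    ss_total = _node_ss(Ymat, list(range(n)))
    if ss_total <= 0:
        return CVResult([1], [0.0], [0.0], 1, folds_eff, reps_eff, rule)

    full = fit_mrt(X, Yfit, min_node_size, max_depth, standardize=False)
    sizes = list(range(1, full.n_leaves + 1))

    rng = np.random.default_rng(seed)
    per_size_obs_err = {s: np.zeros(n) for s in sizes}
    for _ in range(reps_eff):
        if folds_eff == n:
            fold_of = np.arange(n)
        else:
            fold_of = np.empty(n, dtype=int)
            fold_of[rng.permutation(n)] = np.arange(n) % folds_eff
        for f in range(folds_eff):
            test = np.where(fold_of == f)[0]
            train = np.where(fold_of != f)[0]
            if len(train) < 2:
                continue
            sub = fit_mrt(
                X.iloc[train], Yfit.iloc[train], min_node_size, max_depth,
                standardize=False,
            )
            for s in sizes:
                pruned = _prune_to_size(sub, min(s, sub.n_leaves))
                for i in test:
                    pred = pruned.predict(X.iloc[i])
                    per_size_obs_err[s][i] += float(
                        ((Ymat[i] - pred) ** 2).sum()
                    )
    cv_errors, cv_se = [], []
    for s in sizes:
        errs = per_size_obs_err[s] / reps_eff
        cv_errors.append(float(errs.sum() / ss_total))
        cv_se.append(float(np.std(errs, ddof=1) * np.sqrt(n) / ss_total))

    i_min = int(np.argmin(cv_errors))
    if rule == "min":
        selected = sizes[i_min]
    else:
        cutoff = cv_errors[i_min] + cv_se[i_min]
        selected = next(s for s, e in zip(sizes, cv_errors) if e <= cutoff)
    return CVResult(sizes, cv_errors, cv_se, selected, folds_eff, reps_eff, rule)


def first_split_r2(tree: MRTree) -> float:
    """(SS_root - SS_left - SS_right) / SS_root for the primary split."""
    root = tree.root
    if root.is_leaf:
        logger.warning("root-only tree: first-split R^2 is 0")
        return 0.0
    if root.ss <= 0:
        return 0.0
    return float((root.ss - root.left.ss - root.right.ss) / root.ss)


def _render(node: MRTNode, pops: list[str]) -> str:
    if node.is_leaf:
        ids = [pops[i] for i in node.members]
        return ids[0] if len(ids) == 1 else "(" + ",".join(ids) + ")"
    return "(" + _render(node.left, pops) + "," + _render(node.right, pops) + ")"


def newick_topology(tree: MRTree, paper_style: bool = False) -> str:
    """Leaf-group topology in Newick form.

    Left sibling = low side of the split.  ``paper_style`` drops the outer
    parentheses and the terminal semicolon (display form).
    """
    pops = tree.population_ids
    if tree.root.is_leaf:
        inner = "(" + ",".join(pops[i] for i in tree.root.members) + ")"
        return inner if paper_style else inner + ";"
    body = _render(tree.root, pops)
    if paper_style:
        return body[1:-1] if body.startswith("(") else body
    return body + ";"


def primary_split_correlations(
    tree: MRTree, X: pd.DataFrame, Y: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of the primary split variable with each response.

    Hsp70-type responses are reported with a +/- sign; histopathology MAV
    responses map negative correlation to "i" (higher divergence, lower
    damage, i.e. improved condition) and positive to "d" (deteriorated).
    Zero-variance inputs yield an "undefined" flag.
    """
    if tree.root.is_leaf:
        raise ValueError("tree has no split")
    var = tree.root.split_variable
    x = X[var].to_numpy(dtype=float)
    rows = []
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"response": col, "split_variable": var,
                         "r": np.nan, "sign": "undefined",
                         "annotation": "undefined"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        sign = "+" if r > 0 else "-"
        is_mav = col.startswith("mav_") or col.endswith("_score")
        annotation = ("d" if r > 0 else "i") if is_mav else sign
        rows.append({"response": col, "split_variable": var, "r": r,
                     "sign": sign, "annotation": annotation})
    return pd.DataFrame(rows)
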