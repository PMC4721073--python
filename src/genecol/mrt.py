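"""Multivariate regression trees: constrained clustering of populations.

A multivariate regression tree (MRT) recursively splits the rows of a
multivariate response (here: the normalized population x trait matrix)
using rules on external predictors (climate normals, or categorical
ecosystem units), each split chosen to maximize the drop in the
multivariate sum of squared Euclidean distances to node means.  The
result is a constrained clustering: groups are homogeneous in the
traits *and* describable by the predictors, which is what makes the
leaves usable as seed-zone delineations.

Growth is best-first (the node whose best split removes the most sum of
squares is expanded next), which makes "the tree with n leaves" well
defined: pruning keeps the first n-1 splits in growth order.
Tie-breaking is deterministic: numeric ties go to the smaller
threshold, categorical ties to the lexicographically smallest left
level set, and ties across predictors to the first predictor column.

Categorical splits enumerate all 2^(m-1)-1 binary level partitions up
to ``max_exhaustive`` distinct levels; above that, levels are ordered
by the projection of their mean response onto the first principal axis
of the level means and only contiguous partitions of that ordering are
scored (the classic reduction, exact for a single response dimension).
"""

from __future__ import annotations

import heapq
import itertools
import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SplitRule",
    "Node",
    "MRTTree",
    "TreeControl",
    "total_ss",
    "best_numeric_split",
    "best_categorical_split",
    "grow_tree",
    "cross_validate",
    "prune_to_leaves",
    "leaf_profiles",
]


@dataclass(frozen=True)
class SplitRule:
    """A binary split rule on one predictor.

    Numeric rules send ``value < threshold`` left; categorical rules
    send levels in ``left_levels`` left.  ``ss_reduction`` is the drop
    in within-node sum of squares the split achieves on its training
    node, and ``ss_fraction`` the same as a fraction of the tree's total
    SS (the "variance explained by a particular split").
    """

    predictor: str
    kind: str  # "numeric" | "categorical"
    ss_reduction: float
    ss_fraction: float = np.nan
    threshold: float | None = None
    left_levels: frozenset | None = None

    def describe(self) -> str:
        if self.kind == "numeric":
            return f"{self.predictor} < {self.threshold:g}"
        return f"{self.predictor} in {{{', '.join(sorted(self.left_levels))}}}"


@dataclass
class Node:
    """A tree node over a set of response rows (integer positions)."""

    members: np.ndarray
    ss: float
    rule: SplitRule | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TreeControl:
    """Growth control: minimum leaf size, improvement floor, size cap.

    ``min_improvement_fraction`` is the fraction of the total SS a split
    must remove to be made at all (0.01 by default, so the tree does not
    chase noise); set it to 0 when growing large trees for
    cross-validated size selection.
    """

    min_leaf: int = 2
    min_improvement_fraction: float = 0.01
    max_leaves: int | None = None
    max_exhaustive: int = 12


def _as_matrix(response) -> pd.DataFrame:
    if hasattr(response, "values") and isinstance(getattr(response, "values"), pd.DataFrame):
        return response.values  # TraitMatrix
    if isinstance(response, pd.DataFrame):
        return response
    return pd.DataFrame(np.asarray(response, float))


def total_ss(response) -> float:
    """Sum over rows of squared Euclidean distance to the column-mean vector.

    Equals the sum over columns of the centered sum of squares.
    """
    Y = _as_matrix(response).to_numpy(float)
    if len(Y) == 0:
        raise ValueError("need at least one row")
    return float(((Y - Y.mean(axis=0)) ** 2).sum())


def _node_ss(Y: np.ndarray, idx: np.ndarray) -> float:
    sub = Y[idx]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def best_numeric_split(
    values: np.ndarray,
    response,
    min_leaf: int = 2,
    predictor: str = "x",
    min_reduction: float = 0.0,
    tree_total_ss: float | None = None,
) -> SplitRule | None:
    """Best ``value < threshold`` split of the rows by SS reduction.

    Every midpoint between consecutive distinct sorted predictor values
    is scored; both children must keep at least ``min_leaf`` rows.
    Returns None when no admissible split improves on ``min_reduction``.
    Ties are broken toward the smaller threshold.
    """
    Y = _as_matrix(response).to_numpy(float)
    values = np.asarray(values, float)
    n = len(values)
    if n != len(Y):
        raise ValueError("predictor vector and response rows are misaligned")
    order = np.argsort(values, kind="stable")
    v = values[order]
    Ys = Y[order]
    csum = np.cumsum(Ys, axis=0)
    csq = np.cumsum((Ys**2).sum(axis=1))
    s_tot, q_tot = csum[-1], csq[-1]
    parent = q_tot - float(s_tot @ s_tot) / n
    best = None
    best_red = min_reduction
    for i in range(min_leaf, n - min_leaf + 1):
        if i == 0 or i == n or v[i] <= v[i - 1]:
            continue
        sL = csum[i - 1]
        ssL = csq[i - 1] - float(sL @ sL) / i
        sR = s_tot - sL
        ssR = (q_tot - csq[i - 1]) - float(sR @ sR) / (n - i)
        red = parent - ssL - ssR
        if red > best_red + 1e-12 * max(parent, 1.0):
            best_red = red
            best = (v[i - 1] + v[i]) / 2.0
    if best is None:
        return None
    frac = best_red / tree_total_ss if tree_total_ss else np.nan
    return SplitRule(
        predictor=predictor,
        kind="numeric",
        threshold=float(best),
        ss_reduction=float(best_red),
        ss_fraction=float(frac),
    )


def _partition_reduction(counts, sums, mask_idx):
    nL = counts[mask_idx].sum()
    nR = counts.sum() - nL
    if nL == 0 or nR == 0:
        return None
    sL = sums[mask_idx].sum(axis=0)
    sAll = sums.sum(axis=0)
    sR = sAll - sL
    return (
        float(sL @ sL) / nL + float(sR @ sR) / nR - float(sAll @ sAll) / counts.sum(),
        int(nL),
        int(nR),
    )


def best_categorical_split(
    levels: Sequence,
    response,
    min_leaf: int = 2,
    max_exhaustive: int = 12,
    predictor: str = "x",
    min_reduction: float = 0.0,
    tree_total_ss: float | None = None,
) -> SplitRule | None:
    """Best binary partition of categorical levels by SS reduction.

    With at most ``max_exhaustive`` distinct levels all 2^(m-1)-1
    partitions are scored exactly; above that, levels are ordered by the
    projection of their mean response onto the first principal axis of
    the level means and only contiguous partitions are scored.  The left
    set is canonicalized to the side containing the lexicographically
    smallest level; ties are broken toward the lexicographically
    smallest left set.
    """
    Y = _as_matrix(response).to_numpy(float)
    levels = np.asarray(levels, dtype=object)
    if len(levels) != len(Y):
        raise ValueError("level vector and response rows are misaligned")
    uniq = sorted(set(levels))
    m = len(uniq)
    if m < 2:
        return None
    code = np.array([uniq.index(l) for l in levels])
    counts = np.bincount(code, minlength=m).astype(float)
    sums = np.zeros((m, Y.shape[1]))
    np.add.at(sums, code, Y)

    candidates: list[tuple[int, ...]]
    if m <= max_exhaustive:
        # all 2^(m-1)-1 partitions, each once: left side contains level 0
        candidates = [
            (0,) + combo
            for r in range(m - 1)
            for combo in itertools.combinations(range(1, m), r)
        ]
    else:
        means = sums / counts[:, None]
        centered = means - means.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        order = np.argsort(proj, kind="stable")
        candidates = [tuple(sorted(order[: j + 1])) for j in range(m - 1)]

    best_red = min_reduction
    best_set: tuple[str, ...] | None = None
    for cand in candidates:
        idx = np.array(cand)
        res = _partition_reduction(counts, sums, idx)
        if res is None:
            continue
        red, nL, nR = res
        if nL < min_leaf or nR < min_leaf:
            continue
        # canonical: left side contains the lexicographically smallest level
        left = tuple(sorted(uniq[i] for i in idx))
        if uniq[0] not in left:
            left = tuple(sorted(set(uniq) - set(left)))
        tol = 1e-12 * max(abs(best_red), 1.0)
        if red > best_red + tol or (
            best_set is not None and abs(red - best_red) <= tol and left < best_set
        ):
            best_red = red
            best_set = left
    if best_set is None:
        return None
    frac = best_red / tree_total_ss if tree_total_ss else np.nan
    return SplitRule(
        predictor=predictor,
        kind="categorical",
        left_levels=frozenset(best_set),
        ss_reduction=float(best_red),
        ss_fraction=float(frac),
    )


class MRTTree:
    """A grown multivariate regression tree.

    Attributes
    ----------
    root : Node
    total_ss : float
        SS of the full response around its multivariate mean.
    split_order : list[Node]
        Internal nodes in the order their splits were made (best-first),
        the growth path along which trees of every size are defined.
    """

    def __init__(
        self,
        root: Node,
        response: pd.DataFrame,
        predictors: pd.DataFrame,
        categorical: frozenset,
        control: TreeControl,
        total_ss_: float,
        split_order: list[Node],
    ):
        self.root = root
        self.response = response
        self.predictors = predictors
        self.categorical = categorical
        self.control = control
        self.total_ss = total_ss_
        self.split_order = split_order
        self._number_leaves()

    # -- structure ---------------------------------------------------------
    def _number_leaves(self) -> None:
        for i, leaf in enumerate(self.leaves(), start=1):
            leaf.leaf_id = i

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def rec(nd: Node) -> None:
            if nd.is_leaf:
                out.append(nd)
            else:
                rec(nd.left)
                rec(nd.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def r_squared(self) -> float:
        """Fraction of the total SS explained by all splits."""
        if self.total_ss == 0:
            return 0.0
        return sum(nd.rule.ss_reduction for nd in self.split_order) / self.total_ss

    # -- routing -----------------------------------------------------------
    def route(self, row: pd.Series, log_unseen: bool = True) -> Node:
        """Route one predictor row to a leaf.

        Unseen categorical levels fall back to the child with more
        training members (logged).
        """
        nd = self.root
        while not nd.is_leaf:
            rule = nd.rule
            x = row[rule.predictor]
            if rule.kind == "numeric":
                go_left = float(x) < rule.threshold
            else:
                right_levels = (
                    set(self.predictors[rule.predictor].iloc[nd.right.members])
                    if self.predictors is not None
                    else None
                )
                if x in rule.left_levels:
                    go_left = True
                elif right_levels is None or x in right_levels:
                    go_left = False
                else:
                    go_left = nd.left.n >= nd.right.n
                    if log_unseen:
                        logger.warning(
                            "unseen level %r for %r; routed to larger child",
                            x,
                            rule.predictor,
                        )
            nd = nd.left if go_left else nd.right
        return nd

    def assignments(self) -> pd.Series:
        """Leaf id per training row (by membership, not re-routing)."""
        out = np.empty(len(self.response), dtype=int)
        for leaf in self.leaves():
            out[leaf.members] = leaf.leaf_id
        return pd.Series(out, index=self.response.index, name="leaf")

    # -- export ------------------------------------------------------------
    def _node_json(self, nd: Node) -> dict:
        base = {
            "n": nd.n,
            "ss": nd.ss,
            "members": [str(self.response.index[i]) for i in nd.members],
            "profile": self.response.iloc[nd.members].mean(axis=0).round(10).to_dict(),
        }
        if nd.is_leaf:
            return {"kind": "leaf", "leaf_id": nd.leaf_id, **base}
        right_levels = None
        if nd.rule.kind == "categorical":
            right_levels = sorted(
                set(self.predictors[nd.rule.predictor].iloc[nd.right.members])
            )
        return {
            "kind": "split",
            "rule": {
                "predictor": nd.rule.predictor,
                "type": nd.rule.kind,
                "threshold": nd.rule.threshold,
                "left_levels": sorted(nd.rule.left_levels) if nd.rule.left_levels else None,
                "right_levels": right_levels,
                "ss_reduction": nd.rule.ss_reduction,
                "ss_fraction": nd.rule.ss_fraction,
            },
            **base,
            "left": self._node_json(nd.left),
            "right": self._node_json(nd.right),
        }

    def to_json(self) -> str:
        payload = {
            "total_ss": self.total_ss,
            "r_squared": self.r_squared,
            "n_leaves": self.n_leaves,
            "response_columns": list(self.response.columns),
            "categorical": sorted(self.categorical),
            "root": self._node_json(self.root),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(nd: Node, depth: int, label: str) -> None:
            pad = "  " * depth
            if nd.is_leaf:
                prof = ", ".join(
                    f"{c}={v:+.2f}"
                    for c, v in self.response.iloc[nd.members].mean(axis=0).items()
                )
                lines.append(f"{pad}{label}leaf {nd.leaf_id} (n={nd.n}): {prof}")
            else:
                lines.append(
                    f"{pad}{label}{nd.rule.describe()}"
                    f"  [explains {100 * nd.rule.ss_fraction:.1f}%]"
                )
                rec(nd.left, depth + 1, "yes: ")
                rec(nd.right, depth + 1, "no:  ")

        rec(self.root, 0, "")
        return "\n".join(lines)


def _best_split_for_node(
    node: Node,
    Y: pd.DataFrame,
    predictors: pd.DataFrame,
    categorical: frozenset,
    control: TreeControl,
    tree_total: float,
) -> SplitRule | None:
    floor = control.min_improvement_fraction * tree_total
    sub = Y.iloc[node.members]
    best: SplitRule | None = None
    for col in predictors.columns:
        colvals = predictors[col].iloc[node.members]
        if col in categorical:
            rule = best_categorical_split(
                colvals.to_numpy(object),
                sub,
                min_leaf=control.min_leaf,
                max_exhaustive=control.max_exhaustive,
                predictor=col,
                min_reduction=floor,
                tree_total_ss=tree_total,
            )
        else:
            if colvals.isna().any():
                raise ValueError(f"missing values in numeric predictor {col!r}")
            rule = best_numeric_split(
                colvals.to_numpy(float),
                sub,
                min_leaf=control.min_leaf,
                predictor=col,
                min_reduction=floor,
                tree_total_ss=tree_total,
            )
        if rule is not None and (best is None or rule.ss_reduction > best.ss_reduction):
            best = rule
    return best


def _apply_rule(rule: SplitRule, predictors: pd.DataFrame, members: np.ndarray):
    col = predictors[rule.predictor].iloc[members]
    if rule.kind == "numeric":
        mask = col.to_numpy(float) < rule.threshold
    else:
        mask = col.isin(rule.left_levels).to_numpy()
    return members[mask], members[~mask]


def grow_tree(
    response,
    predictors: pd.DataFrame,
    categorical: Sequence[str] = (),
    control: TreeControl | None = None,
) -> MRTTree:
    """Grow an MRT by best-first greedy splitting.

    Parameters
    ----------
    response : TraitMatrix or DataFrame
        Rows are populations, columns the (normalized) traits.
    predictors : DataFrame
        Aligned with the response rows (same index or same length).
    categorical : sequence of str
        Predictor columns to treat as categorical.
    control : TreeControl

    The node whose best admissible split removes the most SS is expanded
    next, until ``max_leaves`` is reached or no split clears the
    improvement floor.
    """
    control = control or TreeControl()
    Y = _as_matrix(response)
    if len(Y) != len(predictors):
        raise ValueError("response and predictor tables are misaligned")
    if not Y.index.equals(predictors.index):
        if set(Y.index) == set(predictors.index):
            predictors = predictors.reindex(Y.index)
        elif isinstance(predictors.index, pd.RangeIndex):
            predictors = predictors.set_axis(Y.index)
        else:
            raise ValueError("response and predictor tables are misaligned")
    missing_cols = set(categorical) - set(predictors.columns)
    if missing_cols:
        raise ValueError(f"categorical columns not in predictors: {sorted(missing_cols)}")
    # non-numeric predictor columns are categorical whether declared or not
    auto = {c for c in predictors.columns if not pd.api.types.is_numeric_dtype(predictors[c])}
    categorical = frozenset(categorical) | frozenset(auto)
    Ynp = Y.to_numpy(float)
    all_rows = np.arange(len(Y))
    tree_total = float(((Ynp - Ynp.mean(axis=0)) ** 2).sum())
    root = Node(members=all_rows, ss=tree_total)
    split_order: list[Node] = []

    heap: list[tuple[float, int, Node, SplitRule]] = []
    seq = itertools.count()
    if tree_total > 0:
        first = _best_split_for_node(root, Y, predictors, categorical, control, tree_total)
        if first is not None:
            heapq.heappush(heap, (-first.ss_reduction, next(seq), root, first))

    max_leaves = control.max_leaves if control.max_leaves is not None else len(Y)
    n_leaves = 1
    while heap and n_leaves < max_leaves:
        _, _, node, rule = heapq.heappop(heap)
        li, ri = _apply_rule(rule, predictors, node.members)
        node.rule = rule
        node.left = Node(members=li, ss=_node_ss(Ynp, li))
        node.right = Node(members=ri, ss=_node_ss(Ynp, ri))
        split_order.append(node)
        n_leaves += 1
        for child in (node.left, node.right):
            if child.n >= 2 * control.min_leaf and child.ss > 0:
                r = _best_split_for_node(child, Y, predictors, categorical, control, tree_total)
                if r is not None:
                    heapq.heappush(heap, (-r.ss_reduction, next(seq), child, r))
    return MRTTree(root, Y, predictors, categorical, control, tree_total, split_order)


def prune_to_leaves(tree: MRTTree, n_leaves: int) -> MRTTree:
    """The tree with ``n_leaves`` leaves along the growth path.

    Keeps the first ``n_leaves - 1`` splits in best-first growth order
    (parents always precede children, so the result is a valid tree).
    """
    if not 1 <= n_leaves <= tree.n_leaves:
        raise ValueError(
            f"n_leaves must be in [1, {tree.n_leaves}], got {n_leaves}"
        )
    kept = set(id(nd) for nd in tree.split_order[: n_leaves - 1])
    order_map: dict[int, Node] = {}

    def rec(nd: Node) -> Node:
        new = Node(members=nd.members, ss=nd.ss)
        if not nd.is_leaf and id(nd) in kept:
            new.rule = nd.rule
            new.left = rec(nd.left)
            new.right = rec(nd.right)
            order_map[id(nd)] = new
        return new

    new_root = rec(tree.root)
    new_order = [order_map[id(nd)] for nd in tree.split_order[: n_leaves - 1]]
    return MRTTree(
        new_root,
        tree.response,
        tree.predictors,
        tree.categorical,
        tree.control,
        tree.total_ss,
        new_order,
    )


def leaf_profiles(tree: MRTTree) -> pd.DataFrame:
    """Per-leaf multivariate mean profile (SD units) and membership size.

    Indexed by leaf id (left-to-right); trait columns plus ``n_members``.
    The member-weighted mean of the profiles equals the overall response
    mean (zero for a normalized response).
    """
    rows = {}
    for leaf in tree.leaves():
        prof = tree.response.iloc[leaf.members].mean(axis=0)
        prof["n_members"] = leaf.n
        rows[leaf.leaf_id] = prof
    out = pd.DataFrame(rows).T
    out.index.name = "leaf"
    out["n_members"] = out["n_members"].astype(int)
    return out


def cross_validate(
    response,
    predictors: pd.DataFrame,
    categorical: Sequence[str] = (),
    sizes: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8),
    folds: int = 10,
    reps: int = 5,
    seed: int = 0,
    control: TreeControl | None = None,
) -> pd.DataFrame:
    """Cross-validated relative error per candidate tree size.

    For each repetition the rows are shuffled into ``folds`` folds; a
    tree grown on the training folds (improvement floor 0 so every
    candidate size is reachable) is pruned to each size and the held-out
    rows are routed to leaves; the relative error is the held-out SS to
    the assigned leaf means divided by the total SS of the full
    response.  Sizes larger than any training tree achieved are skipped
    with a warning.

    Returns a DataFrame (size, cv_error, se) with
    ``attrs["best_size"]`` (minimum error) and ``attrs["size_1se"]``
    (smallest size within one SE of the minimum).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    control = control or TreeControl()
    Y = _as_matrix(response)
    n = len(Y)
    folds = min(folds, n)
    sizes = sorted(set(int(s) for s in sizes))
    grand_total = total_ss(Y)
    rng = np.random.default_rng(seed)
    grow_control = TreeControl(
        min_leaf=control.min_leaf,
        min_improvement_fraction=0.0,
        max_leaves=max(sizes),
        max_exhaustive=control.max_exhaustive,
    )

    per_rep = {s: [] for s in sizes}
    achievable = max(sizes)
    for _ in range(reps):
        perm = rng.permutation(n)
        fold_of = np.empty(n, int)
        for f in range(folds):
            fold_of[perm[f::folds]] = f
        errs = {s: 0.0 for s in sizes}
        for f in range(folds):
            test = np.where(fold_of == f)[0]
            train = np.where(fold_of != f)[0]
            tr_tree = grow_tree(
                Y.iloc[train], predictors.iloc[train], categorical, grow_control
            )
            achievable = min(achievable, tr_tree.n_leaves)
            Yt = Y.iloc[test].to_numpy(float)
            for s in sizes:
                sub = prune_to_leaves(tr_tree, min(s, tr_tree.n_leaves))
                profs = {
                    leaf.leaf_id: sub.response.iloc[leaf.members].mean(axis=0).to_numpy()
                    for leaf in sub.leaves()
                }
                err = 0.0
                for pos, i in enumerate(test):
                    leaf = sub.route(predictors.iloc[i], log_unseen=False)
                    err += float(((Yt[pos] - profs[leaf.leaf_id]) ** 2).sum())
                errs[s] += err
        for s in sizes:
            per_rep[s].append(errs[s] / grand_total)

    skipped = [s for s in sizes if s > achievable]
    if skipped:
        warnings.warn(f"sizes {skipped} exceed the achievable leaf count {achievable}")
    keep = [s for s in sizes if s <= achievable]
    table = pd.DataFrame(
        {
            "size": keep,
            "cv_error": [float(np.mean(per_rep[s])) for s in keep],
            "se": [
                float(np.std(per_rep[s], ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
                for s in keep
            ],
        }
    )
    best_i = int(table["cv_error"].idxmin())
    best_size = int(table.loc[best_i, "size"])
    cutoff = table.loc[best_i, "cv_error"] + table.loc[best_i, "se"]
    ok = table[table["cv_error"] <= cutoff]
    table.attrs["best_size"] = best_size
    table.attrs["size_1se"] = int(ok["size"].min())
    return table
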