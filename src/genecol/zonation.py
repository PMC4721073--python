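"""Seed-zone assembly from tree leaves, partition comparison, reporting.

Tree leaves group populations that are similar in their multitrait
profiles and describable by climate or ecosystem predictors.  For
deployment, groups must be expressed in terms of mapped ecosystem
variants: each variant is assigned to the group holding the majority of
its populations (ties to the larger group), and variants whose
populations straddle several leaves are logged as conflicts rather than
hidden.

Alternative partitions (climate tree vs ecozone tree vs variant tree)
are compared with the adjusted Rand index, which is 1 for identical
partitions (up to relabeling) and has expectation 0 under random
labeling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from genecol.mrt import MRTTree, leaf_profiles

logger = logging.getLogger(__name__)

__all__ = ["GroupAssignment", "assign_groups", "compare_partitions", "render_report", "load_tree"]


@dataclass
class GroupAssignment:
    """Populations and ecosystem variants mapped to seed-zone groups.

    Attributes
    ----------
    population_group : Series
        Group (leaf) id per population.
    variant_group : Series
        Group id per ecosystem variant (majority of its populations).
    group_variants : dict
        Group id -> sorted list of its ecosystem variants.
    group_profiles : DataFrame
        Leaf trait profiles (SD units) per group, when available.
    conflicts : list
        Variants whose populations landed in more than one leaf.
    """

    population_group: pd.Series
    variant_group: pd.Series
    group_variants: dict[int, list[str]]
    group_profiles: pd.DataFrame | None = None
    conflicts: list[str] = field(default_factory=list)

    @property
    def group_sizes(self) -> pd.Series:
        return self.population_group.value_counts().sort_index()


def load_tree(path: str | Path) -> dict:
    """Load a tree exported with ``MRTTree.to_json`` for routing."""
    return json.loads(Path(path).read_text())


def _route_json(node: dict, row: pd.Series) -> dict:
    while node["kind"] == "split":
        rule = node["rule"]
        x = row[rule["predictor"]]
        if rule["type"] == "numeric":
            left = float(x) < rule["threshold"]
        elif x in rule["left_levels"]:
            left = True
        elif rule["right_levels"] is None or x in rule["right_levels"]:
            left = False
        else:
            left = node["left"]["n"] >= node["right"]["n"]
            logger.warning(
                "unseen level %r for %r; routed to larger child", x, rule["predictor"]
            )
        node = node["left"] if left else node["right"]
    return node


def assign_groups(
    tree: MRTTree | dict,
    populations: pd.DataFrame,
    population: str = "seedlot_id",
    variant: str = "ecosystem_variant",
) -> GroupAssignment:
    """Route each population through the tree; map variants by majority.

    Works on a live :class:`MRTTree` or on a tree loaded from its JSON
    export.  Populations with a categorical level never seen in
    training are routed to the larger sibling and logged.
    """
    pops = populations.set_index(population) if population in populations else populations
    groups = {}
    if isinstance(tree, MRTTree):
        for pid, row in pops.iterrows():
            groups[pid] = int(tree.route(row).leaf_id)
        profiles = leaf_profiles(tree)
    else:
        for pid, row in pops.iterrows():
            groups[pid] = int(_route_json(tree["root"], row)["leaf_id"])
        profiles = _profiles_from_json(tree)
    population_group = pd.Series(groups, name="group").sort_index()

    variant_group = pd.Series(dtype=int)
    group_variants: dict[int, list[str]] = {}
    conflicts: list[str] = []
    if variant in pops.columns:
        sizes = population_group.value_counts()
        vg = {}
        for v, sub in population_group.groupby(pops[variant]):
            tally = sub.value_counts()
            if len(tally) > 1:
                conflicts.append(str(v))
                logger.warning(
                    "ecosystem variant %r spans groups %s; assigned by majority",
                    v,
                    sorted(tally.index),
                )
            top = tally[tally == tally.max()].index
            # ties go to the larger group overall
            vg[v] = int(max(top, key=lambda g: (sizes.get(g, 0), -g)))
        variant_group = pd.Series(vg, name="group").sort_index()
        for v, g in variant_group.items():
            group_variants.setdefault(int(g), []).append(v)
        group_variants = {g: sorted(vs) for g, vs in sorted(group_variants.items())}
    return GroupAssignment(
        population_group=population_group,
        variant_group=variant_group,
        group_variants=group_variants,
        group_profiles=profiles,
        conflicts=sorted(conflicts),
    )


def _profiles_from_json(tree: dict) -> pd.DataFrame:
    rows = {}

    def rec(node: dict) -> None:
        if node["kind"] == "leaf":
            prof = pd.Series(node["profile"])
            prof["n_members"] = node["n"]
            rows[node["leaf_id"]] = prof
        else:
            rec(node["left"])
            rec(node["right"])

    rec(tree["root"])
    out = pd.DataFrame(rows).T.sort_index()
    out.index.name = "leaf"
    return out


def _labels(x) -> pd.Series:
    if isinstance(x, GroupAssignment):
        return x.population_group
    return pd.Series(x)


def compare_partitions(a, b) -> float:
    """Adjusted Rand index between two partitions of the same populations.

    1 for identical partitions up to relabeling; expectation 0 for
    independent random labelings; can be negative for partitions that
    agree less than chance.
    """
    la, lb = _labels(a), _labels(b)
    if set(la.index) != set(lb.index):
        raise ValueError("partitions cover different population sets")
    lb = lb.reindex(la.index)
    ct = pd.crosstab(la.to_numpy(), lb.to_numpy()).to_numpy()
    n = ct.sum()
    sum_ij = comb(ct, 2).sum()
    ai = comb(ct.sum(axis=1), 2).sum()
    bj = comb(ct.sum(axis=0), 2).sum()
    expected = ai * bj / comb(n, 2)
    max_index = (ai + bj) / 2.0
    if max_index == expected:  # e.g. both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def render_report(
    out_dir: str | Path,
    assignment: GroupAssignment | None = None,
    decomps: Sequence = (),
    tree: MRTTree | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the report bundle: variance table, tree, groups, profiles, log.

    All outputs are CSV/JSON with fixed float formatting and sorted keys
    so a rerun on identical inputs is byte-identical.  Returns the paths
    written.  An empty decomposition list omits the variance table with
    a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if decomps:
        rows = []
        for d in decomps:
            c = d.components
            for term, r in c.iterrows():
                rows.append(
                    {
                        "trait": d.trait,
                        "term": term,
                        "variance": r["variance"],
                        "se": r["se"],
                        "percent": r["percent"],
                        "percent_se": r["percent_se"],
                        "pinned": bool(r["pinned"]),
                        "dropped": bool(r["dropped"]),
                    }
                )
            rows.append(
                {
                    "trait": d.trait,
                    "term": "vpop",
                    "variance": d.vpop,
                    "se": d.vpop_se,
                    "percent": 100.0 * d.vpop if np.isfinite(d.vpop) else np.nan,
                    "percent_se": 100.0 * d.vpop_se if np.isfinite(d.vpop_se) else np.nan,
                    "pinned": False,
                    "dropped": False,
                }
            )
        p = out / "variance_components.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        paths["variance_components"] = p
    else:
        logger.warning("no variance decompositions supplied; variance table omitted")

    if tree is not None:
        p = out / "tree.json"
        p.write_text(tree.to_json() + "\n")
        paths["tree_json"] = p
        p = out / "tree.txt"
        p.write_text(tree.to_text() + "\n")
        paths["tree_text"] = p
        p = out / "leaf_profiles.csv"
        leaf_profiles(tree).to_csv(p, float_format="%.10g")
        paths["leaf_profiles"] = p

    if assignment is not None:
        p = out / "groups.csv"
        df = assignment.population_group.rename("group").to_frame()
        df.index.name = "population"
        df.to_csv(p)
        paths["groups"] = p
        if len(assignment.variant_group):
            p = out / "variant_groups.csv"
            vg = assignment.variant_group.rename("group").to_frame()
            vg.index.name = "ecosystem_variant"
            vg["conflict"] = vg.index.isin(assignment.conflicts)
            vg.to_csv(p)
            paths["variant_groups"] = p

    import genecol

    log = {
        "package_version": genecol.__version__,
        "config": config or {},
        "n_decompositions": len(decomps),
        "tree_leaves": None if tree is None else tree.n_leaves,
        "tree_r_squared": None if tree is None else round(tree.r_squared, 10),
        "conflicts": [] if assignment is None else assignment.conflicts,
    }
    p = out / "run_log.json"
    p.write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
    paths["run_log"] = p
    return paths
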