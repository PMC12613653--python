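"""Geotree: the hierarchical attribute-space tree.

The tree organises region-year observations by their stratification:
root -> branches (natural-environment types I/II/III) -> twigs
(development stages 1/2/3) -> leaves (region-year records carrying life
expectancy). Reading a region's leaves across years reconstructs its
trajectory through the tree — the stage it occupied each decade under a
fixed environment type.

Canonical serialization is nested JSON; a Newick export with annotated
leaf names is provided for tree viewers, and a minimal tiered plot for
smoke-testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stratify import ROMAN


@dataclass(frozen=True)
class Leaf:
    region: int
    year: int
    le: float
    env_type: int
    stage: int


@dataclass
class Geotree:
    """branches[env_type][stage] -> list of leaves, sorted by (region, year)."""

    branches: dict = field(default_factory=dict)

    @property
    def leaves(self) -> list[Leaf]:
        out = []
        for t in sorted(self.branches):
            for s in sorted(self.branches[t]):
                out.extend(self.branches[t][s])
        return out

    @property
    def n_leaves(self) -> int:
        return sum(len(v) for tw in self.branches.values() for v in tw.values())

    def cell(self, env_type: int, stage: int) -> list[Leaf]:
        return self.branches.get(env_type, {}).get(stage, [])


class CompletenessError(ValueError):
    """A panel row has no stratum assignment (or vice versa)."""


def build_geotree(panel: pd.DataFrame, assignments: pd.DataFrame) -> Geotree:
    """Assemble the tree from a panel and its stratum assignments.

    Every panel row must appear as exactly one leaf whose path (branch,
    twig) equals its assignment; empty twigs are omitted; leaves are sorted
    by region id (then year) within a twig, so the structure is independent
    of input row order.
    """
    amap = {
        (int(r.region), int(r.year)): (int(r.env_type), int(r.stage))
        for r in assignments.itertuples()
    }
    branches: dict[int, dict[int, list[Leaf]]] = {}
    seen = set()
    for row in panel.itertuples():
        key = (int(row.region), int(row.year))
        if key in seen:
            raise CompletenessError(f"duplicate panel row for region-year {key}")
        seen.add(key)
        if key not in amap:
            raise CompletenessError(f"panel row {key} has no stratum assignment")
        t, s = amap[key]
        leaf = Leaf(region=key[0], year=key[1], le=float(row.le),
                    env_type=t, stage=s)
        branches.setdefault(t, {}).setdefault(s, []).append(leaf)
    for tw in branches.values():
        for leaves in tw.values():
            leaves.sort(key=lambda lf: (lf.region, lf.year))
    return Geotree(branches=branches)


def trajectory(panel: pd.DataFrame, assignments: pd.DataFrame, region: int) -> pd.DataFrame:
    """Chronological (year, env_type, stage, le) path of one region."""
    sub = panel[panel["region"] == region]
    if sub.empty:
        raise KeyError(f"region {region} not present in panel")
    asub = assignments[assignments["region"] == region].set_index("year")
    rows = []
    for row in sub.sort_values("year").itertuples():
        yr = int(row.year)
        rows.append(
            {
                "year": yr,
                "env_type": int(asub.loc[yr, "env_type"]),
                "stage": int(asub.loc[yr, "stage"]),
                "le": float(row.le),
            }
        )
    return pd.DataFrame(rows)


def summarize_tree(tree: Geotree) -> pd.DataFrame:
    """Per-(type, stage) cell statistics: leaf count, mean LE, quartiles.

    Empty cells are omitted; counts sum to the leaf total.
    """
    rows = []
    for t in sorted(tree.branches):
        for s in sorted(tree.branches[t]):
            le = np.array([lf.le for lf in tree.branches[t][s]])
            q1, med, q3 = np.percentile(le, [25, 50, 75])
            rows.append(
                {
                    "env_type": t,
                    "stage": s,
                    "count": le.size,
                    "mean_le": float(le.mean()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def tree_to_dict(tree: Geotree) -> dict:
    return {
        "branches": {
            str(t): {
                str(s): [
                    {"region": lf.region, "year": lf.year, "le": lf.le}
                    for lf in tree.branches[t][s]
                ]
                for s in sorted(tree.branches[t])
            }
            for t in sorted(tree.branches)
        }
    }


def tree_from_dict(doc: dict) -> Geotree:
    branches: dict[int, dict[int, list[Leaf]]] = {}
    for t_str, twigs in doc["branches"].items():
        t = int(t_str)
        for s_str, leaves in twigs.items():
            s = int(s_str)
            branches.setdefault(t, {})[s] = [
                Leaf(region=int(d["region"]), year=int(d["year"]),
                     le=float(d["le"]), env_type=t, stage=s)
                for d in leaves
            ]
    return Geotree(branches=branches)


def write_tree_json(path, tree: Geotree) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tree_json(path) -> Geotree:
    with open(path) as fh:
        return tree_from_dict(json.load(fh))


def tree_to_newick(tree: Geotree) -> str:
    """Newick string with leaf names ``R<region>_<year>__LE<value>`` and
    branch/twig labels, for generic tree viewers."""
    branch_strs = []
    for t in sorted(tree.branches):
        twig_strs = []
        for s in sorted(tree.branches[t]):
            leaf_strs = [
                f"R{lf.region:02d}_{lf.year}__LE{lf.le:.2f}"
                for lf in tree.branches[t][s]
            ]
            twig_strs.append("(" + ",".join(leaf_strs) + f")stage{s}")
        branch_strs.append("(" + ",".join(twig_strs) + f")type{ROMAN[t]}")
    return "(" + ",".join(branch_strs) + ")root;"


def plot_tree(tree: Geotree, ax=None):
    """Minimal tiered rendering: branches fan out by type, twigs by stage,
    leaves coloured by LE on a continuous scale. Smoke-test quality only."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    leaves = tree.leaves
    les = [lf.le for lf in leaves]
    x = 0
    for t in sorted(tree.branches):
        for s in sorted(tree.branches[t]):
            for lf in tree.branches[t][s]:
                ax.plot([0, (t - 2) * 2, (t - 2) * 2 + (s - 2) * 0.6, x * 0.05 - 2],
                        [0, 1, 2, 3], lw=0.3, color="0.7", zorder=1)
                ax.scatter([x * 0.05 - 2], [3], c=[lf.le],
                           vmin=min(les), vmax=max(les), cmap="YlGn",
                           s=12, zorder=2)
                x += 1
    ax.set_axis_off()
    return ax
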