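"""Paired clonotype definition, expansion statistics, usage matrices.

A clone is the set of a subject's cells sharing identical first-alpha and
beta CDR3 amino-acid sequences; a clone with two or more member cells
within one subject x condition is *dominant* (expanded).  Group-level
expansion fractions, ranked dominant-clone tables with integer percentages
(round half up), cross-group shared-clone lists at gene-usage or CDR3
granularity, and row-normalized gene-usage matrices with an
average-linkage/Euclidean clustering order all derive from that definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CLONE_KEY = ["subject_id", "cdr3a_aa", "cdr3b_aa"]
USAGE_KEY = ["trav", "traj", "trbv", "trbj"]
CONDITIONS = ("unstimulated", "stimulated")


def round_half_up_percent(n: int, total: int) -> int:
    """Integer percent of n/total with exact round-half-up (no float)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (200 * n + total) // (2 * total)


def paired_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Cells with both an asserted beta and first alpha chain."""
    if cells.empty:
        return cells
    mask = (cells["cdr3a_aa"].astype(str) != "") & \
           (cells["cdr3b_aa"].astype(str) != "")
    if "paired" in cells.columns:
        mask &= cells["paired"].astype(bool)
    return cells.loc[mask]


def define_clones(cells: pd.DataFrame) -> pd.DataFrame:
    """Group paired-call cells into clones.

    Returns one row per (subject, CDR3alpha, CDR3beta) with per-condition
    member counts ``n_unstimulated``/``n_stimulated``, per-condition
    dominance flags, and the clone's gene-usage key (majority vote across
    member cells; disagreements are QC-flagged, not dropped).
    """
    cols = ["group", "n_unstimulated", "n_stimulated",
            "dominant_unstimulated", "dominant_stimulated",
            "trav", "traj", "trbv", "trbj", "usage_conflict"]
    cells = paired_cells(cells)
    if cells.empty:
        return pd.DataFrame(columns=CLONE_KEY + cols)
    rows = []
    for key, grp in cells.groupby(CLONE_KEY, sort=True):
        counts = grp["condition"].value_counts()
        usage = {}
        conflict = False
        for col in USAGE_KEY:
            vals = grp[col].value_counts()
            usage[col] = vals.index[0]
            conflict |= len(vals) > 1
        row = dict(zip(CLONE_KEY, key))
        row["group"] = grp["group"].iloc[0]
        for cond in CONDITIONS:
            n = int(counts.get(cond, 0))
            row[f"n_{cond}"] = n
            row[f"dominant_{cond}"] = n >= 2
        row.update(usage)
        row["usage_conflict"] = conflict
        rows.append(row)
    return pd.DataFrame(rows, columns=CLONE_KEY + cols)


def expansion_fraction(cells: pd.DataFrame, clones: pd.DataFrame,
                       group: str, condition: str) -> float:
    """Percentage of paired-call cells belonging to dominant clones.

    Returns NaN (undefined marker) when the group x condition has no
    paired-call cells.
    """
    cells = paired_cells(cells)
    sub = cells[(cells["group"] == group) & (cells["condition"] == condition)]
    denom = len(sub)
    if denom == 0:
        return float("nan")
    dom = clones[(clones["group"] == group) & clones[f"dominant_{condition}"]]
    dom_keys = set(map(tuple, dom[CLONE_KEY].itertuples(index=False)))
    member = sum(tuple(t) in dom_keys
                 for t in sub[CLONE_KEY].itertuples(index=False))
    return 100.0 * member / denom


def top_clones_table(clones: pd.DataFrame, group: str,
                     n_top: int = 5) -> pd.DataFrame:
    """Ranked dominant-clone table for one group, pooled across subjects.

    The percentage denominator is the total number of cells in dominant
    clones of that group x condition ("total expanded clones"); percentages
    are integer round-half-up.  Rows rank by max member count across
    conditions (descending), ties by CDR3beta lexicographic order.
    """
    cols = ["trav", "traj", "trbv", "trbj", "cdr3a_aa", "cdr3b_aa",
            "n_unstim", "total_unstim", "pct_unstim",
            "n_stim", "total_stim", "pct_stim"]
    sub = clones[(clones["group"] == group) &
                 (clones["dominant_unstimulated"] | clones["dominant_stimulated"])]
    if sub.empty:
        return pd.DataFrame(columns=cols)
    totals = {
        cond: int(sub.loc[sub[f"dominant_{cond}"], f"n_{cond}"].sum())
        for cond in CONDITIONS
    }
    rows = []
    for rec in sub.itertuples(index=False):
        row = {c: getattr(rec, c) for c in
               ["trav", "traj", "trbv", "trbj", "cdr3a_aa", "cdr3b_aa"]}
        for cond, short in (("unstimulated", "unstim"), ("stimulated", "stim")):
            # a clone dominant in only one condition still reports its
            # (possibly 0 or 1) member count in the other
            n = int(getattr(rec, f"n_{cond}"))
            total = totals[cond]
            row[f"n_{short}"] = n
            row[f"total_{short}"] = total
            row[f"pct_{short}"] = round_half_up_percent(n, total) if total else 0
        rows.append(row)
    table = pd.DataFrame(rows, columns=cols)
    table["_rank"] = table[["n_unstim", "n_stim"]].max(axis=1)
    table = table.sort_values(["_rank", "cdr3b_aa"], ascending=[False, True],
                              kind="mergesort").drop(columns="_rank")
    return table.head(n_top).reset_index(drop=True)


def shared_clones(clones: pd.DataFrame, group_a: str, group_b: str,
                  condition: str, level: str = "usage") -> list[tuple]:
    """Dominant-clone keys present in at least one subject of each group.

    ``level="usage"`` intersects (TRAV, TRAJ, TRBV, TRBJ) combinations;
    ``level="cdr3"`` intersects full (CDR3alpha, CDR3beta) clone keys.
    """
    if level not in ("usage", "cdr3"):
        raise ValueError("level must be 'usage' or 'cdr3'")
    key_cols = USAGE_KEY if level == "usage" else ["cdr3a_aa", "cdr3b_aa"]

    def keys(group: str) -> set[tuple]:
        sub = clones[(clones["group"] == group) &
                     clones[f"dominant_{condition}"]]
        return set(map(tuple, sub[key_cols].itertuples(index=False)))

    return sorted(keys(group_a) & keys(group_b))


def usage_matrix(cells: pd.DataFrame, clones: pd.DataFrame, locus: str,
                 by: str = "donor", condition: str | None = None,
                 expanded_only: bool = True,
                 ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row-normalized gene-usage frequency matrix.

    Rows are donors (or groups), columns gene names of one locus (TRAJ,
    TRBV or TRBJ); entries are the fraction of in-scope cells using that
    gene.  Default scope: paired-call cells belonging to dominant clones of
    the given condition.  Also returns row and column orders from
    average-linkage hierarchical clustering on Euclidean distance (the
    heatmap ordering; rendering is left to the caller).
    """
    locus_col = {"TRAJ": "traj", "TRBV": "trbv", "TRBJ": "trbj"}[locus]
    axis_col = {"donor": "subject_id", "group": "group"}[by]
    cells = paired_cells(cells)
    if condition is not None:
        cells = cells[cells["condition"] == condition]
    if expanded_only and condition is not None:
        dom = clones[clones[f"dominant_{condition}"]]
        dom_keys = set(map(tuple, dom[CLONE_KEY].itertuples(index=False)))
        cells = cells[[tuple(t) in dom_keys
                       for t in cells[CLONE_KEY].itertuples(index=False)]]
    if cells.empty:
        return pd.DataFrame(), [], []
    counts = cells.groupby([axis_col, locus_col]).size().unstack(fill_value=0)
    freq = counts.div(counts.sum(axis=1), axis=0)

    def _order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 3:
            return list(frame.index)
        link = hierarchy.linkage(pdist(frame.values, metric="euclidean"),
                                 method="average")
        return [frame.index[i] for i in hierarchy.leaves_list(link)]

    return freq, _order(freq), _order(freq.T)
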