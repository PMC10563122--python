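"""Phenotype-gene frequencies among dominant-clone cells, with two-way
ANOVA (group x stimulation condition) and Tukey HSD multiple comparisons.

The observational unit is the donor: for each donor x condition the
response is the percentage of that donor's dominant-clone cells with a
positive call for the gene.  Main effects and the interaction are tested
with a fixed-effects two-factor ANOVA (Type II sums of squares by default,
appropriate for the unbalanced 4/4/3-donor design; Type I available);
pairwise contrasts among the six group x condition cells use Tukey HSD
with the Tukey-Kramer correction for unequal cell sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .clonality import CLONE_KEY, paired_cells
from .reference import PHENOTYPE_GENES


def phenotype_frequencies(cells: pd.DataFrame, clones: pd.DataFrame,
                          genes=PHENOTYPE_GENES) -> pd.DataFrame:
    """Per-donor x condition percentage of dominant-clone cells per gene.

    A donor x condition with zero dominant-clone cells yields NaN entries
    (undefined, not 0); the denominator is recorded in ``n_cells``.
    """
    cells = paired_cells(cells)
    rows = []
    for (subject, condition), grp in cells.groupby(
            ["subject_id", "condition"], sort=True):
        dom = clones[(clones["subject_id"] == subject) &
                     clones[f"dominant_{condition}"]]
        dom_keys = set(map(tuple, dom[CLONE_KEY].itertuples(index=False)))
        member = grp[[tuple(t) in dom_keys
                      for t in grp[CLONE_KEY].itertuples(index=False)]]
        n = len(member)
        row = {"subject_id": subject, "group": grp["group"].iloc[0],
               "condition": condition, "n_cells": n}
        for gene in genes:
            row[gene] = 100.0 * member[gene].sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    gene: str
    table: pd.DataFrame   # effect, sum_sq, df, F, p
    tukey: pd.DataFrame   # cell-pair contrasts with Tukey-adjusted p
    ss_total: float


def two_way_anova(freq: pd.DataFrame, gene: str, ss_type: int = 2,
                  tukey: bool = True) -> AnovaResult:
    """Fixed-effects two-factor ANOVA of one gene's donor frequencies.

    ``freq`` is the phenotype_frequencies table.  Tests group, condition
    and their interaction; Tukey HSD runs over the group x condition cell
    labels.  Raises when a factor level has no observations.
    """
    data = freq[["subject_id", "group", "condition", gene]].dropna()
    data = data.rename(columns={gene: "value"})
    for factor in ("group", "condition"):
        counts = data[factor].value_counts()
        empty = [lev for lev in freq[factor].unique()
                 if counts.get(lev, 0) == 0]
        if empty:
            raise ValueError(f"factor {factor!r} level(s) {empty} have no "
                             f"observations for gene {gene}")
    if data["group"].nunique() < 2 or data["condition"].nunique() < 2:
        raise ValueError("need >=2 groups and 2 conditions")

    model = smf.ols("value ~ C(group) * C(condition)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    aov = aov.rename(index={
        "C(group)": "group", "C(condition)": "condition",
        "C(group):C(condition)": "interaction", "Residual": "residual"})
    y = data["value"].values
    ss_total = float(np.sum((y - y.mean()) ** 2))

    # degenerate data (all observations equal): 0/0 F ratios are reported
    # as "no effect" rather than NaN
    if ss_total < 1e-12 * max(1.0, float(np.mean(y) ** 2)):
        aov["F"] = 0.0
        aov["PR(>F)"] = 1.0
        aov.loc["residual", ["F", "PR(>F)"]] = np.nan

    table = aov.reset_index().rename(columns={
        "index": "effect", "PR(>F)": "p"})

    cell = data["group"] + ":" + data["condition"]
    if tukey and ss_total > 0 and cell.nunique() >= 2 and \
            len(data) > cell.nunique():
        tk = pairwise_tukeyhsd(data["value"].values, cell.values)
        tukey = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
    else:
        tukey = pd.DataFrame()
    return AnovaResult(gene=gene, table=table, tukey=tukey, ss_total=ss_total)


def anova_all_genes(freq: pd.DataFrame, genes=PHENOTYPE_GENES,
                    ss_type: int = 2) -> pd.DataFrame:
    """Long-format ANOVA table (gene x effect) over a gene panel."""
    rows = []
    for gene in genes:
        res = two_way_anova(freq, gene, ss_type=ss_type)
        for rec in res.table.itertuples(index=False):
            if rec.effect == "residual":
                continue
            rows.append({"gene": gene, "effect": rec.effect,
                         "F": rec.F, "df": rec.df, "p": rec.p})
    return pd.DataFrame(rows)
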