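#!/usr/bin/env python
"""Clonal structure: expansion fractions, top dominant clones, shared
clones across groups, and gene-usage matrices.

Also recomputes the published dominant-clone percentages from their raw
(n, total) counts as a worked check of the percentage rule.  Writes
clones.tsv, expansion.tsv, top_clones_<group>.tsv, shared_clones.tsv and
usage_<locus>_<condition>.tsv under results/.
"""

import argparse
import itertools
from pathlib import Path

import pandas as pd

import maitseq as m
from maitseq.clonality import round_half_up_percent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cells", type=Path, default=Path("results/cells.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=5)
    args = ap.parse_args()

    cells = pd.read_csv(args.cells, sep="\t").fillna("")
    clones = m.define_clones(cells)
    clones.to_csv(args.out / "clones.tsv", sep="\t", index=False)

    rows = []
    for g in ("HD", "PR", "EC"):
        for c in ("unstimulated", "stimulated"):
            frac = m.expansion_fraction(cells, clones, g, c)
            rows.append({"group": g, "condition": c, "expansion_pct": frac})
            print(f"{g} {c:13s}: {frac:.1f}% of paired cells in dominant clones")
    pd.DataFrame(rows).to_csv(args.out / "expansion.tsv", sep="\t", index=False)

    for g in ("HD", "PR", "EC"):
        top = m.top_clones_table(clones, g, n_top=args.top)
        top.to_csv(args.out / f"top_clones_{g}.tsv", sep="\t", index=False)

    shared_rows = []
    for c in ("unstimulated", "stimulated"):
        for a, b in itertools.combinations(("HD", "PR", "EC"), 2):
            for key in m.shared_clones(clones, a, b, c, level="usage"):
                shared_rows.append({"condition": c, "group_a": a, "group_b": b,
                                    "trav": key[0], "traj": key[1],
                                    "trbv": key[2], "trbj": key[3]})
    pd.DataFrame(shared_rows).to_csv(args.out / "shared_clones.tsv", sep="\t",
                                     index=False)
    print(f"{len(shared_rows)} shared dominant usage keys across group pairs")

    for locus in ("TRAJ", "TRBV", "TRBJ"):
        for c in ("unstimulated", "stimulated"):
            freq, row_order, col_order = m.usage_matrix(
                cells, clones, locus, by="donor", condition=c)
            if freq.empty:
                continue
            ordered = freq.loc[row_order, col_order]
            ordered.to_csv(args.out / f"usage_{locus}_{c}.tsv", sep="\t")

    # worked check on the published counts
    table = m.cohort.dominant_clone_table()
    mismatches = sum(
        round_half_up_percent(r.n_unstim, r.total_unstim) != r.pct_unstim
        or round_half_up_percent(r.n_stim, r.total_stim) != r.pct_stim
        for r in table.itertuples(index=False))
    print(f"published percentage rule: {len(table) * 2 - mismatches}/"
          f"{len(table) * 2} printed percentages reproduced")


if __name__ == "__main__":
    main()
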