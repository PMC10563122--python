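"""Published cohort summary: dominant MAIT clones from an HIV study cohort.

The tables below are the printed dominant-clone summaries for a cohort of
healthy donors (HD), ART-treated HIV progressors (PR) and HIV elite
controllers (EC): for each group's top expanded clones, the gene-segment
usage, the paired CDR3 amino-acid sequences, and the clone's member-cell
count against the group's total expanded-clone cells in each stimulation
condition, with the published integer percentage.  They serve as worked
inputs for the percentage, length and position analyses.

Note: one printed CDR3beta ("CASSIGLGSSYEQYV") ends in V rather than the
canonical F/W; it is kept verbatim.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["group", "trav", "traj", "trbv", "trbj", "cdr3a_aa", "cdr3b_aa",
            "n_unstim", "total_unstim", "pct_unstim",
            "n_stim", "total_stim", "pct_stim"]

_ROWS = [
    ("HD", "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-5",
     "CVPMDSNYQLIW", "CSARLGTPNQAGVQETQYF", 12, 139, 9, 11, 104, 11),
    ("HD", "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-7",
     "CAVLDSNYQLIW", "CSATRGPDFYEQYF", 12, 139, 9, 8, 104, 8),
    ("HD", "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-1",
     "CAVLDSNYQLIW", "CSARDVAGDSYNEQFF", 10, 139, 7, 2, 104, 2),
    ("HD", "TRAV1-2", "TRAJ33", "TRBV10-2", "TRBJ2-6",
     "CAVRDSNYQLIW", "CASSETEDGANVLTF", 0, 139, 0, 6, 104, 6),
    ("HD", "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-5",
     "CAVRDSNYQLIW", "CSARLGTPNQAGVQETQYF", 12, 139, 9, 11, 104, 11),
    ("PR", "TRAV1-2", "TRAJ33", "TRBV6-2", "TRBJ2-1",
     "CAGLDSNYQLIW", "CASSSNLGGGGDEQFF", 25, 237, 11, 26, 117, 22),
    ("PR", "TRAV1-2", "TRAJ33", "TRBV6-1", "TRBJ2-2",
     "CAVTNSNYQLIW", "CASSDGTGHTGELFF", 26, 237, 11, 9, 117, 8),
    ("PR", "TRAV1-2", "TRAJ20", "TRBV6-4", "TRBJ1-5",
     "CAVVLGDYKLSF", "CASSSTGEGNQPQHF", 12, 237, 5, 0, 117, 0),
    ("PR", "TRAV1-2", "TRAJ33", "TRBV6-1", "TRBJ2-7",
     "CAGLDSNYQLIW", "CASSIGLGSSYEQYV", 0, 237, 0, 5, 117, 4),
    ("PR", "TRAV1-2", "TRAJ33", "TRBV6-1", "TRBJ2-3",
     "CAVTDSNYQLIW", "CASSPLAGADTQYF", 4, 237, 2, 5, 117, 4),
    ("PR", "TRAV1-2", "TRAJ33", "TRBV4-2", "TRBJ2-7",
     "CAVRDSNYQLIW", "CASSQEGASSYEQYF", 8, 237, 3, 5, 117, 4),
    ("EC", "TRAV1-2", "TRAJ34", "TRBV7-2", "TRBJ2-2",
     "CAVRSSYNTDKLIF", "CASSQDTNTGELFF", 43, 205, 21, 43, 148, 29),
    ("EC", "TRAV1-2", "TRAJ33", "TRBV29-1", "TRBJ2-5",
     "CAVTDSNYQLIW", "CSVEVGTAHSETQYF", 33, 205, 16, 8, 148, 5),
    ("EC", "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-1",
     "CAVSDSNYQLIW", "CSARSPGTHNEQFF", 17, 205, 8, 10, 148, 7),
    ("EC", "TRAV1-2", "TRAJ33", "TRBV30", "TRBJ2-2",
     "CAVRDSNYQLIW", "CAWGQGGGHVGELFF", 4, 205, 2, 12, 148, 8),
    ("EC", "TRAV1-2", "TRAJ33", "TRBV7-2", "TRBJ2-2",
     "CAVRDSNYQLIW", "CASSQDTNTGELFF", 10, 205, 5, 11, 148, 7),
]

# Cohort-level fraction of cells in expanded (dominant) clones, percent.
EXPANSION_PCT = {
    "HD": {"unstimulated": 35, "stimulated": 35},
    "PR": {"unstimulated": 51, "stimulated": 37},
    "EC": {"unstimulated": 55, "stimulated": 51},
}


def dominant_clone_table() -> pd.DataFrame:
    """Published top dominant clones per group, with printed percentages."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def cdr3_alpha_sequences(group: str | None = None) -> list[str]:
    t = dominant_clone_table()
    if group is not None:
        t = t[t["group"] == group]
    return list(t["cdr3a_aa"])


def cdr3_beta_sequences(group: str | None = None) -> list[str]:
    t = dominant_clone_table()
    if group is not None:
        t = t[t["group"] == group]
    return list(t["cdr3b_aa"])
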