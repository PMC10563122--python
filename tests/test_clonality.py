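import numpy as np
import pandas as pd
import pytest

import maitseq as m
from maitseq.clonality import paired_cells, round_half_up_percent


def _cells(rows):
    """rows: (subject, group, condition, cdr3a, cdr3b, trav, traj, trbv, trbj)"""
    recs = []
    for i, (subj, grp, cond, a, b, *usage) in enumerate(rows):
        usage = usage or ["TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-1"]
        recs.append({
            "cell_id": f"c{i}", "subject_id": subj, "group": grp,
            "condition": cond, "cdr3a_aa": a, "cdr3b_aa": b,
            "trav": usage[0], "traj": usage[1], "trbv": usage[2],
            "trbj": usage[3], "paired": True,
        })
    return pd.DataFrame(recs)


def test_identical_pairs_form_one_dominant_clone():
    cells = _cells([("EC1", "EC", "unstimulated",
                     "CAVRSSYNTDKLIF", "CASSQDTNTGELFF")] * 3)
    clones = m.define_clones(cells)
    assert len(clones) == 1
    assert clones.loc[0, "n_unstimulated"] == 3
    assert bool(clones.loc[0, "dominant_unstimulated"])


def test_same_beta_different_alpha_are_distinct_singletons():
    cells = _cells([
        ("HD1", "HD", "unstimulated", "CAVLDSNYQLIW", "CASSQDTNTGELFF"),
        ("HD1", "HD", "unstimulated", "CAVRDSNYQLIW", "CASSQDTNTGELFF"),
    ])
    clones = m.define_clones(cells)
    assert len(clones) == 2
    assert not clones["dominant_unstimulated"].any()


def test_empty_input_empty_clones():
    assert m.define_clones(pd.DataFrame()).empty


def test_expansion_fraction_examples():
    rows = [("HD1", "HD", "unstimulated", "CAVLDSNYQLIW", "CASSAAAAGELFF")] * 3
    rows += [("HD1", "HD", "unstimulated", f"CAVXDSNYQLIW".replace("X", x),
              "CASSBBBBGELFF") for x in "RT"]
    cells = _cells(rows)
    clones = m.define_clones(cells)
    assert m.expansion_fraction(cells, clones, "HD", "unstimulated") == 60.0
    # all singletons
    singles = _cells([("HD1", "HD", "unstimulated", f"CAV{x}DSNYQLIW", "CASSF")
                      for x in "RTLMS"])
    assert m.expansion_fraction(singles, m.define_clones(singles),
                                "HD", "unstimulated") == 0.0
    # all cells one clone
    mono = _cells([("HD1", "HD", "unstimulated", "CAVLDSNYQLIW", "CASSF")] * 4)
    assert m.expansion_fraction(mono, m.define_clones(mono),
                                "HD", "unstimulated") == 100.0
    # empty denominator is undefined, not zero
    assert np.isnan(m.expansion_fraction(mono, m.define_clones(mono),
                                         "EC", "unstimulated"))


@pytest.mark.parametrize("n,total,expected", [
    (43, 205, 21), (43, 148, 29), (25, 237, 11), (26, 117, 22),
    (33, 205, 16), (0, 139, 0), (1, 200, 1),
])
def test_round_half_up_percent(n, total, expected):
    assert round_half_up_percent(n, total) == expected


def test_top_clones_table_ranking_and_percentages():
    rows = []
    rows += [("HD1", "HD", "unstimulated", "CAVADSNYQLIW", "CASSAAAF")] * 3
    rows += [("HD1", "HD", "unstimulated", "CAVBDSNYQLIW", "CASSBBBF")] * 2
    rows += [("HD1", "HD", "unstimulated", "CAVCDSNYQLIW", "CASSCCCF")]
    rows += [("HD1", "HD", "stimulated", "CAVBDSNYQLIW", "CASSBBBF")] * 2
    cells = _cells(rows)
    table = m.top_clones_table(m.define_clones(cells), "HD")
    # denominators: 5 dominant-member cells unstim, 2 stim
    assert list(table["cdr3b_aa"]) == ["CASSAAAF", "CASSBBBF"]
    assert list(table["total_unstim"]) == [5, 5]
    assert list(table["pct_unstim"]) == [60, 40]
    assert list(table["n_stim"]) == [0, 2]
    assert list(table["pct_stim"]) == [0, 100]


def test_top_clones_empty_group():
    cells = _cells([("HD1", "HD", "unstimulated", "CAVADSNYQLIW", "CASSAAAF")])
    assert m.top_clones_table(m.define_clones(cells), "HD").empty


def test_shared_clones_usage_level():
    usage = ["TRAV1-2", "TRAJ33", "TRBV7-2", "TRBJ2-2"]
    rows = [("EC1", "EC", "unstimulated", "CAVADSNYQLIW", "CASSAAAF", *usage)] * 2
    rows += [("HD1", "HD", "unstimulated", "CAVBDSNYQLIW", "CASSBBBF", *usage)] * 2
    rows += [("PR1", "PR", "unstimulated", "CAVCDSNYQLIW", "CASSCCCF",
              "TRAV1-2", "TRAJ20", "TRBV6-2", "TRBJ2-1")] * 2
    clones = m.define_clones(_cells(rows))
    shared = m.shared_clones(clones, "EC", "HD", "unstimulated", level="usage")
    assert shared == [tuple(usage)]
    assert m.shared_clones(clones, "EC", "PR", "unstimulated") == []
    # CDR3-level sharing is stricter: the same usage, different CDR3s
    assert m.shared_clones(clones, "EC", "HD", "unstimulated", level="cdr3") == []
    # a repertoire shares all its dominant usage keys with itself
    assert m.shared_clones(clones, "EC", "EC", "unstimulated") == [tuple(usage)]


def test_usage_matrix_rows_normalized():
    rows = [("HD1", "HD", "unstimulated", "CAVADSNYQLIW", "CASSAAAF",
             "TRAV1-2", "TRAJ33", "TRBV20-1", "TRBJ2-1")] * 2
    rows += [("HD1", "HD", "unstimulated", "CAVBDSNYQLIW", "CASSBBBF",
              "TRAV1-2", "TRAJ33", "TRBV6-2", "TRBJ2-1")] * 2
    cells = _cells(rows)
    clones = m.define_clones(cells)
    freq, row_order, col_order = m.usage_matrix(
        cells, clones, "TRBV", by="donor", condition="unstimulated")
    assert freq.loc["HD1", "TRBV20-1"] == 0.5
    assert freq.loc["HD1", "TRBV6-2"] == 0.5
    assert np.allclose(freq.sum(axis=1), 1.0)
    traj, _, _ = m.usage_matrix(cells, clones, "TRAJ", by="donor",
                                condition="unstimulated")
    assert list(traj.columns) == ["TRAJ33"]
    assert (traj["TRAJ33"] == 1.0).all()


def test_clone_counts_partition_paired_cells(noisy_run):
    truth = noisy_run["truth"]
    clones = m.define_clones(truth)
    for (subj, cond), grp in truth.groupby(["subject_id", "condition"]):
        total = clones[clones["subject_id"] == subj][f"n_{cond}"].sum()
        assert total == len(paired_cells(grp))


def test_adding_singleton_never_increases_expansion():
    rows = [("HD1", "HD", "unstimulated", "CAVADSNYQLIW", "CASSAAAF")] * 3
    rows += [("HD1", "HD", "unstimulated", "CAVBDSNYQLIW", "CASSBBBF")]
    cells = _cells(rows)
    before = m.expansion_fraction(cells, m.define_clones(cells),
                                  "HD", "unstimulated")
    extra = _cells(rows + [("HD1", "HD", "unstimulated",
                            "CAVZDSNYQLIW", "CASSZZZF")])
    after = m.expansion_fraction(extra, m.define_clones(extra),
                                 "HD", "unstimulated")
    assert after <= before


def test_simulated_ec_subject_biased_to_trbv7_2(panel, noisy_run):
    truth = noisy_run["truth"]
    clones = m.define_clones(truth)
    freq, _, _ = m.usage_matrix(truth, clones, "TRBV", by="donor",
                                condition="unstimulated")
    assert freq.loc["EC1"].idxmax() == "TRBV7-2"
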