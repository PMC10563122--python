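import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import maitseq as m
from maitseq.reference import PHENOTYPE_GENES


def _cells_with_phenotypes(rows):
    """rows: (subject, group, condition, cdr3a, cdr3b, ifng)"""
    recs = []
    for i, (subj, grp, cond, a, b, ifng) in enumerate(rows):
        rec = {"cell_id": f"c{i}", "subject_id": subj, "group": grp,
               "condition": cond, "cdr3a_aa": a, "cdr3b_aa": b,
               "trav": "TRAV1-2", "traj": "TRAJ33", "trbv": "TRBV20-1",
               "trbj": "TRBJ2-1", "paired": True}
        for gene in PHENOTYPE_GENES:
            rec[gene] = 0
        rec["IFNG"] = ifng
        recs.append(rec)
    return pd.DataFrame(recs)


def test_phenotype_frequency_among_dominant_cells():
    rows = [("HD1", "HD", "unstimulated", "CAVADSNYQLIW", "CASSAAAF",
             int(i < 7)) for i in range(10)]
    # plus a singleton that must not enter the denominator
    rows.append(("HD1", "HD", "unstimulated", "CAVZDSNYQLIW", "CASSZZZF", 1))
    cells = _cells_with_phenotypes(rows)
    clones = m.define_clones(cells)
    freq = m.phenotype_frequencies(cells, clones)
    row = freq[(freq["subject_id"] == "HD1") &
               (freq["condition"] == "unstimulated")].iloc[0]
    assert row["n_cells"] == 10
    assert row["IFNG"] == pytest.approx(70.0)
    assert row["TNF"] == 0.0


def test_donor_without_dominant_cells_is_undefined():
    rows = [("HD1", "HD", "unstimulated", f"CAV{x}DSNYQLIW", "CASSAAAF", 1)
            for x in "RTL"]
    cells = _cells_with_phenotypes(rows)
    freq = m.phenotype_frequencies(cells, m.define_clones(cells))
    assert freq["n_cells"].iloc[0] == 0
    assert np.isnan(freq["IFNG"].iloc[0])


def _freq_frame(values):
    """values: {(group, condition): [donor values]}"""
    rows = []
    for (grp, cond), vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"subject_id": f"{grp}{i + 1}", "group": grp,
                         "condition": cond, "n_cells": 10, "IFNG": v})
    return pd.DataFrame(rows)


def test_anova_matches_hand_computed_sums_of_squares():
    # balanced 2x2 with 3 donors per cell
    values = {
        ("HD", "unstimulated"): [10.0, 12.0, 14.0],
        ("HD", "stimulated"): [50.0, 55.0, 60.0],
        ("PR", "unstimulated"): [11.0, 13.0, 12.0],
        ("PR", "stimulated"): [20.0, 25.0, 21.0],
    }
    freq = _freq_frame(values)
    res = m.two_way_anova(freq, "IFNG", ss_type=2)
    table = res.table.set_index("effect")

    # independent oracle: textbook balanced two-factor decomposition
    y = np.array(sum(values.values(), []))
    grand = y.mean()
    a_means = {g: np.mean(values[(g, "unstimulated")] + values[(g, "stimulated")])
               for g in ("HD", "PR")}
    b_means = {c: np.mean(values[("HD", c)] + values[("PR", c)])
               for c in ("unstimulated", "stimulated")}
    cell_means = {k: np.mean(v) for k, v in values.items()}
    n_per_cell = 3
    ss_a = 2 * n_per_cell * sum((v - grand) ** 2 for v in a_means.values())
    ss_b = 2 * n_per_cell * sum((v - grand) ** 2 for v in b_means.values())
    ss_ab = n_per_cell * sum(
        (cell_means[(g, c)] - a_means[g] - b_means[c] + grand) ** 2
        for g in ("HD", "PR") for c in ("unstimulated", "stimulated"))
    ss_res = sum((x - cell_means[k]) ** 2
                 for k, v in values.items() for x in v)
    f_a = (ss_a / 1) / (ss_res / 8)
    f_b = (ss_b / 1) / (ss_res / 8)
    f_ab = (ss_ab / 1) / (ss_res / 8)

    assert table.loc["group", "F"] == pytest.approx(f_a, rel=1e-9)
    assert table.loc["condition", "F"] == pytest.approx(f_b, rel=1e-9)
    assert table.loc["interaction", "F"] == pytest.approx(f_ab, rel=1e-9)
    total = table["sum_sq"].sum()
    assert total == pytest.approx(res.ss_total, rel=1e-9)


def test_anova_all_equal_reports_no_effect():
    values = {(g, c): [42.0, 42.0, 42.0]
              for g in ("HD", "PR") for c in ("unstimulated", "stimulated")}
    res = m.two_way_anova(_freq_frame(values), "IFNG")
    effects = res.table.set_index("effect").loc[
        ["group", "condition", "interaction"]]
    assert (effects["F"] == 0.0).all()
    assert (effects["p"] == 1.0).all()


def test_missing_factor_level_is_an_error():
    values = {("HD", "unstimulated"): [1.0, 2.0],
              ("HD", "stimulated"): [3.0, 4.0],
              ("PR", "unstimulated"): [5.0, 6.0],
              ("PR", "stimulated"): [7.0, 8.0]}
    freq = _freq_frame(values)
    freq.loc[freq["group"] == "PR", "IFNG"] = np.nan
    with pytest.raises(ValueError, match="PR"):
        m.two_way_anova(freq, "IFNG")


def test_tukey_adjusted_p_not_below_pairwise_p():
    rng = np.random.default_rng(7)
    values = {(g, c): list(rng.normal(50, 8, size=4))
              for g in ("HD", "PR", "EC")
              for c in ("unstimulated", "stimulated")}
    freq = _freq_frame(values)
    res = m.two_way_anova(freq, "IFNG")
    data = freq.assign(cell=freq["group"] + ":" + freq["condition"])
    assert not res.tukey.empty
    for _, rec in res.tukey.iterrows():
        a = data.loc[data["cell"] == rec["group1"], "IFNG"]
        b = data.loc[data["cell"] == rec["group2"], "IFNG"]
        raw_p = sps.ttest_ind(a, b).pvalue
        assert float(rec["p-adj"]) >= raw_p - 1e-9


def test_simulated_hd_ifng_responds_to_stimulation(panel):
    cfg = m.SimulationConfig(n_subjects={"HD": 2, "PR": 1, "EC": 1},
                             cells_per_subject_condition=60, seed=21)
    truth = m.truth_cells_frame(m.simulate_repertoire(panel, cfg))
    clones = m.define_clones(truth)
    freq = m.phenotype_frequencies(truth, clones)
    hd = freq[freq["group"] == "HD"]
    stim = hd.loc[hd["condition"] == "stimulated", "IFNG"].mean()
    unstim = hd.loc[hd["condition"] == "unstimulated", "IFNG"].mean()
    assert stim > unstim
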