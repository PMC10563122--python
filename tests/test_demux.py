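import numpy as np
import pandas as pd
import pytest

import maitseq as m
from maitseq.demux import CallThresholds, WellReadSet, bucket_reads, call_cell
from maitseq.reference import BARCODE_LEN
from maitseq.simulate import make_chain

from conftest import concordant_first_calls, merge_with_truth


def _chain_read(panel, chain, v_name, j_name, middle_nt):
    """Assemble an error-free chain read body (no barcodes)."""
    v = panel.segment(v_name)
    j = panel.segment(j_name)
    return v.seq + middle_nt + j.seq + panel.constant_tags[chain]


def test_error_free_reads_all_assigned_to_truth_wells(clean_run, panel):
    wells, stats = m.demultiplex(clean_run["reads"], panel, max_mismatch=0)
    assert stats["unassigned"] == 0
    truth = clean_run["reads_truth"].set_index("read_id")
    for (plate, well), bucket in wells.items():
        for rid, _seq in bucket:
            assert truth.loc[rid, "plate_id"] == plate
            assert truth.loc[rid, "well"] == well


def test_single_barcode_mismatch_recovered_only_at_mm1(clean_run, panel):
    # mutate the first base of the 5' barcode of 50 reads
    mutated = []
    for rid, seq in clean_run["reads"][:50]:
        sub = "C" if seq[0] != "C" else "A"
        mutated.append((rid, sub + seq[1:]))
    _, stats1 = m.demultiplex(mutated, panel, max_mismatch=1)
    _, stats0 = m.demultiplex(mutated, panel, max_mismatch=0)
    assert stats1["assigned"] == 50
    assert stats0["assigned"] == 0
    assert stats0["unassigned"] == 50


def test_unmatched_3p_barcode_is_unassigned(clean_run, panel):
    rid, seq = clean_run["reads"][0]
    bad = seq[:-BARCODE_LEN] + "N" * BARCODE_LEN
    wells, stats = m.demultiplex([(rid, bad)], panel, max_mismatch=1)
    assert stats == {"total": 1, "assigned": 0, "unassigned": 1}
    assert wells == {}


def test_assigned_plus_unassigned_conserved(noisy_run, panel):
    _, stats = m.demultiplex(noisy_run["reads"], panel, max_mismatch=1)
    assert stats["assigned"] + stats["unassigned"] == stats["total"]
    assert stats["total"] == len(noisy_run["reads"])


def test_classify_amplicon(panel):
    beta_read = _chain_read(panel, "beta", "TRBV20-1", "TRBJ2-5", "GCTGCTGCT")
    assert m.classify_amplicon(beta_read, panel) == "beta"
    alpha_read = _chain_read(panel, "alpha", "TRAV1-2", "TRAJ33", "GCTGCTGCT")
    assert m.classify_amplicon(alpha_read, panel) == "alpha"
    assert m.classify_amplicon(panel.phenotype_genes["IFNG"], panel) == \
        "phenotype:IFNG"
    assert m.classify_amplicon("ACGT" * 20, panel) == "unclassified"


def test_assign_vj_exact_call(panel):
    rng = np.random.default_rng(0)
    v, j = panel.segment("TRBV20-1"), panel.segment("TRBJ2-5")
    chain = make_chain(rng, panel, v, j, cdr3_len=14)
    read = chain.amplicon + panel.constant_tags["beta"]
    call = m.assign_vj(read, panel, "beta")
    assert call == ("TRBV20-1", "TRBJ2-5", chain.cdr3_nt, chain.cdr3_aa)


def test_assign_vj_rejects_broken_cdr3(panel):
    rng = np.random.default_rng(1)
    v, j = panel.segment("TRBV6-1"), panel.segment("TRBJ2-1")
    chain = make_chain(rng, panel, v, j, cdr3_len=14)
    # stop codon inside the CDR3 middle
    pos = v.anchor + 3
    broken = chain.amplicon[:pos] + "TAA" + chain.amplicon[pos + 3:]
    assert m.assign_vj(broken + panel.constant_tags["beta"], panel, "beta") is None
    # truncated before the J anchor (constant tag directly after V)
    truncated = v.seq + panel.constant_tags["beta"]
    assert m.assign_vj(truncated, panel, "beta") is None


def _well_with_beta_reads(panel, read_plan):
    """read_plan: [(middle_nt, n_reads)] all on TRBV20-1/TRBJ2-5."""
    wrs = WellReadSet(plate_id="P01", well="A1")
    for middle, n in read_plan:
        read = _chain_read(panel, "beta", "TRBV20-1", "TRBJ2-5", middle)
        for _ in range(n):
            wrs.add("beta", read)
    return wrs


def test_call_cell_single_cdr3_full_dominance(panel):
    wrs = _well_with_beta_reads(panel, [("GCAGCAGCA", 12)])
    prof = call_cell(wrs, panel)
    assert prof.beta is not None
    assert prof.beta.dominance == 1.0
    assert prof.beta.supporting_reads == 12


def test_call_cell_even_split_asserted_inclusive(panel):
    # two well-separated CDR3s at exactly 50/50: the threshold is inclusive
    # and the count tie breaks lexicographically on the CDR3 nucleotides
    wrs = _well_with_beta_reads(panel, [("GCAGCAGCA", 10), ("TGGTGGTGG", 10)])
    prof = call_cell(wrs, panel)
    assert prof.beta is not None
    assert prof.beta.dominance == 0.5
    first_nt = panel.segment("TRBV20-1").seq[-3:] + "GCAGCAGCA"
    assert prof.beta.cdr3_nt.startswith(first_nt)


def test_call_cell_no_dominant_cdr3(panel):
    wrs = _well_with_beta_reads(
        panel, [("GCAGCAGCA", 40), ("TGGTGGTGG", 35), ("CAACAACAA", 25)])
    prof = call_cell(wrs, panel)
    assert prof.beta is None
    assert "beta_no_dominant" in prof.qc_flags


def test_empty_well_flagged(panel):
    prof = call_cell(WellReadSet(plate_id="P01", well="A1"), panel)
    assert prof.beta is None and prof.alpha_first is None
    assert "empty_well" in prof.qc_flags
    assert not any(prof.phenotype_calls.values())


def test_raising_dominance_threshold_never_adds_chains(noisy_run, panel):
    wells, _ = m.demultiplex(noisy_run["reads"], panel)
    counts = []
    for thr in (0.5, 0.7, 0.9):
        n_chains = 0
        for (plate, well), bucket in wells.items():
            wrs = bucket_reads(bucket, panel, plate, well)
            prof = call_cell(wrs, panel, CallThresholds(min_dominance=thr))
            n_chains += sum(x is not None for x in
                            (prof.beta, prof.alpha_first))
        counts.append(n_chains)
    assert counts[0] >= counts[1] >= counts[2]


def test_default_noise_concordance_at_least_95pct(noisy_run):
    merged = merge_with_truth(noisy_run["called"], noisy_run["truth"])
    ok = sum(concordant_first_calls(r) for _, r in merged.iterrows())
    assert ok / len(merged) >= 0.95
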