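"""Well demultiplexing, amplicon classification, V/J + CDR3 calling.

Reads are assigned to a plate/well by their 5' (well) and 3' (plate)
barcodes, classified as alpha-chain, beta-chain or phenotype-gene amplicons
by their constant/phenotype tag, and chain reads are resolved to
(V gene, J gene, CDR3) by ungapped anchored matching against the panel.

Per-well calls follow a 50% rule throughout: a chain is asserted when its
top CDR3 holds at least half of the chain bucket's extractable reads
(dominance >= 0.5, inclusive, ties broken lexicographically on the CDR3
nucleotide sequence); a phenotype gene is called expressed when its bucket's
dominant (tag-matching) reads clear the same 50% fraction and a minimum
absolute read count.  A second alpha chain is reported when a distinct CDR3
holds at least a configurable secondary fraction (default 25%) of alpha
reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .reference import (
    BARCODE_LEN, MIN_BARCODE_DIST, PHENOTYPE_GENES, ReferencePanel,
    check_barcode_distances, hamming,
)


@dataclass
class CallThresholds:
    min_dominance: float = 0.5        # top-CDR3 share of the chain bucket
    secondary_alpha_frac: float = 0.25
    min_phenotype_reads: int = 10
    max_barcode_mismatch: int = 1
    max_tag_mismatch: int = 4
    min_segment_identity: float = 0.8
    merge_distance: int = 2           # collapse CDR3 variants within this
                                      # Hamming distance of a larger cluster


@dataclass
class WellReadSet:
    plate_id: str
    well: str
    buckets: dict[str, list[str]] = field(default_factory=dict)
    # category in {"alpha", "beta", "phenotype:<gene>", "unclassified"}

    def add(self, category: str, seq: str) -> None:
        self.buckets.setdefault(category, []).append(seq)

    @property
    def total_reads(self) -> int:
        return sum(len(v) for v in self.buckets.values())


@dataclass
class ChainCall:
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    supporting_reads: int
    dominance: float          # supporting / extractable reads in the bucket
    normalized_depth: float   # bucket reads / well's total accepted reads


@dataclass
class CellProfile:
    cell_id: str
    plate_id: str
    well: str
    subject_id: str
    group: str
    condition: str
    beta: ChainCall | None
    alpha_first: ChainCall | None
    alpha_second: ChainCall | None
    phenotype_calls: dict[str, bool]
    phenotype_reads: dict[str, int]
    qc_flags: list[str]

    @property
    def paired(self) -> bool:
        return self.beta is not None and self.alpha_first is not None


# ---------------------------------------------------------------------------
# Barcode matching

class _BarcodeIndex:
    """Exact plus optional 1-mismatch lookup over one barcode table."""

    def __init__(self, table: dict[str, str], max_mismatch: int):
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if max_mismatch == 1:
            check_barcode_distances(list(table.values()), MIN_BARCODE_DIST)
        self.exact = {seq: bid for bid, seq in table.items()}
        self.neighbors: dict[str, str] = {}
        if max_mismatch == 1:
            for bid, seq in table.items():
                for i in range(len(seq)):
                    for b in "ACGT":
                        if b != seq[i]:
                            self.neighbors[seq[:i] + b + seq[i + 1:]] = bid

    def lookup(self, seq: str) -> str | None:
        hit = self.exact.get(seq)
        if hit is not None:
            return hit
        return self.neighbors.get(seq)


def demultiplex(reads: list[tuple[str, str]], panel: ReferencePanel,
                max_mismatch: int = 1,
                ) -> tuple[dict[tuple[str, str], list[tuple[str, str]]], dict]:
    """Assign reads to wells by their flanking barcodes.

    A read is assigned iff *both* barcodes match uniquely within
    ``max_mismatch`` (the panel's pairwise distance >= 3 guarantees
    uniqueness at one mismatch).  Returns ``{(plate, well): [(read_id,
    inner_sequence), ...]}`` plus a stats dict; assigned + unassigned equals
    the input read count.
    """
    idx5 = _BarcodeIndex(panel.barcodes_5p, max_mismatch)
    idx3 = _BarcodeIndex(panel.barcodes_3p, max_mismatch)
    wells: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    stats = {"total": 0, "assigned": 0, "unassigned": 0}
    for rid, seq in reads:
        stats["total"] += 1
        if len(seq) < 2 * BARCODE_LEN + 1:
            stats["unassigned"] += 1
            continue
        well = idx5.lookup(seq[:BARCODE_LEN])
        plate = idx3.lookup(seq[-BARCODE_LEN:])
        if well is None or plate is None:
            stats["unassigned"] += 1
            continue
        stats["assigned"] += 1
        wells[(plate, well)].append((rid, seq[BARCODE_LEN:-BARCODE_LEN]))
    return dict(wells), stats


# ---------------------------------------------------------------------------
# Amplicon classification

def classify_amplicon(seq: str, panel: ReferencePanel,
                      max_tag_mismatch: int = 4) -> str:
    """Classify a demultiplexed read by its best-matching tag.

    Chain constant tags sit at the 3' end of chain amplicons; phenotype
    tags constitute the whole amplicon.  The best tag within
    ``max_tag_mismatch`` wins; ties are unclassified.
    """
    candidates: list[tuple[int, str]] = []
    for chain, tag in panel.constant_tags.items():
        if len(seq) >= len(tag):
            candidates.append((hamming(seq[-len(tag):], tag), chain))
    for gene, tag in panel.phenotype_genes.items():
        if len(seq) == len(tag):
            candidates.append((hamming(seq, tag), f"phenotype:{gene}"))
    candidates = [c for c in candidates if c[0] <= max_tag_mismatch]
    if not candidates:
        return "unclassified"
    candidates.sort(key=lambda c: c[0])
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return "unclassified"
    return candidates[0][1]


def bucket_reads(well_reads: list[tuple[str, str]], panel: ReferencePanel,
                 plate_id: str, well: str,
                 max_tag_mismatch: int = 4) -> WellReadSet:
    wrs = WellReadSet(plate_id=plate_id, well=well)
    for _rid, seq in well_reads:
        wrs.add(classify_amplicon(seq, panel, max_tag_mismatch), seq)
    return wrs


# ---------------------------------------------------------------------------
# V/J assignment and CDR3 extraction

class _SegmentMatcher:
    """Byte-array panel views for fast ungapped identity scoring."""

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self.v = {chain: [(s, np.frombuffer(s.seq.encode(), dtype=np.uint8))
                          for s in panel.v_by_chain(chain)]
                  for chain in ("alpha", "beta")}
        self.j = {chain: [(s, np.frombuffer(s.seq.encode(), dtype=np.uint8))
                          for s in panel.j_by_chain(chain)]
                  for chain in ("alpha", "beta")}


def _identity(read_arr: np.ndarray, start: int, seg_arr: np.ndarray) -> float:
    stop = start + len(seg_arr)
    if start < 0 or stop > len(read_arr):
        return -1.0
    return float(np.count_nonzero(read_arr[start:stop] == seg_arr)) / len(seg_arr)


def assign_vj(seq: str, panel_or_matcher, chain: str,
              max_tag_mismatch: int = 4, min_identity: float = 0.8,
              ) -> tuple[str, str, str, str] | None:
    """Resolve one chain read to (v_gene, j_gene, cdr3_nt, cdr3_aa).

    The V is scored at the read's 5' end, the J immediately upstream of the
    constant tag; the CDR3 is the translated span from the V's conserved
    cysteine codon through the J's conserved Phe/Trp codon, inclusive.
    Returns None when anchors are missing, identity is too low, the frame
    is broken, or the translation violates the C...F/W convention.
    """
    matcher = (panel_or_matcher if isinstance(panel_or_matcher, _SegmentMatcher)
               else _SegmentMatcher(panel_or_matcher))
    tag = matcher.panel.constant_tags[chain]
    if len(seq) < len(tag) or hamming(seq[-len(tag):], tag) > max_tag_mismatch:
        return None
    body = seq[:-len(tag)]
    arr = np.frombuffer(body.encode(), dtype=np.uint8)

    best_v, best_v_score = None, min_identity
    for seg, seg_arr in matcher.v[chain]:
        score = _identity(arr, 0, seg_arr)
        if score > best_v_score:
            best_v, best_v_score = seg, score
    best_j, best_j_score = None, min_identity
    for seg, seg_arr in matcher.j[chain]:
        score = _identity(arr, len(arr) - len(seg_arr), seg_arr)
        if score > best_j_score:
            best_j, best_j_score = seg, score
    if best_v is None or best_j is None:
        return None

    start = best_v.anchor
    end = len(body) - len(best_j.seq) + best_j.anchor + 3
    if end <= start or (end - start) % 3:
        return None
    cdr3_nt = body[start:end]
    cdr3_aa = str(Seq(cdr3_nt).translate())
    if "*" in cdr3_aa or not cdr3_aa or cdr3_aa[0] != "C" or cdr3_aa[-1] not in "FW":
        return None
    return best_v.name, best_j.name, cdr3_nt, cdr3_aa


# ---------------------------------------------------------------------------
# Per-well calling

def _call_chain_bucket(seqs: list[str], matcher: _SegmentMatcher, chain: str,
                       total_well_reads: int, thresholds: CallThresholds,
                       ) -> tuple[list[tuple[tuple, int]], int]:
    """Group a chain bucket's reads by extracted CDR3.

    Sequencing-error denoising: a CDR3 nucleotide variant of the same
    length within ``merge_distance`` substitutions of a more-abundant
    cluster is absorbed into that cluster (its reads support the parent).
    Returns (sorted [(call_tuple, count)] best-first, n_extracted).
    Ordering: count desc, then CDR3 nucleotide sequence ascending, so exact
    ties resolve deterministically.
    """
    counts: Counter = Counter()
    for seq in seqs:
        call = assign_vj(seq, matcher, chain,
                         thresholds.max_tag_mismatch,
                         thresholds.min_segment_identity)
        if call is not None:
            counts[call] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][2]))
    merged: list[list] = []  # [call_tuple, count], abundant first
    for call, n in ranked:
        parent = None
        for m in merged:
            pnt = m[0][2]
            if m[1] > n and len(pnt) == len(call[2]) and \
                    hamming(pnt, call[2]) <= thresholds.merge_distance:
                parent = m
                break
        if parent is None:
            merged.append([call, n])
        else:
            parent[1] += n
    out = sorted(((tuple(c), n) for c, n in merged),
                 key=lambda kv: (-kv[1], kv[0][2]))
    return out, sum(n for _, n in out)


def call_cell(wrs: WellReadSet, panel_or_matcher,
              thresholds: CallThresholds | None = None,
              subject_id: str = "", group: str = "", condition: str = "",
              ) -> CellProfile:
    """Produce per-cell chain and phenotype calls for one well."""
    thresholds = thresholds or CallThresholds()
    matcher = (panel_or_matcher if isinstance(panel_or_matcher, _SegmentMatcher)
               else _SegmentMatcher(panel_or_matcher))
    qc: list[str] = []
    total = wrs.total_reads
    if total == 0:
        qc.append("empty_well")

    def make_call(chain: str, call_tuple: tuple, n: int, extracted: int,
                  bucket_size: int) -> ChainCall:
        v, j, nt, aa = call_tuple
        return ChainCall(chain=chain, v_gene=v, j_gene=j, cdr3_nt=nt,
                         cdr3_aa=aa, supporting_reads=n,
                         dominance=n / extracted,
                         normalized_depth=bucket_size / total if total else 0.0)

    beta = None
    beta_bucket = wrs.buckets.get("beta", [])
    ranked_b, extracted_b = ([], 0)
    if beta_bucket:
        ranked_b, extracted_b = _call_chain_bucket(
            beta_bucket, matcher, "beta", total, thresholds)
    if ranked_b:
        call, n = ranked_b[0]
        if n / extracted_b >= thresholds.min_dominance:
            beta = make_call("beta", call, n, extracted_b, len(beta_bucket))
        else:
            qc.append("beta_no_dominant")
    else:
        qc.append("no_beta_reads")

    alpha_first = alpha_second = None
    alpha_bucket = wrs.buckets.get("alpha", [])
    ranked_a, extracted_a = ([], 0)
    if alpha_bucket:
        ranked_a, extracted_a = _call_chain_bucket(
            alpha_bucket, matcher, "alpha", total, thresholds)
    if ranked_a:
        call, n = ranked_a[0]
        if n / extracted_a >= thresholds.min_dominance:
            alpha_first = make_call("alpha", call, n, extracted_a,
                                    len(alpha_bucket))
            # second alpha: best distinct CDR3 amino-acid sequence
            for call2, n2 in ranked_a[1:]:
                if call2[3] == call[3]:
                    continue
                if n2 / extracted_a >= thresholds.secondary_alpha_frac:
                    alpha_second = make_call("alpha", call2, n2, extracted_a,
                                             len(alpha_bucket))
                break
        else:
            qc.append("alpha_no_dominant")
    else:
        qc.append("no_alpha_reads")

    phenotype_calls: dict[str, bool] = {}
    phenotype_reads: dict[str, int] = {}
    for gene in PHENOTYPE_GENES:
        n = len(wrs.buckets.get(f"phenotype:{gene}", []))
        phenotype_reads[gene] = n
        # classification already requires the tag match, so the dominant
        # (tag-supporting) fraction of this bucket is 1.0 >= 0.5; the call
        # additionally needs a minimum absolute read support.
        phenotype_calls[gene] = n >= thresholds.min_phenotype_reads

    return CellProfile(
        cell_id=f"{wrs.plate_id}_{wrs.well}", plate_id=wrs.plate_id,
        well=wrs.well, subject_id=subject_id, group=group,
        condition=condition, beta=beta, alpha_first=alpha_first,
        alpha_second=alpha_second, phenotype_calls=phenotype_calls,
        phenotype_reads=phenotype_reads, qc_flags=qc)


# ---------------------------------------------------------------------------
# Whole-run pipeline

def call_cells(reads: list[tuple[str, str]], panel: ReferencePanel,
               samples: pd.DataFrame,
               thresholds: CallThresholds | None = None,
               ) -> tuple[pd.DataFrame, dict]:
    """Demultiplex, classify and call every well listed in the sample sheet.

    ``samples`` maps (plate_id, well) to subject/group/condition.  Returns a
    cells table (one row per well in the sheet) and the demux stats dict.
    """
    thresholds = thresholds or CallThresholds()
    wells, stats = demultiplex(reads, panel, thresholds.max_barcode_mismatch)
    matcher = _SegmentMatcher(panel)
    rows = []
    for rec in samples.itertuples(index=False):
        key = (rec.plate_id, rec.well)
        wrs = bucket_reads(wells.get(key, []), panel, rec.plate_id, rec.well,
                           thresholds.max_tag_mismatch)
        prof = call_cell(wrs, matcher, thresholds, rec.subject_id,
                         rec.group, rec.condition)
        rows.append(profile_to_row(prof))
    cells = pd.DataFrame(rows)
    return cells, stats


def profile_to_row(p: CellProfile) -> dict:
    row = {
        "cell_id": p.cell_id, "plate_id": p.plate_id, "well": p.well,
        "subject_id": p.subject_id, "group": p.group, "condition": p.condition,
        "trbv": p.beta.v_gene if p.beta else "",
        "trbj": p.beta.j_gene if p.beta else "",
        "cdr3b_nt": p.beta.cdr3_nt if p.beta else "",
        "cdr3b_aa": p.beta.cdr3_aa if p.beta else "",
        "beta_reads": p.beta.supporting_reads if p.beta else 0,
        "beta_dominance": p.beta.dominance if p.beta else np.nan,
        "trav": p.alpha_first.v_gene if p.alpha_first else "",
        "traj": p.alpha_first.j_gene if p.alpha_first else "",
        "cdr3a_nt": p.alpha_first.cdr3_nt if p.alpha_first else "",
        "cdr3a_aa": p.alpha_first.cdr3_aa if p.alpha_first else "",
        "alpha_reads": p.alpha_first.supporting_reads if p.alpha_first else 0,
        "alpha_dominance": p.alpha_first.dominance if p.alpha_first else np.nan,
        "trav2": p.alpha_second.v_gene if p.alpha_second else "",
        "traj2": p.alpha_second.j_gene if p.alpha_second else "",
        "cdr3a2_aa": p.alpha_second.cdr3_aa if p.alpha_second else "",
        "paired": p.paired,
        "qc_flags": ";".join(p.qc_flags),
    }
    for gene in PHENOTYPE_GENES:
        row[gene] = int(p.phenotype_calls.get(gene, False))
        row[f"{gene}_reads"] = p.phenotype_reads.get(gene, 0)
    return row
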