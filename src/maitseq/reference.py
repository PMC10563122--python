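"""Synthetic reference panel: gene segments, constant/phenotype tags, well barcodes.

The panel is a fully synthetic stand-in for a germline segment database.
Segment *names* follow standard IMGT-style TR nomenclature (TRAV1-2, TRAJ33,
TRBV20-1, ...) so that downstream usage tables read like real repertoire
output, but the sequences themselves are random DNA with fixed CDR3 anchor
positions.  This gives full control over edge cases (anchors, frames,
barcode distances) with no external download.

Conventions
-----------
* V segments carry the conserved cysteine as their **last** codon; the
  anchor index points at that codon (0-based, always a multiple of 3).
* J segments carry the conserved Phe/Trp codon at a small in-frame offset
  from their 5' end; the bases up to and including that codon are the
  J-encoded tail of the CDR3.
* All barcodes within a set are pairwise Hamming distance >= 3, so
  single-mismatch correction is unambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BARCODE_LEN = 8
MIN_BARCODE_DIST = 3

PHENOTYPE_GENES = (
    "IFNG", "TNF", "GZMB", "PRF1", "TBET",
    "GATA3", "RORC", "BCL6", "RUNX1", "RUNX3",
)

# Segments that must always be present so cohort-style usage tables can be
# expressed; extra filler segments are appended on demand.
NAMED_SEGMENTS = {
    "TRAV": ["TRAV1-2"],
    "TRAJ": ["TRAJ33", "TRAJ34", "TRAJ20", "TRAJ12"],
    "TRBV": [
        "TRBV20-1", "TRBV6-1", "TRBV6-2", "TRBV6-4", "TRBV7-2",
        "TRBV29-1", "TRBV30", "TRBV10-2", "TRBV4-2",
    ],
    "TRBJ": [
        "TRBJ1-5", "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-5",
        "TRBJ2-6", "TRBJ2-7",
    ],
}

# J segments whose CDR3 tail ends in tryptophan rather than phenylalanine
# (the canonical TRAJ33 tail ...NYQLIW).
_TRP_ANCHOR_J = {"TRAJ33"}

CYS_CODONS = ("TGT", "TGC")
PHE_CODONS = ("TTT", "TTC")
TRP_CODON = "TGG"
STOP_CODONS = {"TAA", "TAG", "TGA"}

WELL_ROWS = "ABCDEFGH"
WELL_COLS = range(1, 13)
WELL_IDS = tuple(f"{r}{c}" for r in WELL_ROWS for c in WELL_COLS)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Segment:
    """One germline gene segment.

    ``anchor`` is the 0-based nucleotide index of the conserved CDR3
    boundary codon: the cysteine codon for V segments, the Phe/Trp codon
    for J segments.  Reading frame starts at base 0, so the anchor is
    always a multiple of 3.
    """

    name: str
    seq: str
    anchor: int

    @property
    def chain(self) -> str:
        return "alpha" if self.name.startswith("TRA") else "beta"

    @property
    def locus(self) -> str:
        return self.name[:4]


@dataclass
class ReferencePanel:
    v_segments: list[Segment]
    j_segments: list[Segment]
    constant_tags: dict[str, str]          # chain -> tag sequence
    phenotype_genes: dict[str, str]        # gene name -> tag sequence
    barcodes_5p: dict[str, str]            # well id -> barcode
    barcodes_3p: dict[str, str]            # plate id -> barcode

    def v_by_chain(self, chain: str) -> list[Segment]:
        return [s for s in self.v_segments if s.chain == chain]

    def j_by_chain(self, chain: str) -> list[Segment]:
        return [s for s in self.j_segments if s.chain == chain]

    def segment(self, name: str) -> Segment:
        for s in itertools.chain(self.v_segments, self.j_segments):
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def n_plates(self) -> int:
        return len(self.barcodes_3p)

    def validate(self) -> None:
        """Raise ValueError on any violated panel invariant."""
        for s in self.v_segments + self.j_segments:
            if not (0 <= s.anchor <= len(s.seq) - 3):
                raise ValueError(f"{s.name}: anchor outside sequence")
            if s.anchor % 3:
                raise ValueError(f"{s.name}: anchor not in reading frame")
        for cat, segs in (("V", self.v_segments), ("J", self.j_segments)):
            names = [s.name for s in segs]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {cat} gene names")
        if len(set(PHENOTYPE_GENES) - set(self.phenotype_genes)) not in (0, len(PHENOTYPE_GENES)):
            raise ValueError("partial phenotype gene set")
        for label, table in (("5p", self.barcodes_5p), ("3p", self.barcodes_3p)):
            check_barcode_distances(list(table.values()), MIN_BARCODE_DIST, label)


def check_barcode_distances(barcodes: list[str], min_dist: int, label: str = "") -> None:
    for a, b in itertools.combinations(barcodes, 2):
        if hamming(a, b) < min_dist:
            raise ValueError(
                f"barcode set {label}: {a} and {b} at Hamming distance "
                f"{hamming(a, b)} < {min_dist}"
            )


def _random_barcodes(rng: np.random.Generator, n: int, length: int = BARCODE_LEN,
                     min_dist: int = MIN_BARCODE_DIST, max_tries: int = 20000) -> list[str]:
    """Greedy random code with pairwise Hamming distance >= min_dist."""
    chosen: list[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot build {n} barcodes of length {length} at pairwise "
                f"Hamming distance >= {min_dist}"
            )
        cand = "".join(rng.choice(list(NUCLEOTIDES), size=length))
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = _random_dna(rng, 3)
        if codon not in STOP_CODONS:
            return codon


def _make_v_segment(rng: np.random.Generator, name: str) -> Segment:
    """V segment: random body, conserved Cys codon as the last codon."""
    n_codons = int(rng.integers(20, 39))  # 60..114 nt
    body = "".join(_random_sense_codon(rng) for _ in range(n_codons - 1))
    cys = CYS_CODONS[int(rng.integers(0, 2))]
    seq = body + cys
    return Segment(name=name, seq=seq, anchor=len(seq) - 3)


def _make_j_segment(rng: np.random.Generator, name: str) -> Segment:
    """J segment: short in-frame head, conserved Phe/Trp codon, random tail."""
    head_codons = int(rng.integers(1, 3))  # 1 or 2 codons before the anchor
    head = "".join(_random_sense_codon(rng) for _ in range(head_codons))
    if name in _TRP_ANCHOR_J:
        anchor_codon = TRP_CODON
    else:
        anchor_codon = PHE_CODONS[int(rng.integers(0, 2))]
    tail_codons = int(rng.integers(12, 30))
    tail = "".join(_random_sense_codon(rng) for _ in range(tail_codons))
    seq = head + anchor_codon + tail
    return Segment(name=name, seq=seq, anchor=len(head))


def _segment_names(locus: str, n: int) -> list[str]:
    names = list(NAMED_SEGMENTS[locus])
    filler = 1
    while len(names) < n:
        cand = f"{locus}X{filler}"
        if cand not in names:
            names.append(cand)
        filler += 1
    return names


def build_reference(seed: int, n_v_per_locus: int = 4, n_j_per_locus: int = 8,
                    n_plates: int = 36) -> ReferencePanel:
    """Build a deterministic synthetic reference panel.

    Parameters
    ----------
    seed : master seed; the same seed always yields a byte-identical panel.
    n_v_per_locus, n_j_per_locus : requested segment counts per locus; the
        named canonical segments are always included, so the realized count
        is ``max(requested, number of named segments)``.
    n_plates : number of 3' plate barcodes to generate (96 5' well barcodes
        are always generated).
    """
    if n_v_per_locus < 2 or n_j_per_locus < 2:
        raise ValueError("need at least 2 V and 2 J segments per locus")
    rng = np.random.default_rng(seed)

    v_segments = [
        _make_v_segment(rng, name)
        for locus in ("TRAV", "TRBV")
        for name in _segment_names(locus, n_v_per_locus)
    ]
    j_segments = [
        _make_j_segment(rng, name)
        for locus in ("TRAJ", "TRBJ")
        for name in _segment_names(locus, n_j_per_locus)
    ]

    # Constant-region tags: one 20-mer per chain, forced far apart.
    while True:
        alpha_tag = _random_dna(rng, 20)
        beta_tag = _random_dna(rng, 20)
        if hamming(alpha_tag, beta_tag) >= 10:
            break
    constant_tags = {"alpha": alpha_tag, "beta": beta_tag}

    phenotype_tags: dict[str, str] = {}
    for gene in PHENOTYPE_GENES:
        while True:
            tag = _random_dna(rng, 30)
            if all(hamming(tag, t) >= 10 for t in phenotype_tags.values()):
                phenotype_tags[gene] = tag
                break

    bc5 = _random_barcodes(rng, len(WELL_IDS))
    bc3 = _random_barcodes(rng, n_plates)
    panel = ReferencePanel(
        v_segments=v_segments,
        j_segments=j_segments,
        constant_tags=constant_tags,
        phenotype_genes=phenotype_tags,
        barcodes_5p=dict(zip(WELL_IDS, bc5)),
        barcodes_3p={f"P{i + 1:02d}": b for i, b in enumerate(bc3)},
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# On-disk form: segments and tags as FASTA, anchors/barcodes as a TSV annex.

def write_panel(panel: ReferencePanel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(s.seq), id=s.name, description=f"category=V anchor={s.anchor}")
        for s in panel.v_segments
    ] + [
        SeqRecord(Seq(s.seq), id=s.name, description=f"category=J anchor={s.anchor}")
        for s in panel.j_segments
    ] + [
        SeqRecord(Seq(t), id=f"C_{chain}", description="category=constant_tag")
        for chain, t in panel.constant_tags.items()
    ] + [
        SeqRecord(Seq(t), id=f"PHENO_{g}", description="category=phenotype_tag")
        for g, t in panel.phenotype_genes.items()
    ]
    SeqIO.write(records, out / "panel.fasta", "fasta")
    with open(out / "panel_annex.tsv", "w") as fh:
        fh.write("record_type\tname\tvalue\tanchor\n")
        for s in panel.v_segments:
            fh.write(f"V\t{s.name}\t{s.seq}\t{s.anchor}\n")
        for s in panel.j_segments:
            fh.write(f"J\t{s.name}\t{s.seq}\t{s.anchor}\n")
        for chain, t in panel.constant_tags.items():
            fh.write(f"constant_tag\t{chain}\t{t}\t\n")
        for g, t in panel.phenotype_genes.items():
            fh.write(f"phenotype_tag\t{g}\t{t}\t\n")
        for wid, b in panel.barcodes_5p.items():
            fh.write(f"barcode_5p\t{wid}\t{b}\t\n")
        for pid, b in panel.barcodes_3p.items():
            fh.write(f"barcode_3p\t{pid}\t{b}\t\n")


def read_panel(in_dir: str | Path) -> ReferencePanel:
    annex = Path(in_dir) / "panel_annex.tsv"
    v_segments, j_segments = [], []
    constant_tags: dict[str, str] = {}
    phenotype_genes: dict[str, str] = {}
    bc5: dict[str, str] = {}
    bc3: dict[str, str] = {}
    with open(annex) as fh:
        header = fh.readline()
        assert header.startswith("record_type")
        for line in fh:
            rtype, name, value, anchor = line.rstrip("\n").split("\t")
            if rtype == "V":
                v_segments.append(Segment(name, value, int(anchor)))
            elif rtype == "J":
                j_segments.append(Segment(name, value, int(anchor)))
            elif rtype == "constant_tag":
                constant_tags[name] = value
            elif rtype == "phenotype_tag":
                phenotype_genes[name] = value
            elif rtype == "barcode_5p":
                bc5[name] = value
            elif rtype == "barcode_3p":
                bc3[name] = value
    panel = ReferencePanel(v_segments, j_segments, constant_tags,
                           phenotype_genes, bc5, bc3)
    panel.validate()
    return panel
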