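"""Ground-truth repertoire and read simulator.

Emulates a plate-based single-cell paired TCR experiment: sorted MAIT-like
cells in 96-well plates, each well yielding barcoded amplicon reads for the
beta chain, one or two alpha chains, and a panel of on/off phenotype genes.
The clonal structure mirrors the study design the analysis assumes: three
donor groups (HD = healthy donors, PR = treated progressors, EC = elite
controllers), two stimulation conditions, ~140 cells per subject and
condition, a configurable fraction of cells sitting in expanded clones
(>= 2 cells with identical paired CDR3s), group-biased TRAJ/TRBV usage
(including a TRAJ34/TRBV7-2-dominated "EC-like" subject), dual-alpha cells,
log-normal per-well read depth, flat substitution errors and cross-well
contamination.

Every draw flows from one master seed, so identical configuration yields
byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .reference import (
    NUCLEOTIDES, PHENOTYPE_GENES, STOP_CODONS, WELL_IDS,
    ReferencePanel, Segment,
)

GROUPS = ("HD", "PR", "EC")
CONDITIONS = ("unstimulated", "stimulated")

# aa -> synonymous codons, from the standard genetic code
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


def default_expanded_fraction() -> dict[str, dict[str, float]]:
    """Target fraction of cells in expanded clones, per group x condition.

    Defaults follow the cohort-level expansion pattern the analysis was
    designed around: HD 35%/35%, PR 51%/37%, EC 55%/51%
    (unstimulated/stimulated).
    """
    return {
        "HD": {"unstimulated": 0.35, "stimulated": 0.35},
        "PR": {"unstimulated": 0.51, "stimulated": 0.37},
        "EC": {"unstimulated": 0.55, "stimulated": 0.51},
    }


def default_usage_weights() -> dict[str, dict[str, dict[str, float]]]:
    """Group-specific gene-usage weights per locus (normalized at sampling).

    HD lean on the canonical TRAJ33 with TRBV20-1/TRBV6 family; EC carry
    extra weight on TRAJ34, TRBV7-2/TRBV29-1/TRBV30 and TRBJ2-2.
    """
    return {
        "HD": {
            "TRAV": {"TRAV1-2": 1.0},
            "TRAJ": {"TRAJ33": 0.80, "TRAJ12": 0.10, "TRAJ20": 0.10},
            "TRBV": {"TRBV20-1": 0.35, "TRBV6-1": 0.15, "TRBV6-2": 0.15,
                     "TRBV6-4": 0.10, "TRBV10-2": 0.10, "TRBV4-2": 0.05,
                     "TRBV29-1": 0.05, "TRBV30": 0.05},
            "TRBJ": {"TRBJ2-5": 0.20, "TRBJ2-7": 0.15, "TRBJ2-1": 0.20,
                     "TRBJ2-6": 0.15, "TRBJ1-5": 0.10, "TRBJ2-2": 0.10,
                     "TRBJ2-3": 0.10},
        },
        "PR": {
            "TRAV": {"TRAV1-2": 1.0},
            "TRAJ": {"TRAJ33": 0.80, "TRAJ20": 0.15, "TRAJ12": 0.05},
            "TRBV": {"TRBV6-2": 0.30, "TRBV6-1": 0.20, "TRBV20-1": 0.20,
                     "TRBV4-2": 0.10, "TRBV6-4": 0.10, "TRBV29-1": 0.10},
            "TRBJ": {"TRBJ2-1": 0.25, "TRBJ2-2": 0.15, "TRBJ1-5": 0.15,
                     "TRBJ2-7": 0.15, "TRBJ2-3": 0.15, "TRBJ2-5": 0.15},
        },
        "EC": {
            "TRAV": {"TRAV1-2": 1.0},
            "TRAJ": {"TRAJ33": 0.60, "TRAJ34": 0.30, "TRAJ20": 0.10},
            "TRBV": {"TRBV7-2": 0.35, "TRBV29-1": 0.15, "TRBV30": 0.15,
                     "TRBV20-1": 0.20, "TRBV6-2": 0.15},
            "TRBJ": {"TRBJ2-2": 0.30, "TRBJ2-5": 0.20, "TRBJ2-1": 0.20,
                     "TRBJ2-7": 0.15, "TRBJ1-5": 0.15},
        },
    }


def default_phenotype_on_prob() -> dict[str, dict[str, dict[str, float]]]:
    """P(gene transcribed) per gene x group x condition.

    IFNG is the one gene with a strong stimulation response in HD and a
    blunted response in the HIV groups; the remaining effector and
    transcription-factor genes respond mildly and uniformly.
    """
    probs: dict[str, dict[str, dict[str, float]]] = {}
    flat = {"TNF": 0.30, "GZMB": 0.40, "PRF1": 0.30, "TBET": 0.50,
            "GATA3": 0.20, "RORC": 0.30, "BCL6": 0.15, "RUNX1": 0.50,
            "RUNX3": 0.40}
    for gene, p in flat.items():
        probs[gene] = {g: {"unstimulated": p, "stimulated": min(1.0, p + 0.10)}
                       for g in GROUPS}
    probs["IFNG"] = {
        "HD": {"unstimulated": 0.15, "stimulated": 0.65},
        "PR": {"unstimulated": 0.10, "stimulated": 0.25},
        "EC": {"unstimulated": 0.10, "stimulated": 0.25},
    }
    return probs


@dataclass
class SimulationConfig:
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"HD": 4, "PR": 4, "EC": 3})
    cells_per_subject_condition: int = 140
    expanded_fraction: dict[str, dict[str, float]] = field(
        default_factory=default_expanded_fraction)
    clone_size_geom_p: float = 0.45       # clone size = 2 + Geometric(p) - 1
    dominant_pool_size: int = 8           # candidate expanded clonotypes/subject
    usage_weights: dict = field(default_factory=default_usage_weights)
    dual_alpha_prob: float = 0.15
    cdr3a_length_weights: dict[int, float] = field(
        default_factory=lambda: {11: 0.05, 12: 0.55, 13: 0.10, 14: 0.20, 16: 0.10})
    cdr3b_length_weights: dict[int, float] = field(
        default_factory=lambda: {11: 0.05, 12: 0.10, 13: 0.15, 14: 0.20,
                                 15: 0.20, 16: 0.12, 17: 0.08, 18: 0.06,
                                 19: 0.04})
    reads_per_chain_median: float = 40.0  # log-normal median, per chain bucket
    reads_per_chain_sigma: float = 0.6
    min_reads_per_chain: int = 5
    reads_per_phenotype_median: float = 25.0
    reads_per_phenotype_sigma: float = 0.5
    error_rate: float = 0.005             # substitutions per base
    contamination_rate: float = 0.02      # reads re-barcoded to another well
    phenotype_on_prob: dict = field(default_factory=default_phenotype_on_prob)
    n_plates: int | None = None           # default: derived from cell count
    seed: int = 0

    def validate(self) -> None:
        for g, conds in self.expanded_fraction.items():
            for c, f in conds.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"expanded_fraction[{g}][{c}]={f} outside [0,1]")
        for p in (self.dual_alpha_prob, self.error_rate, self.contamination_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        for table in (self.cdr3a_length_weights, self.cdr3b_length_weights):
            if any(w < 0 for w in table.values()) or sum(table.values()) <= 0:
                raise ValueError("length weights must be nonnegative, not all zero")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass(frozen=True)
class Chain:
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    amplicon: str  # V + CDR3 middle + J (constant tag appended at read time)


@dataclass(frozen=True)
class Clonotype:
    clone_id: str
    beta: Chain
    alphas: tuple[Chain, ...]  # 1 or 2


@dataclass
class TruthCell:
    cell_id: str
    subject_id: str
    group: str
    condition: str
    plate_id: str
    well: str
    beta: Chain
    alphas: tuple[Chain, ...]
    phenotype_state: dict[str, bool]
    clone_id: str


def _weighted_choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = sorted(table)
    w = np.array([table[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def _encode_aa(rng: np.random.Generator, aa: str) -> str:
    return "".join(_CODONS_BY_AA[a][int(rng.integers(0, len(_CODONS_BY_AA[a])))]
                   for a in aa)


def make_chain(rng: np.random.Generator, panel: ReferencePanel, v: Segment,
               j: Segment, cdr3_len: int) -> Chain:
    """Assemble a chain whose CDR3 spans the V cysteine to the J Phe/Trp.

    The CDR3 consists of the V's terminal Cys codon, a random in-frame
    middle (the "N region"), and the J head through its anchor codon.  The
    amplicon is simply V + middle + J, so translating between the anchors
    reproduces the CDR3 exactly.
    """
    j_tail_aa = len(j.seq[: j.anchor + 3]) // 3
    middle_len = cdr3_len - 1 - j_tail_aa
    if middle_len < 0:
        raise ValueError(f"CDR3 length {cdr3_len} too short for {j.name}")
    middle_aa = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=middle_len))
    middle_nt = _encode_aa(rng, middle_aa)
    cdr3_nt = v.seq[v.anchor:] + middle_nt + j.seq[: j.anchor + 3]
    cdr3_aa = str(Seq(cdr3_nt).translate())
    assert cdr3_aa[0] == "C" and cdr3_aa[-1] in "FW" and "*" not in cdr3_aa
    amplicon = v.seq + middle_nt + j.seq
    return Chain(v.name, j.name, cdr3_nt, cdr3_aa, amplicon)


class _ClonotypeFactory:
    def __init__(self, panel: ReferencePanel, config: SimulationConfig):
        self.panel = panel
        self.config = config
        self._counter = 0
        self._v = {s.name: s for s in panel.v_segments}
        self._j = {s.name: s for s in panel.j_segments}

    def _sample_len(self, rng, weights: dict[int, float], j: Segment) -> int:
        min_len = 1 + len(j.seq[: j.anchor + 3]) // 3 + 1  # C + >=1 middle + J tail
        table = {L: w for L, w in weights.items() if L >= min_len}
        return int(_weighted_choice(rng, {str(k): v for k, v in table.items()}))

    def new(self, rng: np.random.Generator, group: str,
            forced_usage: dict[str, str] | None = None) -> Clonotype:
        w = self.config.usage_weights[group]
        forced = forced_usage or {}

        def pick(locus: str) -> Segment:
            if locus in forced:
                return (self._v if locus.endswith("V") else self._j)[forced[locus]]
            name = _weighted_choice(rng, w[locus])
            return (self._v if locus.endswith("V") else self._j)[name]

        bv, bj = pick("TRBV"), pick("TRBJ")
        beta = make_chain(rng, self.panel, bv, bj,
                          self._sample_len(rng, self.config.cdr3b_length_weights, bj))
        av, aj = pick("TRAV"), pick("TRAJ")
        alphas = [make_chain(rng, self.panel, av, aj,
                             self._sample_len(rng, self.config.cdr3a_length_weights, aj))]
        if rng.random() < self.config.dual_alpha_prob:
            av2, aj2 = pick("TRAV"), pick("TRAJ")
            second = make_chain(rng, self.panel, av2, aj2,
                                self._sample_len(rng, self.config.cdr3a_length_weights, aj2))
            if second.cdr3_aa != alphas[0].cdr3_aa:
                alphas.append(second)
        self._counter += 1
        return Clonotype(f"cl{self._counter:05d}", beta, tuple(alphas))


def _clone_sizes(rng: np.random.Generator, n_cells: int, target_fraction: float,
                 geom_p: float) -> list[int]:
    """Sizes (>= 2) of expanded clones covering ~target_fraction of cells."""
    n_expanded = int(round(target_fraction * n_cells))
    if n_expanded < 2:
        return []
    sizes: list[int] = []
    remaining = n_expanded
    while remaining >= 2:
        size = 2 + int(rng.geometric(geom_p)) - 1
        size = min(size, remaining)
        if remaining - size == 1:
            size += 1  # absorb a would-be orphan into this clone
        sizes.append(size)
        remaining -= size
    return sorted(sizes, reverse=True)


def simulate_repertoire(panel: ReferencePanel, config: SimulationConfig) -> list[TruthCell]:
    """Simulate the ground-truth cellular repertoire (no reads yet).

    Each subject owns a pool of candidate expanded clonotypes reused across
    conditions, so a clone can appear (and differ in size) in both the
    unstimulated and stimulated repertoires.  The first EC subject's top
    clonotype is pinned to TRAJ34/TRBV7-2/TRBJ2-2 usage, mimicking a
    noncanonical dominant clone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _ClonotypeFactory(panel, config)

    total_cells = sum(config.n_subjects.get(g, 0) for g in GROUPS) \
        * 2 * config.cells_per_subject_condition
    n_plates = config.n_plates
    if n_plates is None:
        n_plates = -(-total_cells // len(WELL_IDS))
    if total_cells > n_plates * len(WELL_IDS):
        raise ValueError(
            f"{total_cells} cells exceed {n_plates} plates x 96 wells")
    if n_plates > panel.n_plates:
        raise ValueError(
            f"need {n_plates} plate barcodes but panel has {panel.n_plates}")

    wells = ((f"P{p + 1:02d}", w) for p in range(n_plates) for w in WELL_IDS)
    cells: list[TruthCell] = []
    cell_no = 0
    for group in GROUPS:
        for si in range(config.n_subjects.get(group, 0)):
            subject = f"{group}{si + 1}"
            pool: list[Clonotype] = []
            if group == "EC" and si == 0:
                pool.append(factory.new(rng, group, forced_usage={
                    "TRAJ": "TRAJ34", "TRBV": "TRBV7-2", "TRBJ": "TRBJ2-2"}))
            for condition in CONDITIONS:
                n = config.cells_per_subject_condition
                target = config.expanded_fraction[group][condition]
                sizes = _clone_sizes(rng, n, target, config.clone_size_geom_p)
                while len(pool) < max(len(sizes), config.dominant_pool_size):
                    pool.append(factory.new(rng, group))
                plan: list[Clonotype] = []
                for ci, size in enumerate(sizes):
                    plan.extend([pool[ci]] * size)
                while len(plan) < n:
                    plan.append(factory.new(rng, group))  # singleton
                for ct in plan:
                    plate_id, well = next(wells)
                    cell_no += 1
                    state = {
                        gene: bool(rng.random() <
                                   config.phenotype_on_prob[gene][group][condition])
                        for gene in PHENOTYPE_GENES
                    }
                    cells.append(TruthCell(
                        cell_id=f"{plate_id}_{well}",
                        subject_id=subject, group=group, condition=condition,
                        plate_id=plate_id, well=well,
                        beta=ct.beta, alphas=ct.alphas,
                        phenotype_state=state, clone_id=f"{subject}_{ct.clone_id}",
                    ))
    assert cell_no == total_cells
    return cells


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(cells: list[TruthCell], panel: ReferencePanel,
                   config: SimulationConfig) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit barcoded amplicon reads plus a per-read truth table.

    Read layout (single-end): 5' well barcode + amplicon + 3' plate barcode,
    where the amplicon is either V+CDR3+J+constant-tag (chains) or a
    phenotype-gene tag.  Per-bucket read counts are log-normal with a floor;
    contamination re-barcodes a fraction of reads to a random other occupied
    well; substitution errors hit every base (barcodes included) at a flat
    rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # child stream: read stage
    occupied = [(c.plate_id, c.well) for c in cells]
    nt = np.array(list(NUCLEOTIDES))

    raw: list[tuple[str, str, str, str]] = []  # (plate, well, category, amplicon)
    for cell in cells:
        chain_items = [("beta", cell.beta)] + \
            [("alpha", a) for a in cell.alphas]
        for category, chain in chain_items:
            n_reads = max(config.min_reads_per_chain, int(round(
                rng.lognormal(np.log(config.reads_per_chain_median),
                              config.reads_per_chain_sigma))))
            amplicon = chain.amplicon + panel.constant_tags[chain_cat(category)]
            raw.extend((cell.plate_id, cell.well, category, amplicon)
                       for _ in range(n_reads))
        for gene, on in sorted(cell.phenotype_state.items()):
            if not on:
                continue
            n_reads = max(1, int(round(
                rng.lognormal(np.log(config.reads_per_phenotype_median),
                              config.reads_per_phenotype_sigma))))
            raw.extend((cell.plate_id, cell.well, f"phenotype:{gene}",
                        panel.phenotype_genes[gene]) for _ in range(n_reads))

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i, (plate, well, category, amplicon) in enumerate(raw):
        bc_plate, bc_well = plate, well
        contaminated = rng.random() < config.contamination_rate
        if contaminated and len(occupied) > 1:
            while True:
                j = int(rng.integers(0, len(occupied)))
                if occupied[j] != (plate, well):
                    bc_plate, bc_well = occupied[j]
                    break
        seq = panel.barcodes_5p[bc_well] + amplicon + panel.barcodes_3p[bc_plate]
        if config.error_rate > 0:
            k = rng.binomial(len(seq), config.error_rate)
            if k:
                pos = rng.choice(len(seq), size=k, replace=False)
                arr = np.array(list(seq))
                for p in pos:
                    choices = [b for b in NUCLEOTIDES if b != arr[p]]
                    arr[p] = choices[int(rng.integers(0, 3))]
                seq = "".join(arr)
        rid = f"read{i:07d}"
        reads.append((rid, seq))
        truth_rows.append((rid, plate, well, category, contaminated))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "plate_id", "well", "category",
                             "contaminated"])
    return reads, truth


def chain_cat(category: str) -> str:
    return "alpha" if category == "alpha" else "beta"


# ---------------------------------------------------------------------------
# Writers

def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def truth_cells_frame(cells: list[TruthCell]) -> pd.DataFrame:
    """Flatten TruthCells into the same tabular schema as called cells."""
    rows = []
    for c in cells:
        a1 = c.alphas[0]
        a2 = c.alphas[1] if len(c.alphas) > 1 else None
        row = {
            "cell_id": c.cell_id, "plate_id": c.plate_id, "well": c.well,
            "subject_id": c.subject_id, "group": c.group,
            "condition": c.condition, "clone_id": c.clone_id,
            "trbv": c.beta.v_gene, "trbj": c.beta.j_gene,
            "cdr3b_nt": c.beta.cdr3_nt, "cdr3b_aa": c.beta.cdr3_aa,
            "trav": a1.v_gene, "traj": a1.j_gene,
            "cdr3a_nt": a1.cdr3_nt, "cdr3a_aa": a1.cdr3_aa,
            "trav2": a2.v_gene if a2 else "", "traj2": a2.j_gene if a2 else "",
            "cdr3a2_aa": a2.cdr3_aa if a2 else "",
            "paired": True,
        }
        for gene in PHENOTYPE_GENES:
            row[gene] = int(c.phenotype_state[gene])
        rows.append(row)
    return pd.DataFrame(rows)


def sample_sheet(cells: list[TruthCell]) -> pd.DataFrame:
    """Plate/well -> subject/group/condition map (what a lab would provide)."""
    rows = [(c.plate_id, c.well, c.subject_id, c.group, c.condition)
            for c in cells]
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "subject_id", "group", "condition"])


def write_outputs(out_dir: str | Path, panel: ReferencePanel,
                  cells: list[TruthCell], reads: list[tuple[str, str]],
                  reads_truth: pd.DataFrame, config: SimulationConfig) -> None:
    from .reference import write_panel
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(panel, out / "panel")
    write_fastq(reads, out / "reads.fastq")
    truth_cells_frame(cells).to_csv(out / "cells_truth.tsv", sep="\t", index=False)
    reads_truth.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
    sample_sheet(cells).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    (out / "config.json").write_text(config.to_json())
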