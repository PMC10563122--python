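# maitseq

Single-cell **paired MAIT TCR repertoire analysis**: well demultiplexing of
barcoded amplicon reads, V/J + CDR3 calling under 50% dominance thresholds,
paired-clonotype expansion statistics, CDR3 diversity (length spectra,
per-position Shannon entropy, substitution-kernel repertoire similarity) and
phenotype-gene group comparisons — exercised end-to-end on a synthetic
plate-based experiment with known ground truth.

MAIT (mucosal-associated invariant T) cells carry a semi-invariant
TRAV1-2 alpha chain paired with a variable beta chain. In chronic HIV
infection their clonal structure and function are altered; analyses of this
kind sort single MAIT cells from healthy donors (HD), treated progressors
(PR) and elite controllers (EC) into 96-well plates, sequence barcoded
TCRalpha, TCRbeta and phenotype-gene amplicons per well, and compare clonal
expansion, CDR3 composition and gene expression across groups and
stimulation conditions. This package implements that full computational
chain as a reusable, tested library, plus a simulator that generates the
raw FASTQ inputs with complete ground truth so every stage is verifiable
without any data download.

## The core definitions

- **Dominance / normalized depth.** Within a well, reads are bucketed per
  amplicon (alpha, beta, or one phenotype gene). A chain is asserted iff its
  top CDR3 holds >= 50% of the bucket's extractable reads (ties break
  lexicographically); a phenotype gene is called iff its bucket passes the
  same 50% dominant-sequence rule and >= 10 supporting reads. A cell enters
  TCR analyses only with both an asserted beta and first alpha.
- **Dominant clone.** Within a subject, >= 2 cells sharing identical CDR3alpha
  and CDR3beta amino-acid sequences (per condition). Expansion is the
  percentage of paired-call cells belonging to dominant clones; top-clone
  percentages are round-half-up of 100·n/total over the group's
  dominant-clone member cells.
- **Entropy.** Per CDR3 position c (1 = conserved Cys),
  H(c) = −Σ_a p_a(c) log2 p_a(c) bits, from 0 (conserved) to log2 20 ≈ 4.32.
- **Similarity.** Normalized BLOSUM62 string kernel
  K(u,v) = k3(u,v)/√(k3(u,u)·k3(v,v)) with residue kernel
  K1(a,b) = (2^{S(a,b)/2})^β (β = 0.11387, substrings up to k_max = 3), so
  K(u,u) = 1 and 1 means 100% similarity.

## Worked example

The analysis drivers run the whole chain at desk scale (2 subjects/group,
60 cells per subject and condition) and write their tables under `results/`:

```bash
python analysis/01_simulate.py      # panel + repertoire + FASTQ + truth
python analysis/02_call_cells.py    # demultiplex, call chains/phenotypes
python analysis/03_clonality.py     # clones, expansion, top/shared clones, usage
python analysis/04_diversity.py     # lengths, PFMs, entropy, similarity
python analysis/05_phenotypes.py    # frequencies, two-way ANOVA, Tukey
```

With the default seed this prints, among other things:

```
simulated 720 cells (98 dual-alpha) across 8 plates
emitted 90921 reads (1837 contaminated)
assigned 90809/90921 reads; 720/720 wells paired
beta+first-alpha concordance with truth: 720/720 (100.0%)
HD unstimulated : 35.0% of paired cells in dominant clones
PR unstimulated : 51.7% of paired cells in dominant clones
EC unstimulated : 53.3% of paired cells in dominant clones
published percentage rule: 32/32 printed percentages reproduced
HD IFNG frequency: unstimulated 16.7% vs stimulated 54.8%
```

i.e. every well's beta and first alpha chain is recovered exactly despite
0.5% substitution errors and 2% cross-well contamination; the recovered
expansion fractions sit at the configured group targets; all 32 printed
percentages of the published dominant-clone table follow the integer
round-half-up rule; and the healthy-donor group shows the expected IFNG
response to stimulation.

Library use mirrors the drivers:

```python
import maitseq as m

panel = m.build_reference(seed=1)
cfg = m.SimulationConfig(seed=1)
cells = m.simulate_repertoire(panel, cfg)
reads, truth = m.simulate_reads(cells, panel, cfg)
called, stats = m.call_cells(reads, panel, m.sample_sheet(cells))
clones = m.define_clones(called)
m.expansion_fraction(called, clones, "EC", "unstimulated")  # ~55.0
```

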