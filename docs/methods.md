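# Methods

`maitseq` re-implements, as a tested pipeline over synthetic data with known
ground truth, a single-cell paired TCR analysis of MAIT (mucosal-associated
invariant T) cells: plate/well demultiplexing of barcoded amplicon reads,
chain and phenotype-gene calling under 50% read-support thresholds, paired
clonotype expansion statistics, CDR3 diversity measures, and group-level
phenotype comparisons. This note records the models, the parameters that
matter, and the design choices made where the procedure was genuinely open.

## The synthetic study

The simulator emulates a plate-based experiment: single cells sorted into
96-well plates, three donor groups (HD healthy donors, PR treated HIV
progressors, EC elite controllers; 4/4/3 subjects by default), two
stimulation conditions, and 140 cells per subject and condition. Every well
yields reads of the form

    5'-well-barcode + amplicon + 3'-plate-barcode

where the amplicon is either a chain fragment `V + CDR3-middle + J +
constant-tag` or a phenotype-gene tag. Key default parameters:

| parameter | default | meaning |
|---|---|---|
| expanded fraction | HD .35/.35, PR .51/.37, EC .55/.51 | target share of cells in clones of >= 2 cells, per group (unstim/stim) |
| clone sizes | 2 + (Geometric(p=0.45) − 1) | member cells per expanded clone |
| dual-alpha probability | 0.15 | clonotypes carrying a second alpha chain |
| reads per chain bucket | log-normal, median 40, sigma 0.6, floor 5 | per-well sequencing depth |
| reads per expressed phenotype gene | log-normal, median 25, sigma 0.5 | only genes in the "on" state emit reads |
| substitution error | 0.005 per base | flat, applied to the whole read including barcodes |
| cross-well contamination | 0.02 | a read's barcodes re-assigned to a random other occupied well |
| IFNG on-probability | HD .15→.65, PR/EC .10→.25 (unstim→stim) | the one gene with a group-dependent stimulation response |

Targets for the expanded fractions and the group-biased usage tables follow
the cohort the analysis was designed around (canonical TRAJ33/TRBV20-1/TRBV6
usage in HD; extra TRAJ34, TRBV7-2/TRBV29-1/TRBV30 and TRBJ2-2 weight in EC,
with the first EC subject's top clone pinned to TRAJ34/TRBV7-2/TRBJ2-2). The
read-depth distribution is invented: realized per-well depths for the real
experiment are not published, so the log-normal defaults are a plausible
shape, not a measured one.

Gene *segments* are synthetic: random DNA of roughly 60–120 nt with fixed
CDR3 anchors (the V's conserved cysteine as its last codon, the J's conserved
Phe/Trp codon one or two codons from its 5' end). Only the IMGT-style names
carry biological meaning. Consequences: V/J assignment faces none of the real
allelic near-identity of TRBV6 family members, and there are no indels, no
PCR chimeras, no quality-score structure. Passing tests therefore demonstrate
the correctness of the logic (thresholds, anchors, frames, barcode
correction, statistics), not robustness to every artifact of real MiSeq data.

Wells are assigned sequentially, one cell per (plate, well); the plate count
is derived from the cell count (error if a configured plate budget is
exceeded). One master seed drives everything; the read stage uses a child
stream at a fixed offset (seed + 1). Identical configurations give
byte-identical FASTQ and truth tables.

## Demultiplexing and calling

Barcodes within each set are pairwise Hamming distance >= 3, so one-mismatch
correction is unambiguous; reads are assigned iff both barcodes match
uniquely within the configured mismatch budget (0 or 1). Amplicons are
classified by their best tag match (chain constant tags at the 3' end,
phenotype tags spanning the amplicon; ties or matches worse than 4
mismatches are unclassified).

For a chain read, the V is scored by ungapped identity at the read's 5' end
and the J immediately upstream of the constant tag (best segment, minimum
identity 0.8); the CDR3 is the translated span from the V cysteine codon
through the J Phe/Trp codon inclusive. Reads with broken frames, internal
stops, or violations of the C...F/W convention are dropped to a QC counter.

Per-well calling uses a 50% rule throughout, with thresholds inclusive
(">= 50%"): the support criterion for any amplicon bucket is the fraction of
the bucket's reads carrying the dominant sequence. For chains this coincides
with CDR3 dominance: the beta chain (and first alpha) is asserted iff the top
CDR3 holds >= 50% of the bucket's extractable reads. Exact count ties break
lexicographically on the CDR3 nucleotide sequence, for reproducibility. A
second alpha is reported when a distinct CDR3 holds >= 25% of alpha reads
(the primary threshold applies only to the first alpha; the secondary value
is this package's choice). A phenotype gene is called expressed when its
bucket passes the same 50% dominant-sequence rule (guaranteed by
classification) and has >= 10 supporting reads — the absolute floor guards
against contamination. Cells lacking an asserted beta or first alpha are
excluded from all clonality and diversity analyses.

Before dominance is computed, CDR3 nucleotide variants of equal length
within 2 substitutions of a more-abundant variant are absorbed into it.
This is standard amplicon denoising: at a 0.5% per-base error rate, roughly
one read in five carries an error inside a ~40 nt CDR3, and without
collapsing, those singleton variants dilute the true clonotype's dominance
below 50% in dual-alpha wells. Genuinely distinct clonotypes are essentially
never within 2 nt of each other at equal length, and equal-count clusters
are never merged (preserving exact-tie semantics).

Note that in a dual-alpha cell the "first" alpha is an artifact of read
sampling: whichever alpha drew more reads dominates the well. Recovery is
therefore assessed on the beta chain plus the requirement that the called
first alpha be one of the cell's true alpha chains; the second alpha is
reported when it clears the 25% rule (a minority alpha below that share is
deliberately not reported).

## Clonality

Clones are defined within subject as cells sharing identical first-alpha and
beta CDR3 amino-acid sequences; a clone with >= 2 members in a subject x
condition is dominant in that condition (it may be singleton or absent in
the other). Expansion is reported as 100 x (cells in dominant clones) /
(paired-call cells) per group x condition, pooling cells across subjects
(per-subject averaging is available); an empty denominator is NaN, not 0.

Top-clone tables report each dominant clone's member count `n` against the
group x condition total of dominant-clone member cells, with integer
percentages computed by exact round-half-up (`floor(100 n / total + 1/2)` in
integer arithmetic) — the rule that reproduces all 32 published percentage
entries in the worked cohort table. Cross-group sharing is computed at
gene-usage granularity (TRAV/TRAJ/TRBV/TRBJ combinations of dominant clones
present in >= 1 subject of each group), matching the granularity of the
published shared-clone table; CDR3-level sharing is an option. Usage
matrices are row-normalized gene frequencies over dominant-clone cells, with
an average-linkage/Euclidean clustering order emitted for heatmap rendering
(the rendering itself is out of scope).

## CDR3 diversity

Positions are 1-based from the conserved cysteine, so the MAIT-activation
tyrosine falls at position 8 of a 12-mer CDR3alpha. Position frequency
matrices are empirical 20 x L frequencies with no pseudocounts, restricted
to a single length — by default the modal length of the set, since pooling
mixed lengths would misalign positions; entropy reporting covers the first
10 positions. Per-position Shannon entropy is computed in bits
(−Σ p log2 p, 0 log 0 := 0), ranging from 0 (conserved) to log2 20 ≈ 4.32.

Repertoire similarity uses the normalized substitution-kernel family of
Shen, Wong, Xiao, Guo and Smale (arXiv:1205.6031). The residue kernel is
K1(a,b) = Q(a,b)^beta, where Q = 2^(S/2) are the odds ratios recovered from
the integer BLOSUM62 log-odds scores S, correlation-normalized to unit
diagonal; beta defaults to 0.11387 (the values used by the original cohort
analysis are not recoverable, so beta and the substring cap are exposed as
parameters and logged). The string kernel sums, over all pairs of
equal-length contiguous substrings up to length k_max = 3, the product of
per-position residue similarities, then normalizes K(u,v) =
k3(u,v)/sqrt(k3(u,u) k3(v,v)), so K(u,u) = 1 exactly and 1 means 100%
similarity. Subject-level similarity is the mean kernel value over the
Cartesian product of two subjects' unique dominant-clone CDR3 sets
(self-pairs excluded within a subject; clone-size weighting available);
group summaries average subject pairs within (intra) or across (inter)
groups.

## Phenotype statistics

The observational unit is the donor: per donor x condition, the percentage
of dominant-clone cells with a positive call per gene (undefined, not zero,
when a donor has no dominant-clone cells). Each gene is tested with a
fixed-effects two-way ANOVA (group, condition, interaction) via OLS; Type II
sums of squares are the default because the 4/4/3-donor design is unbalanced
and Type II main effects do not depend on factor ordering (Type I by flag).
Pairwise contrasts among the six group x condition cells use Tukey HSD with
the Tukey–Kramer unequal-n correction. The degenerate all-equal case (0/0 F
ratios) is reported as F = 0, p = 1 ("no effect") rather than NaN. Presence/
absence calls only — per-gene transcript quantities are not modeled.

## Problem sizes

Tests and the acceptance script scale the simulations to run comfortably on
one CPU: the oracle-equivalence check uses 504 cells (2 subjects/group x 42
cells x 2 conditions), expansion-recovery uses 20 seeds of the full
4/4/3 x 140 design at the truth level (no reads), the read-level recovery
checks use 180–360 cells, and the ANOVA null calibration uses 1000
replicates. The analysis drivers use 2 subjects/group x 60 cells, ~90k
reads.

## Known limitations

- Synthetic segments make V/J assignment easier than with real IMGT alleles;
  identity thresholds would need re-tuning for real data.
- No indels anywhere (barcodes, amplicons), no UMI logic, no chimeras; the
  denoising step assumes substitution-only errors.
- "Normalized depth" is implemented as a per-bucket dominant-sequence
  fraction plus an absolute read floor for phenotype genes; the original
  pipeline's exact definition is not published, so this is a documented
  interpretation.
- Cohort-level results depending on the real subjects' repertoires (e.g.
  which clones are shared between groups) are only reproduced qualitatively
  on synthetic data; the worked numeric checks are the published
  dominant-clone table's counts, lengths and percentages.
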