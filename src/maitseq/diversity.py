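"""CDR3 diversity: length spectra, position frequencies, entropy, similarity.

Positions are 1-based from the conserved cysteine (position 1 = C), so the
MAIT-activation tyrosine sits at position 8 of a 12-mer CDR3alpha.
Per-position variability is Shannon entropy in bits over the 20 amino
acids, between 0 (conserved) and log2(20) ~ 4.32 (uniform).

Repertoire similarity uses the normalized substitution-matrix string
kernel of Shen, Wong, Xiao, Guo & Smale (arXiv:1205.6031): a residue
kernel built by raising BLOSUM62 odds ratios to a small power beta and
correlation-normalizing, lifted to sequences by summing products over all
pairs of equal-length contiguous substrings (lengths 1..k_max) and
normalizing so any sequence scores exactly 1 against itself.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DEFAULT_BETA = 0.11387
DEFAULT_KMAX = 3


# ---------------------------------------------------------------------------
# Lengths / position frequencies / entropy

def length_distribution(cdr3_set) -> pd.Series:
    """Counts of amino-acid lengths (terminal C and F/W included)."""
    lengths = pd.Series([len(s) for s in cdr3_set], dtype=int)
    if lengths.empty:
        return pd.Series(dtype=int)
    return lengths.value_counts().sort_index()


def modal_length(cdr3_set) -> int | None:
    dist = length_distribution(cdr3_set)
    if dist.empty:
        return None
    top = dist[dist == dist.max()]
    return int(top.index.min())


def position_frequency_matrix(cdr3_set, length: int | None = None,
                              ) -> pd.DataFrame | None:
    """Empirical 20 x L amino-acid frequency matrix (no pseudocounts).

    Restricted to sequences of one length (default: the modal length of the
    set).  Rows are amino acids, columns positions 1..L; each column sums
    to 1.  Returns None when no sequence has the requested length.
    """
    seqs = list(cdr3_set)
    if length is None:
        length = modal_length(seqs)
        if length is None:
            return None
    seqs = [s for s in seqs if len(s) == length]
    if not seqs:
        return None
    mat = np.zeros((len(AMINO_ACIDS), length))
    for s in seqs:
        for pos, a in enumerate(s):
            mat[_AA_INDEX[a], pos] += 1
    mat /= len(seqs)
    return pd.DataFrame(mat, index=list(AMINO_ACIDS),
                        columns=range(1, length + 1))


def shannon_entropy(pfm: pd.DataFrame) -> pd.Series:
    """Per-position Shannon entropy in bits (0 log 0 := 0)."""
    return pd.Series(
        {pos: float(_scipy_entropy(pfm[pos].values, base=2)) for pos in pfm.columns})


# ---------------------------------------------------------------------------
# Residue kernel

def blosum62_odds() -> pd.DataFrame:
    """BLOSUM62 substitution odds ratios 2^(S/2) over the 20 amino acids.

    S is the integer BLOSUM62 log-odds score (half-bit units), so the
    back-transformed values are the substitution-to-background probability
    ratios; all entries are strictly positive.
    """
    from Bio.Align import substitution_matrices
    S = substitution_matrices.load("BLOSUM62")
    mat = np.array([[2.0 ** (S[a, b] / 2.0) for b in AMINO_ACIDS]
                    for a in AMINO_ACIDS])
    return pd.DataFrame(mat, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


@lru_cache(maxsize=8)
def _k1_matrix(beta: float) -> np.ndarray:
    raw = blosum62_odds().values
    if np.any(raw <= 0):
        raise ValueError("substitution odds must be strictly positive")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    k = raw ** beta
    d = np.sqrt(np.diag(k))
    k = k / np.outer(d, d)
    np.fill_diagonal(k, 1.0)  # exact unit diagonal (correlation form)
    return k


def aa_kernel(a: str, b: str, beta: float = DEFAULT_BETA) -> float:
    """Normalized residue similarity in (0, 1]; 1 iff a == b."""
    k = _k1_matrix(beta)
    return float(k[_AA_INDEX[a], _AA_INDEX[b]])


# ---------------------------------------------------------------------------
# String kernel

def _k3(u: str, v: str, k1: np.ndarray, k_max: int) -> float:
    """Unnormalized kernel: sum over equal-length contiguous substring pairs
    (lengths 1..k_max) of the product of per-position residue similarities."""
    iu = np.array([_AA_INDEX[a] for a in u])
    iv = np.array([_AA_INDEX[a] for a in v])
    M = k1[np.ix_(iu, iv)]
    total = float(M.sum())
    P = M
    for length in range(2, min(k_max, len(u), len(v)) + 1):
        P = P[:-1, :-1] * M[length - 1:, length - 1:]
        total += float(P.sum())
    return total


def string_kernel(u: str, v: str, beta: float = DEFAULT_BETA,
                  k_max: int = DEFAULT_KMAX) -> float:
    """Normalized string-kernel similarity K(u, v) in [0, 1]; K(u, u) = 1."""
    if not u or not v:
        raise ValueError("sequences must be nonempty")
    for s in (u, v):
        bad = set(s) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {s}")
    k1 = _k1_matrix(beta)
    kuv = _k3(u, v, k1, k_max)
    kuu = _k3(u, u, k1, k_max)
    kvv = _k3(v, v, k1, k_max)
    return kuv / np.sqrt(kuu * kvv)


def gram_matrix(seqs, beta: float = DEFAULT_BETA,
                k_max: int = DEFAULT_KMAX) -> np.ndarray:
    seqs = list(seqs)
    k1 = _k1_matrix(beta)
    selfs = [_k3(s, s, k1, k_max) for s in seqs]
    n = len(seqs)
    G = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            G[i, j] = G[j, i] = _k3(seqs[i], seqs[j], k1, k_max) / \
                np.sqrt(selfs[i] * selfs[j])
    return G


# ---------------------------------------------------------------------------
# Repertoire similarity

def mean_similarity(repertoire_a, repertoire_b, same_subject: bool = False,
                    beta: float = DEFAULT_BETA, k_max: int = DEFAULT_KMAX,
                    ) -> float:
    """Mean kernel similarity over the Cartesian product of two CDR3 sets.

    For a subject compared against itself (``same_subject=True``) the
    diagonal self-pairs are excluded.  Returns NaN when either repertoire
    is empty (or, within-subject, has fewer than two sequences).
    """
    a, b = sorted(set(repertoire_a)), sorted(set(repertoire_b))
    if not a or not b:
        return float("nan")
    vals = []
    for i, u in enumerate(a):
        for j, v in enumerate(b):
            if same_subject and u == v:
                continue
            vals.append(string_kernel(u, v, beta, k_max))
    return float(np.mean(vals)) if vals else float("nan")


def subject_similarity_matrix(repertoires: dict[str, list[str]],
                              beta: float = DEFAULT_BETA,
                              k_max: int = DEFAULT_KMAX) -> pd.DataFrame:
    """Symmetric subject x subject matrix of mean kernel similarities.

    ``repertoires`` maps subject id -> CDR3 amino-acid sequences (dominant
    clones, unique).  The diagonal holds within-subject means (self-pairs
    excluded).
    """
    subjects = sorted(repertoires)
    n = len(subjects)
    M = np.full((n, n), np.nan)
    for i in range(n):
        M[i, i] = mean_similarity(repertoires[subjects[i]],
                                  repertoires[subjects[i]],
                                  same_subject=True, beta=beta, k_max=k_max)
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = mean_similarity(
                repertoires[subjects[i]], repertoires[subjects[j]],
                beta=beta, k_max=k_max)
    return pd.DataFrame(M, index=subjects, columns=subjects)


def group_similarity_summary(sim: pd.DataFrame,
                             groups: dict[str, str]) -> pd.DataFrame:
    """Intra- and inter-group means of subject-pair similarities.

    ``groups`` maps subject id -> group label.  Intra-group means average
    distinct subject pairs within a group (self-pairs excluded); inter-group
    means average all cross-group subject pairs.
    """
    labels = sorted(set(groups.values()))
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i:]:
            vals = []
            subj_a = [s for s in sim.index if groups[s] == ga]
            subj_b = [s for s in sim.index if groups[s] == gb]
            for a in subj_a:
                for b in subj_b:
                    if ga == gb and a >= b:
                        continue
                    vals.append(sim.loc[a, b])
            rows.append({
                "group_a": ga, "group_b": gb,
                "scope": "intra" if ga == gb else "inter",
                "n_pairs": len(vals),
                "mean_similarity": float(np.nanmean(vals)) if vals else float("nan"),
            })
    return pd.DataFrame(rows)


def dominant_repertoires(cells: pd.DataFrame, clones: pd.DataFrame,
                         chain: str, condition: str) -> dict[str, list[str]]:
    """Unique dominant-clone CDR3s per subject for one chain x condition."""
    col = {"alpha": "cdr3a_aa", "beta": "cdr3b_aa"}[chain]
    dom = clones[clones[f"dominant_{condition}"]]
    out: dict[str, list[str]] = {}
    for subject, grp in dom.groupby("subject_id"):
        out[subject] = sorted(set(grp[col]))
    return out
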