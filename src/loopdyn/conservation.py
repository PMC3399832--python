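"""Alignment-column conservation scoring and consensus patterns.

Three scoring families per column: Shannon entropy, mean pairwise
substitution-matrix score (BLOSUM62, BLOSUM45 or PET91-derived log-odds),
and the same matrix score under Henikoff position-based sequence weights.
Consensus patterns use the reduced alphabet of the E2 loop analyses:
x non-conserved, h hydrophobic, u tiny (A/G/S), n acidic (D/E), literal
residues and two-residue alternatives "(A,B)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AlignmentBlock

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: matrix registry; "pet91" resolves to the Jones–Taylor–Thornton 1992
#: mutation-data log-odds (the PET91 matrix) shipped with Biopython.
_MATRIX_NAMES = {
    "blosum62": "BLOSUM62",
    "blosum45": "BLOSUM45",
    "pet91": "JONES",
}


def _load_matrix(name: str):
    from Bio.Align import substitution_matrices

    key = name.lower()
    if key not in _MATRIX_NAMES:
        raise ValueError(
            f"unknown matrix {name!r}; available: {sorted(_MATRIX_NAMES)}"
        )
    return substitution_matrices.load(_MATRIX_NAMES[key])


@dataclass
class ColumnScore:
    column: int
    entropy: float                  # bits
    gap_fraction: float
    matrix_score: float | None      # normalized to [0, 1]
    weighted_score: float | None
    conservation: float             # mean of requested normalized scores


def shannon_entropy(column: list[str]) -> float:
    """Shannon entropy in bits over observed residues (gaps excluded)."""
    residues = [c for c in column if c in AMINO_ACIDS]
    if not residues:
        return 0.0
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def henikoff_weights(alignment: AlignmentBlock) -> np.ndarray:
    """Position-based sequence weights (normalized to sum 1).

    Each column contributes 1/(r·s) to every sequence holding residue a,
    where r is the number of distinct residues in the column and s the
    count of a. Duplicated sequences are down-weighted automatically.
    """
    n = alignment.n_sequences
    w = np.zeros(n)
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        obs = [c for c in col if c in AMINO_ACIDS]
        if not obs:
            continue
        kinds, counts = np.unique(obs, return_counts=True)
        r = len(kinds)
        count_of = dict(zip(kinds, counts))
        for i, c in enumerate(col):
            if c in count_of:
                w[i] += 1.0 / (r * count_of[c])
    if w.sum() == 0:
        return np.full(n, 1.0 / n)
    return w / w.sum()


def _normalized_similarity(matrix, a: str, b: str) -> float:
    """Karlin-normalized substitution score M(a,b)/√(M(a,a)M(b,b)), clipped
    to [0, 1] so that an invariant column scores exactly 1."""
    val = matrix[a, b] / math.sqrt(matrix[a, a] * matrix[b, b])
    return min(max(val, 0.0), 1.0)


def _pairwise_matrix_score(column: list[str], matrix) -> float | None:
    """Mean normalized similarity over unordered sequence pairs."""
    obs = [c for c in column if c in AMINO_ACIDS]
    if len(obs) < 2:
        return None
    total = 0.0
    n_pairs = 0
    for a in range(len(obs)):
        for b in range(a + 1, len(obs)):
            total += _normalized_similarity(matrix, obs[a], obs[b])
            n_pairs += 1
    return total / n_pairs


def _weighted_matrix_score(column: list[str], matrix,
                           weights: np.ndarray) -> float | None:
    """Similarity under Henikoff weights via weighted residue frequencies.

    Using frequencies (rather than weighted pair sums) makes the score of a
    duplicated alignment exactly equal to the original's.
    """
    idx = [i for i, c in enumerate(column) if c in AMINO_ACIDS]
    if not idx:
        return None
    w = weights[idx]
    if w.sum() == 0:
        return None
    w = w / w.sum()
    kinds = sorted({column[i] for i in idx})
    p = {a: float(w[[k for k, i in enumerate(idx) if column[i] == a]].sum())
         for a in kinds}
    return sum(
        p[a] * p[b] * _normalized_similarity(matrix, a, b)
        for a in kinds for b in kinds
    )


def score_columns(alignment: AlignmentBlock,
                  methods: tuple[str, ...] = ("entropy", "matrix", "weighted"),
                  matrix: str = "blosum62") -> list[ColumnScore]:
    """Score every column with the requested methods.

    The normalized entropy conservation is 1 − H/log2(20); matrix scores
    use the Karlin diagonal normalization M(a,b)/√(M(a,a)M(b,b)) clipped
    to [0, 1], so an invariant column scores exactly 1. ``conservation``
    averages the normalized scores of the requested methods.
    """
    for m in methods:
        if m not in ("entropy", "matrix", "weighted"):
            raise ValueError(f"unknown method {m!r}")
    M = _load_matrix(matrix) if ("matrix" in methods or "weighted" in methods) else None
    weights = henikoff_weights(alignment) if "weighted" in methods else None
    out = []
    max_h = math.log2(20)
    for j in range(alignment.n_columns):
        col = alignment.column(j)
        gap_frac = sum(c not in AMINO_ACIDS for c in col) / len(col)
        h = shannon_entropy(col)
        parts = []
        ms = ws = None
        if "entropy" in methods:
            parts.append(1.0 - h / max_h)
        if "matrix" in methods:
            ms = _pairwise_matrix_score(col, M)
            if ms is not None:
                parts.append(ms)
        if "weighted" in methods:
            ws = _weighted_matrix_score(col, M, weights)
            if ws is not None:
                parts.append(ws)
        out.append(ColumnScore(
            column=j, entropy=h, gap_fraction=gap_frac,
            matrix_score=ms, weighted_score=ws,
            conservation=float(np.mean(parts)) if parts else 0.0,
        ))
    return out


# ---------------------------------------------------------------------------
# Consensus patterns
# ---------------------------------------------------------------------------

@dataclass
class ConsensusAlphabet:
    """Reduced residue classes for consensus patterns.

    Classes are checked smallest-first (acidic, tiny, then the pair rule,
    then hydrophobic) so that a column conserved within a compact chemical
    class is named by the class rather than by an arbitrary residue pair.
    """

    hydrophobic: frozenset = frozenset("AVLIMFWCY")
    tiny: frozenset = frozenset("AGS")
    acidic: frozenset = frozenset("DE")


def _column_symbol(column: list[str], threshold: float,
                   alphabet: ConsensusAlphabet) -> str:
    n_all = len(column)
    obs = [c for c in column if c in AMINO_ACIDS]
    if len(obs) < n_all / 2:
        return "-"
    kinds, counts = np.unique(obs, return_counts=True)
    freq = dict(zip(kinds, counts / len(obs)))
    order = sorted(freq, key=lambda a: (-freq[a], a))
    if freq[order[0]] >= threshold:
        return order[0]
    for members, symbol in ((alphabet.acidic, "n"), (alphabet.tiny, "u")):
        if sum(freq.get(a, 0.0) for a in members) >= threshold:
            return symbol
    if len(order) >= 2 and freq[order[0]] + freq[order[1]] >= threshold:
        return f"({order[0]},{order[1]})"
    if sum(freq.get(a, 0.0) for a in alphabet.hydrophobic) >= threshold:
        return "h"
    return "x"


def consensus_pattern(alignment: AlignmentBlock, threshold: float = 0.70,
                      alphabet: ConsensusAlphabet | None = None) -> str:
    """Consensus pattern string, one symbol (or "(A,B)") per column."""
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    alphabet = alphabet or ConsensusAlphabet()
    return "".join(
        _column_symbol(alignment.column(j), threshold, alphabet)
        for j in range(alignment.n_columns)
    )


#: specificity follows the evaluation order: a higher threshold can only
#: move a column's symbol to a later (less specific) rule, never earlier.
SYMBOL_SPECIFICITY = {"literal": 4, "n": 3, "u": 3, "pair": 2, "h": 1, "x": 0, "-": 0}


def symbol_specificity(symbol: str) -> int:
    """Rank of a consensus symbol; raising the threshold never raises it."""
    if symbol.startswith("("):
        return SYMBOL_SPECIFICITY["pair"]
    if symbol in ("n", "u", "h", "x", "-"):
        return SYMBOL_SPECIFICITY[symbol]
    return SYMBOL_SPECIFICITY["literal"]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fractional identity over aligned, non-gap columns."""
    pairs = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
             if a in AMINO_ACIDS and b in AMINO_ACIDS]
    if not pairs:
        return 0.0
    return sum(a == b for a, b in pairs) / len(pairs)
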