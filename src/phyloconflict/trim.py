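"""Removal of gap-rich and poorly conserved alignment columns.

A block-mapping-style filter inspired by the BMGE family of trimmers: each
column gets a gap fraction ``g`` and a conservation score ``c`` (the mean
min-max-normalized similarity-matrix score over ungapped residue pairs),
``c`` is smoothed with a centred moving average, and a column is kept iff
``g <= gap_max`` and smoothed ``c >= score_min``.  This is a self-contained
formalization, not a bit-compatible reimplementation of any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import AMINO_ACIDS, GAP, UNKNOWN, Alignment

# The NCBI BLOSUM30 table (not shipped with Biopython), row/column order
# ARNDCQEGHILKMFPSTWYV.
_BLOSUM30_TEXT = """\
A  4 -1  0  0 -3  1  0  0 -2  0 -1  0  1 -2 -1  1  1 -5 -4  1
R -1  8 -2 -1 -2  3 -1 -2 -1 -3 -2  1  0 -1 -1 -1 -3  0  0 -1
N  0 -2  8  1 -1 -1 -1  0 -1  0 -2  0  0 -1 -3  0  1 -7 -4 -2
D  0 -1  1  9 -3 -1  1 -1 -2 -4 -1  0 -3 -5 -1  0 -1 -4 -1 -2
C -3 -2 -1 -3 17 -2  1 -4 -5 -2  0 -3 -2 -3 -3 -2 -2 -2 -6 -2
Q  1  3 -1 -1 -2  8  2 -2  0 -2 -2  0 -1 -3  0 -1  0 -1 -1 -3
E  0 -1 -1  1  1  2  6 -2  0 -3 -1  2 -1 -4  1  0 -2 -1 -2 -3
G  0 -2  0 -1 -4 -2 -2  8 -3 -1 -2 -1 -2 -3 -1  0 -2  1 -3 -3
H -2 -1 -1 -2 -5  0  0 -3 14 -2 -1 -2  2 -3  1 -1 -2 -5  0 -3
I  0 -3  0 -4 -2 -2 -3 -1 -2  6  2 -2  1  0 -3 -1  0 -3 -1  4
L -1 -2 -2 -1  0 -2 -1 -2 -1  2  4 -2  2  2 -3 -2  0 -2  3  1
K  0  1  0  0 -3  0  2 -1 -2 -2 -2  4  2 -1  1  0 -1 -2 -1 -2
M  1  0  0 -3 -2 -1 -1 -2  2  1  2  2  6 -2 -4 -2  0 -3 -1  0
F -2 -1 -1 -5 -3 -3 -4 -3 -3  0  2 -1 -2 10 -4 -1 -2  1  3  1
P -1 -1 -3 -1 -3  0  1 -1  1 -3 -3  1 -4 -4 11 -1  0 -3 -2 -4
S  1 -1  0  0 -2 -1  0  0 -1 -1 -2  0 -2 -1 -1  4  2 -3 -2 -1
T  1 -3  1 -1 -2  0 -2 -2 -2  0  0 -1  0 -2  0  2  5 -5 -1  1
W -5  0 -7 -4 -2 -1 -1  1 -5 -3 -2 -2 -3  1 -3 -3 -5 20  5 -3
Y -4  0 -4 -1 -6 -1 -2 -3  0 -1  3 -1 -1  3 -2 -2 -1  5  9  1
V  1 -1 -2 -2 -2 -3 -3 -3 -3  4  1 -2  0  1 -4 -1  1 -3  1  5
"""


@dataclass(frozen=True)
class SimilarityMatrix:
    """A symmetric 20x20 integer residue-similarity matrix."""

    name: str
    scores: dict  # (aa1, aa2) -> int, both orders present

    def __post_init__(self):
        for a, b in combinations(AMINO_ACIDS, 2):
            if self.scores[(a, b)] != self.scores[(b, a)]:
                raise ValueError(f"{self.name}: asymmetric at ({a},{b})")
        for a in AMINO_ACIDS:
            if self.scores[(a, a)] <= 0:
                raise ValueError(f"{self.name}: non-positive diagonal at {a}")

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    @property
    def min_score(self) -> int:
        return min(self.scores.values())

    @property
    def max_score(self) -> int:
        return max(self.scores.values())


def _matrix_from_rows(name: str, order: str, rows) -> SimilarityMatrix:
    scores = {}
    for a, row in zip(order, rows):
        for b, v in zip(order, row):
            scores[(a, b)] = int(v)
    return SimilarityMatrix(name, scores)


def load_similarity_matrix(name: str) -> SimilarityMatrix:
    """Load BLOSUM30 (embedded) or any matrix Biopython ships (e.g. BLOSUM62)."""
    name = name.upper()
    if name == "BLOSUM30":
        order, rows = "", []
        for line in _BLOSUM30_TEXT.strip().splitlines():
            parts = line.split()
            order += parts[0]
            rows.append([int(x) for x in parts[1:]])
        return _matrix_from_rows("BLOSUM30", order, rows)
    arr = substitution_matrices.load(name)
    scores = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            scores[(a, b)] = int(arr[a, b])
    return SimilarityMatrix(name, scores)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of a column-trimming pass."""

    kept_columns: tuple[int, ...]
    trimmed: Alignment
    gap_fractions: tuple[float, ...]
    conservation: tuple[float, ...]         # smoothed scores actually used
    parameters: dict


def column_statistics(aln: Alignment, matrix: SimilarityMatrix):
    """Per-column gap fraction and raw (unsmoothed) conservation score.

    Conservation is the mean of ``(score(a,b) - min) / (max - min)`` over all
    unordered residue pairs in the column; pairs involving ``-`` or ``X`` are
    excluded, and a column with no scorable pair scores 0.
    """
    lo, hi = matrix.min_score, matrix.max_score
    span = hi - lo
    n = aln.n_taxa
    gaps = np.empty(aln.n_columns)
    cons = np.empty(aln.n_columns)
    for j in range(aln.n_columns):
        col = aln.column(j)
        gaps[j] = col.count(GAP) / n
        residues = [ch for ch in col if ch != GAP and ch != UNKNOWN]
        if len(residues) < 2:
            cons[j] = 0.0
            continue
        total = 0.0
        k = 0
        counts = {}
        for ch in residues:
            counts[ch] = counts.get(ch, 0) + 1
        items = list(counts.items())
        for i, (a, ca) in enumerate(items):
            total += (matrix.score(a, a) - lo) / span * (ca * (ca - 1) // 2)
            k += ca * (ca - 1) // 2
            for b, cb in items[i + 1:]:
                total += (matrix.score(a, b) - lo) / span * (ca * cb)
                k += ca * cb
        cons[j] = total / k
    return gaps, cons


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window is truncated at the edges."""
    if window == 1:
        return values.copy()
    half = window // 2
    out = np.empty_like(values)
    for j in range(len(values)):
        lo = max(0, j - half)
        hi = min(len(values), j + half + 1)
        out[j] = values[lo:hi].mean()
    return out


def trim_columns(
    aln: Alignment,
    matrix: SimilarityMatrix | str = "BLOSUM30",
    gap_max: float = 0.2,
    score_min: float = 0.3,
    smooth_window: int = 3,
) -> TrimResult:
    """Keep columns passing both the gap rule and the smoothed-score rule."""
    if aln.n_columns == 0 or aln.n_taxa == 0:
        raise ValueError("cannot trim an empty alignment")
    if not (0 <= gap_max <= 1 and 0 <= score_min <= 1):
        raise ValueError("gap_max and score_min must lie in [0, 1]")
    if smooth_window % 2 != 1 or smooth_window < 1:
        raise ValueError("smooth_window must be odd and positive")
    if isinstance(matrix, str):
        matrix = load_similarity_matrix(matrix)
    gaps, cons = column_statistics(aln, matrix)
    smoothed = _smooth(cons, smooth_window)
    kept = tuple(
        j for j in range(aln.n_columns)
        if gaps[j] <= gap_max and smoothed[j] >= score_min
    )
    return TrimResult(
        kept_columns=kept,
        trimmed=aln.select_columns(kept),
        gap_fractions=tuple(gaps),
        conservation=tuple(smoothed),
        parameters={
            "matrix": matrix.name,
            "gap_max": gap_max,
            "score_min": score_min,
            "smooth_window": smooth_window,
        },
    )
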