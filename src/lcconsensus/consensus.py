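"""Consensus matrices and their comparison.

A consensus matrix tabulates, for one germline gene and one cohort, the
count and fraction of sequences carrying each of the 21 symbols (20
amino acids + gap) at each of the 127 IMGT positions.  Matrices are
compared by subtraction (difference matrices), position-wise Pearson
correlation, per-position Gini inequality, Frobenius/Euclidean distance,
and hierarchical clustering of those distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .scaffold import ALPHABET, N_POSITIONS, N_SYMBOLS, SequenceSet

__all__ = [
    "ConsensusMatrix",
    "DifferenceMatrix",
    "Dendrogram",
    "LogoData",
    "build_consensus",
    "difference_matrix",
    "position_gini",
    "gini",
    "position_correlation",
    "residue_correlation",
    "matrix_distance",
    "cluster_matrices",
    "logo_data",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class ConsensusMatrix:
    """Per-gene, per-cohort 127 x 21 residue counts and fractions."""

    gene: str
    cohort: str
    n_sequences: int
    counts: np.ndarray  # (127, 21) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (N_POSITIONS, N_SYMBOLS):
            raise ValueError("counts must be (127, 21)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        rowsums = counts.sum(axis=1)
        if not (rowsums == self.n_sequences).all():
            bad = int(np.flatnonzero(rowsums != self.n_sequences)[0]) + 1
            raise ValueError(
                f"counts at position {bad} sum to {rowsums[bad - 1]}, "
                f"expected n_sequences={self.n_sequences}"
            )

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_sequences

    @property
    def label(self) -> str:
        return f"{self.gene}/{self.cohort}"

    def fraction(self, position: int, residue: str) -> float:
        """Fraction of sequences with ``residue`` at IMGT ``position``."""
        return float(
            self.counts[position - 1, ALPHABET.index(residue)] / self.n_sequences
        )


@dataclass(frozen=True)
class DifferenceMatrix:
    """Element-wise difference of two consensus matrices (a - b)."""

    gene: str
    cohort_a: str
    cohort_b: str
    values: np.ndarray  # (127, 21), rows sum to 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (N_POSITIONS, N_SYMBOLS):
            raise ValueError("values must be (127, 21)")
        if np.abs(values.sum(axis=1)).max() > 1e-6:
            raise ValueError("difference rows must sum to 0")
        if np.abs(values).max() > 1 + _ATOL:
            raise ValueError("difference entries must lie in [-1, 1]")


def build_consensus(seq_set: SequenceSet) -> ConsensusMatrix:
    """Tabulate residue counts/fractions over a set of aligned sequences.

    Gaps are counted like any residue, so every position's counts sum to
    the number of sequences.
    """
    if seq_set.n < 1:
        raise ValueError("cannot build a consensus matrix from an empty set")
    counts = np.zeros((N_POSITIONS, N_SYMBOLS), dtype=np.int64)
    # one bincount per position over the uint8 code matrix
    for pos in range(N_POSITIONS):
        counts[pos] = np.bincount(seq_set.matrix[:, pos], minlength=N_SYMBOLS)
    return ConsensusMatrix(
        gene=seq_set.gene, cohort=seq_set.cohort, n_sequences=seq_set.n, counts=counts
    )


def difference_matrix(a: ConsensusMatrix, b: ConsensusMatrix) -> DifferenceMatrix:
    """Subtract b's fractions from a's, position by position."""
    if a.gene != b.gene:
        raise ValueError(f"gene mismatch: {a.gene} vs {b.gene}")
    return DifferenceMatrix(
        gene=a.gene,
        cohort_a=a.cohort,
        cohort_b=b.cohort,
        values=a.fractions - b.fractions,
    )


def gini(x: np.ndarray, corrected: bool = True) -> float:
    """Gini inequality coefficient of a non-negative vector.

    With the small-sample correction n/(n-1) (the default), a point mass
    scores exactly 1 and a uniform vector exactly 0, matching the usual
    interpretation for residue distributions over a fixed alphabet.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    total = x.sum()
    if total <= 0:
        return 0.0
    xs = np.sort(x)
    # mean absolute difference via the sorted-rank identity
    ranks = np.arange(1, n + 1)
    g = float((2 * ranks - n - 1) @ xs) / (n * total)
    if corrected and n > 1:
        g *= n / (n - 1)
    return g


def position_gini(
    matrix: ConsensusMatrix, position: int, corrected: bool = True
) -> float:
    """Gini coefficient of the 21-symbol fraction vector at one position.

    0 means all 21 symbols equally frequent; 1 (with the correction)
    means a single symbol carried by every sequence.
    """
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position {position} outside scaffold")
    return gini(matrix.fractions[position - 1], corrected=corrected)


def position_correlation(a: ConsensusMatrix, b: ConsensusMatrix) -> np.ndarray:
    """Per-position Pearson correlation of residue distributions.

    Returns a length-127 float array; positions where either cohort's
    21-entry fraction vector has zero variance (all symbols equally
    frequent) are NaN, flagging the correlation as undefined.
    """
    if a.gene != b.gene:
        raise ValueError(f"gene mismatch: {a.gene} vs {b.gene}")
    fa, fb = a.fractions, b.fractions
    ca = fa - fa.mean(axis=1, keepdims=True)
    cb = fb - fb.mean(axis=1, keepdims=True)
    va = (ca**2).sum(axis=1)
    vb = (cb**2).sum(axis=1)
    out = np.full(N_POSITIONS, np.nan)
    # variances below rounding noise count as zero (undefined rho)
    ok = (va > _VAR_TOL) & (vb > _VAR_TOL)
    out[ok] = (ca[ok] * cb[ok]).sum(axis=1) / np.sqrt(va[ok] * vb[ok])
    return out


_VAR_TOL = 1e-20


def residue_correlation(a: ConsensusMatrix, b: ConsensusMatrix) -> np.ndarray:
    """Secondary mode: Pearson correlation per residue column (length 21)
    between the two matrices' 127-position fraction profiles."""
    if a.gene != b.gene:
        raise ValueError(f"gene mismatch: {a.gene} vs {b.gene}")
    fa, fb = a.fractions.T, b.fractions.T  # (21, 127)
    ca = fa - fa.mean(axis=1, keepdims=True)
    cb = fb - fb.mean(axis=1, keepdims=True)
    va = (ca**2).sum(axis=1)
    vb = (cb**2).sum(axis=1)
    out = np.full(N_SYMBOLS, np.nan)
    ok = (va > _VAR_TOL) & (vb > _VAR_TOL)
    out[ok] = (ca[ok] * cb[ok]).sum(axis=1) / np.sqrt(va[ok] * vb[ok])
    return out


def matrix_distance(
    a: ConsensusMatrix, b: ConsensusMatrix, on: str = "fractions"
) -> float:
    """Euclidean (Frobenius) distance between two consensus matrices.

    The square root of the sum of squared entry-wise differences over
    all 127 x 21 cells; equals the total magnitude of the corresponding
    difference matrix.  Genes may differ (cross-gene comparison).
    """
    if on == "fractions":
        diff = a.fractions - b.fractions
    elif on == "counts":
        diff = a.counts - b.counts
    else:
        raise ValueError("on must be 'fractions' or 'counts'")
    return float(np.sqrt((diff**2).sum()))


@dataclass
class Dendrogram:
    """Agglomerative clustering of consensus matrices by pairwise distance."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id].replace(" ", "_")
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({render(left)}:{ld:g},{render(right)}:{rd:g})"

        return render(tree) + ";"


def cluster_matrices(
    matrices: list[ConsensusMatrix], method: str = "complete"
) -> Dendrogram:
    """Hierarchically cluster consensus matrices on Euclidean distances.

    Complete linkage by default; 'average' and 'single' are accepted.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to cluster")
    if method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage method {method!r}")
    n = len(matrices)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = matrix_distance(matrices[i], matrices[j])
    linkage = sch.linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(
        labels=[m.label for m in matrices], linkage=linkage, method=method
    )


@dataclass(frozen=True)
class LogoData:
    """Letter heights for a modified sequence logo.

    The most frequent symbol at each position is removed so that the
    logo highlights non-germline residues; remaining letter heights are
    raw fractions (not information content).  Ties for "most frequent"
    are broken toward the lowest alphabet index.
    """

    gene: str
    cohort: str
    heights: tuple[dict[str, float], ...] = field(repr=False)  # len 127

    def at(self, position: int) -> dict[str, float]:
        return dict(self.heights[position - 1])


def logo_data(matrix: ConsensusMatrix) -> LogoData:
    """Per-position letter heights with the top residue excluded."""
    fractions = matrix.fractions
    top = fractions.argmax(axis=1)  # argmax takes the lowest index on ties
    heights = []
    for pos in range(N_POSITIONS):
        row = {
            ALPHABET[s]: float(fractions[pos, s])
            for s in range(N_SYMBOLS)
            if s != top[pos] and fractions[pos, s] > 0
        }
        heights.append(row)
    return LogoData(gene=matrix.gene, cohort=matrix.cohort, heights=tuple(heights))
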