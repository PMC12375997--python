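"""Core domain types for IMGT-numbered light-chain variable domains.

The IMGT unique numbering scheme assigns every light-chain V-domain
residue to one of 127 fixed positions; positions that a given sequence
does not use (e.g. 58-64 in most human light chains, or the CDR3
insertion slots 110-113) are held by a gap character.  All analysis in
this package operates on this fixed 127-column scaffold, with the gap
treated as a first-class 21st symbol alongside the 20 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "ALPHABET",
    "N_POSITIONS",
    "N_SYMBOLS",
    "ResidueAlphabet",
    "ImgtScaffold",
    "DEFAULT_REGION_BOUNDS",
    "GermlineAllele",
    "GermlineRegistry",
    "AlignedLightChain",
    "SequenceSet",
    "RejectionRecord",
    "region_of",
    "validate_sequence",
    "residue_differences",
    "normalize_gene_name",
]

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: Gap character used on the scaffold ("." is accepted on input as a synonym).
GAP: str = "-"
#: Fixed 21-symbol ordering: amino acids alphabetically, gap last.
ALPHABET: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP,)

N_POSITIONS: int = 127
N_SYMBOLS: int = 21

_SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}
GAP_INDEX: int = _SYMBOL_INDEX[GAP]


@dataclass(frozen=True)
class ResidueAlphabet:
    """Ordered residue alphabet: 20 amino acids plus the gap symbol."""

    symbols: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        if len(self.symbols) != N_SYMBOLS or len(set(self.symbols)) != N_SYMBOLS:
            raise ValueError("alphabet must contain exactly 21 unique symbols")

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)


DEFAULT_ALPHABET = ResidueAlphabet()

#: IMGT unique-numbering framework/CDR boundaries for V domains
#: (inclusive position ranges).  Overridable via ImgtScaffold.
DEFAULT_REGION_BOUNDS: tuple[tuple[str, int, int], ...] = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 127),
)


@dataclass(frozen=True)
class ImgtScaffold:
    """The fixed 127-position scaffold with FR/CDR region annotations.

    ``region_bounds`` must partition 1..127 into seven contiguous blocks;
    the defaults follow the IMGT unique-numbering convention but may be
    overridden, e.g. to test sensitivity to boundary placement.
    """

    region_bounds: tuple[tuple[str, int, int], ...] = DEFAULT_REGION_BOUNDS

    def __post_init__(self) -> None:
        expected_start = 1
        for name, start, stop in self.region_bounds:
            if start != expected_start or stop < start:
                raise ValueError(
                    f"region bounds must be contiguous from 1; bad block {name}"
                )
            expected_start = stop + 1
        if expected_start != N_POSITIONS + 1:
            raise ValueError("region bounds must cover positions 1..127")

    @property
    def positions(self) -> range:
        return range(1, N_POSITIONS + 1)

    @property
    def region_map(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for name, start, stop in self.region_bounds:
            for pos in range(start, stop + 1):
                out[pos] = name
        return out

    def region_of(self, position: int) -> str:
        if not 1 <= position <= N_POSITIONS:
            raise ValueError(f"position {position} outside scaffold 1..{N_POSITIONS}")
        for name, start, stop in self.region_bounds:
            if start <= position <= stop:
                return name
        raise AssertionError("unreachable: bounds partition 1..127")


DEFAULT_SCAFFOLD = ImgtScaffold()


def region_of(position: int, scaffold: ImgtScaffold = DEFAULT_SCAFFOLD) -> str:
    """Return the FR/CDR region label of an IMGT position."""
    return scaffold.region_of(position)


def _encode(residues: Sequence[str]) -> np.ndarray:
    """Encode a 127-symbol vector to uint8 alphabet indices. Raises on
    unknown symbols or wrong length."""
    if len(residues) != N_POSITIONS:
        raise ValueError(f"expected {N_POSITIONS} residues, got {len(residues)}")
    try:
        return np.fromiter(
            (_SYMBOL_INDEX[r] for r in residues), dtype=np.uint8, count=N_POSITIONS
        )
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet") from exc


def _decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


# Paralogous IGKV genes from the distal locus are counted under the
# proximal-locus name (IGKV1D-33 -> IGKV1-33, etc.).
def normalize_gene_name(gene: str) -> str:
    head, sep, tail = gene.partition("-")
    if sep and head.startswith("IGKV") and head.endswith("D"):
        return head[:-1] + sep + tail
    return gene


@dataclass(frozen=True)
class GermlineAllele:
    """A germline V-gene allele on the 127-position scaffold."""

    gene: str
    allele_id: str  # e.g. "*01"
    residues: str   # 127 alphabet symbols; gap allowed

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene_name(self.gene))
        _encode(self.residues)  # validates length and symbols

    @property
    def codes(self) -> np.ndarray:
        return _encode(self.residues)

    @property
    def name(self) -> str:
        return f"{self.gene}{self.allele_id}"

    def residue_at(self, position: int) -> str:
        if not 1 <= position <= N_POSITIONS:
            raise ValueError(f"position {position} outside scaffold")
        return self.residues[position - 1]


@dataclass
class GermlineRegistry:
    """Mapping gene -> available alleles, with a reference-allele policy.

    The reference allele (default ``*01``) is the one used for residue-
    change calls and pattern eligibility; allele-aware operations may
    use any registered allele.
    """

    entries: dict[str, list[GermlineAllele]] = field(default_factory=dict)
    reference_allele_policy: str = "*01"

    def add(self, allele: GermlineAllele) -> None:
        self.entries.setdefault(allele.gene, []).append(allele)

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def alleles(self, gene: str) -> list[GermlineAllele]:
        gene = normalize_gene_name(gene)
        if gene not in self.entries:
            raise KeyError(f"gene {gene} not in registry")
        return list(self.entries[gene])

    def reference(self, gene: str) -> GermlineAllele:
        for allele in self.alleles(gene):
            if allele.allele_id == self.reference_allele_policy:
                return allele
        raise KeyError(
            f"no {self.reference_allele_policy} allele registered for {gene}"
        )

    def get(self, gene: str, allele_id: str) -> GermlineAllele:
        for allele in self.alleles(gene):
            if allele.allele_id == allele_id:
                return allele
        raise KeyError(f"{gene}{allele_id} not in registry")


@dataclass(frozen=True)
class AlignedLightChain:
    """One IMGT-aligned V-L sequence with gene/allele/cohort labels."""

    id: str
    gene: str
    cohort: str
    residues: str
    allele: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene_name(self.gene))
        _encode(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return _encode(self.residues)

    def residue_at(self, position: int) -> str:
        if not 1 <= position <= N_POSITIONS:
            raise ValueError(f"position {position} outside scaffold")
        return self.residues[position - 1]


@dataclass(frozen=True)
class RejectionRecord:
    """Why an input record was excluded from analysis (data, not an error)."""

    id: str
    reason: str


class SequenceSet:
    """All light chains from one germline gene and one cohort.

    Internally backed by an ``(n, 127)`` uint8 matrix of alphabet indices
    so that consensus building and carrier counting are vectorised;
    ``AlignedLightChain`` views are materialised on demand.
    """

    def __init__(
        self,
        gene: str,
        cohort: str,
        matrix: np.ndarray,
        ids: Sequence[str],
        alleles: Sequence[str | None] | None = None,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[1] != N_POSITIONS:
            raise ValueError("matrix must be (n, 127)")
        if matrix.size and matrix.max() >= N_SYMBOLS:
            raise ValueError("matrix contains codes outside the 21-symbol alphabet")
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids length must match matrix rows")
        self.gene = normalize_gene_name(gene)
        self.cohort = cohort
        self.matrix = matrix
        self.ids = list(ids)
        self.alleles = list(alleles) if alleles is not None else [None] * len(ids)
        if len(self.alleles) != len(self.ids):
            raise ValueError("alleles length must match ids")

    @classmethod
    def from_chains(
        cls, gene: str, cohort: str, chains: Iterable[AlignedLightChain]
    ) -> "SequenceSet":
        chains = list(chains)
        gene = normalize_gene_name(gene)
        for chain in chains:
            if chain.gene != gene:
                raise ValueError(
                    f"chain {chain.id} has gene {chain.gene}, set requires {gene}"
                )
        matrix = (
            np.vstack([c.codes for c in chains])
            if chains
            else np.empty((0, N_POSITIONS), dtype=np.uint8)
        )
        return cls(
            gene,
            cohort,
            matrix,
            [c.id for c in chains],
            [c.allele for c in chains],
        )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[AlignedLightChain]:
        for i in range(self.n):
            yield self[i]

    def __getitem__(self, i: int) -> AlignedLightChain:
        return AlignedLightChain(
            id=self.ids[i],
            gene=self.gene,
            cohort=self.cohort,
            residues=_decode(self.matrix[i]),
            allele=self.alleles[i],
        )

    def subset(self, indices: Sequence[int], cohort: str | None = None) -> "SequenceSet":
        idx = list(indices)
        return SequenceSet(
            self.gene,
            cohort or self.cohort,
            self.matrix[idx],
            [self.ids[i] for i in idx],
            [self.alleles[i] for i in idx],
        )


_AMBIGUITY_CODES = set("BJOUXZ*")


def validate_sequence(
    id: str,
    residues: Sequence[str],
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    gene: str = "",
    cohort: str = "custom",
    allele: str | None = None,
) -> AlignedLightChain | RejectionRecord:
    """Validate a raw 127-symbol vector into an AlignedLightChain.

    Rejections (wrong scaffold length, ambiguity codes, any symbol
    outside the 21-symbol alphabet) are returned as data, not raised.
    "." is normalised to the gap symbol before validation.
    """
    seq = "".join(residues).upper().replace(".", GAP)
    if len(seq) != N_POSITIONS:
        return RejectionRecord(id, "wrong scaffold length")
    bad = [r for r in seq if r not in alphabet]
    if bad:
        if any(b in _AMBIGUITY_CODES for b in bad):
            return RejectionRecord(id, "ambiguous residue")
        return RejectionRecord(id, f"invalid symbol {bad[0]!r}")
    return AlignedLightChain(id=id, gene=gene, cohort=cohort, residues=seq, allele=allele)


def residue_differences(
    seq: AlignedLightChain, germline: GermlineAllele
) -> list[tuple[int, str, str]]:
    """All positions where a sequence differs from its germline.

    Differences involving the gap count too: residue observed where the
    germline has a gap is an insertion-type difference, gap observed
    where the germline has a residue is a deletion-type one.  The term
    "residue change" is used rather than "mutation" because only protein
    sequences are compared.
    """
    if seq.gene != germline.gene:
        raise ValueError(
            f"gene mismatch: sequence {seq.gene} vs germline {germline.gene}"
        )
    return [
        (pos, g, o)
        for pos, (g, o) in enumerate(zip(germline.residues, seq.residues), start=1)
        if g != o
    ]
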