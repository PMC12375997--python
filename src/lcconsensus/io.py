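"""Reading and writing the pipeline's file formats.

Formats
-------
* Aligned FASTA: one record per sequence, pre-gapped to the 127-column
  IMGT scaffold ("-" for gaps; "." accepted as a synonym on read).
* Numbered table: TSV with one row per (sequence, position) in the
  style of antibody-numbering tool output — columns ``id``,
  ``imgt_position``, ``residue`` and an optional ``over_length`` flag
  marking CDR3 insertions that did not fit the numbering scheme.
  Positions absent from the table become gaps.
* Consensus matrix TSV: a small metadata header followed by the
  127 x 21 count matrix; fractions are reconstructed as counts / n.
* Germline registry FASTA: headers like ``>IGKV1-33*01``, sequences
  pre-gapped to 127 columns.

Records failing the inclusion filters (wrong scaffold length, ambiguity
codes, over-length insertions, duplicate positions) are rejected with a
reason and reported, not raised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ConsensusMatrix
from .scaffold import (
    ALPHABET,
    GAP,
    N_POSITIONS,
    N_SYMBOLS,
    DEFAULT_ALPHABET,
    AlignedLightChain,
    GermlineAllele,
    GermlineRegistry,
    RejectionRecord,
    ResidueAlphabet,
    SequenceSet,
    validate_sequence,
)

__all__ = [
    "IngestReport",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_numbered_table",
    "write_consensus_tsv",
    "read_consensus_tsv",
    "read_germline_fasta",
    "write_germline_fasta",
]


@dataclass
class IngestReport:
    """QC bookkeeping for one ingestion: reads, accepts, rejections."""

    n_read: int = 0
    rejections: list[RejectionRecord] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return self.n_read - len(self.rejections)

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["id", "reason"])
            for rec in self.rejections:
                writer.writerow([rec.id, rec.reason])


def read_aligned_fasta(
    path,
    gene: str,
    cohort: str,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    deduplicate: bool = False,
) -> tuple[SequenceSet, IngestReport]:
    """Read a 127-column gapped FASTA into a SequenceSet.

    Records with a wrong scaffold length or symbols outside the
    21-symbol alphabet are rejected with reasons.  ``deduplicate``
    drops exact repeats of an already-accepted residue string (first
    occurrence kept).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    report = IngestReport()
    chains: list[AlignedLightChain] = []
    seen: set[str] = set()
    for rec in records:
        report.n_read += 1
        result = validate_sequence(
            rec.id, str(rec.seq), alphabet=alphabet, gene=gene, cohort=cohort
        )
        if isinstance(result, RejectionRecord):
            report.rejections.append(result)
            continue
        if deduplicate:
            if result.residues in seen:
                report.rejections.append(RejectionRecord(rec.id, "duplicate sequence"))
                continue
            seen.add(result.residues)
        chains.append(result)
    return SequenceSet.from_chains(gene, cohort, chains), report


def write_aligned_fasta(seq_set: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(chain.residues), id=chain.id, description="")
        for chain in seq_set
    ]
    SeqIO.write(records, str(path), "fasta")


def _truthy(value: str) -> bool:
    return value.strip().lower() in ("1", "true", "yes", "y")


def read_numbered_table(
    path,
    gene: str,
    cohort: str,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> tuple[SequenceSet, IngestReport]:
    """Assemble per-position numbered rows onto the 127-slot scaffold.

    Expected TSV columns: ``id``, ``imgt_position``, ``residue``
    [, ``over_length``].  Unlisted positions become gaps; duplicate
    (id, position) rows reject the whole id, as does a set over-length
    flag (CDR3 insertions beyond the numbering scheme's capacity).
    """
    path = Path(path)
    rows: dict[str, dict[int, str]] = {}
    rejected: dict[str, str] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "imgt_position", "residue"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: numbered table needs columns id, imgt_position, residue"
            )
        for lineno, row in enumerate(reader, start=2):
            seq_id = row["id"]
            try:
                position = int(row["imgt_position"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: bad imgt_position {row['imgt_position']!r}"
                ) from None
            if not 1 <= position <= N_POSITIONS:
                raise ValueError(f"{path}:{lineno}: position {position} outside 1..127")
            if seq_id not in rows:
                rows[seq_id] = {}
                order.append(seq_id)
            if row.get("over_length") and _truthy(row["over_length"]):
                rejected.setdefault(seq_id, "CDR3 insertion over-length")
                continue
            if position in rows[seq_id]:
                rejected.setdefault(seq_id, "duplicate position")
                continue
            rows[seq_id][position] = (row["residue"] or GAP).strip()
    if not rows:
        raise ValueError(f"no rows in numbered table {path}")
    report = IngestReport()
    chains: list[AlignedLightChain] = []
    for seq_id in order:
        report.n_read += 1
        if seq_id in rejected:
            report.rejections.append(RejectionRecord(seq_id, rejected[seq_id]))
            continue
        residues = [
            rows[seq_id].get(pos, GAP) for pos in range(1, N_POSITIONS + 1)
        ]
        result = validate_sequence(
            seq_id, residues, alphabet=alphabet, gene=gene, cohort=cohort
        )
        if isinstance(result, RejectionRecord):
            report.rejections.append(result)
        else:
            chains.append(result)
    return SequenceSet.from_chains(gene, cohort, chains), report


def write_consensus_tsv(matrix: ConsensusMatrix, path) -> None:
    """Serialise a consensus matrix losslessly (counts + metadata)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"#gene={matrix.gene}\n")
        fh.write(f"#cohort={matrix.cohort}\n")
        fh.write(f"#n_sequences={matrix.n_sequences}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", *ALPHABET])
        for pos in range(N_POSITIONS):
            writer.writerow([pos + 1, *matrix.counts[pos].tolist()])


def read_consensus_tsv(path) -> ConsensusMatrix:
    """Read a consensus matrix TSV; per-position count sums must equal n."""
    path = Path(path)
    meta: dict[str, str] = {}
    counts = np.zeros((N_POSITIONS, N_SYMBOLS), dtype=np.int64)
    with open(path, newline="") as fh:
        while True:
            offset = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(offset)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header[1:]) != ALPHABET:
            raise ValueError(f"{path}: bad or missing symbol header row")
        seen = 0
        for row in reader:
            pos = int(row[0])
            counts[pos - 1] = [int(v) for v in row[1:]]
            seen += 1
    if seen != N_POSITIONS:
        raise ValueError(f"{path}: expected 127 position rows, got {seen}")
    for key in ("gene", "cohort", "n_sequences"):
        if key not in meta:
            raise ValueError(f"{path}: missing #{key}= metadata line")
    n = int(meta["n_sequences"])
    rowsums = counts.sum(axis=1)
    if not (rowsums == n).all():
        bad = int(np.flatnonzero(rowsums != n)[0]) + 1
        raise ValueError(
            f"{path}: counts at position {bad} sum to {rowsums[bad - 1]}, "
            f"inconsistent with n_sequences={n}"
        )
    return ConsensusMatrix(
        gene=meta["gene"], cohort=meta["cohort"], n_sequences=n, counts=counts
    )


def read_germline_fasta(path, reference_allele_policy: str = "*01") -> GermlineRegistry:
    """Load a germline registry from gapped FASTA (headers gene*allele)."""
    registry = GermlineRegistry(reference_allele_policy=reference_allele_policy)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no germline records in {path}")
    for rec in records:
        name, star, allele = rec.id.partition("*")
        if not star:
            raise ValueError(f"germline header {rec.id!r} lacks an *allele suffix")
        seq = str(rec.seq).upper().replace(".", GAP)
        registry.add(GermlineAllele(gene=name, allele_id=f"*{allele}", residues=seq))
    return registry


def write_germline_fasta(registry: GermlineRegistry, path) -> None:
    records = [
        SeqRecord(Seq(allele.residues), id=allele.name, description="")
        for gene in registry.genes
        for allele in registry.alleles(gene)
    ]
    SeqIO.write(records, str(path), "fasta")
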