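"""Common/uncommon/rare residue classification against a reference matrix.

A residue observed in a monoclonal light chain is judged by how often it
appears at the same position among polyclonal sequences from the same
germline gene: below 10% of the reference it is "uncommon", below 1%
"rare".  Gaps are classified like any residue, so a germline-gap
position is usually "common" for the gap while an insertion there
registers as uncommon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import ConsensusMatrix
from .scaffold import ALPHABET, N_POSITIONS, AlignedLightChain, SequenceSet

__all__ = [
    "RarityThresholds",
    "ProfileEntry",
    "FrequencyProfile",
    "PositionCarrierCounts",
    "classify_residue",
    "classify_fraction",
    "uncommon_mask",
    "frequency_profile",
    "count_uncommon_carriers",
    "rarity_histogram",
]


@dataclass(frozen=True)
class RarityThresholds:
    """Frequency cutoffs: common >= uncommon_cutoff > rare residues."""

    uncommon_cutoff: float = 0.10
    rare_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.rare_cutoff < self.uncommon_cutoff < 1:
            raise ValueError("require 0 < rare_cutoff < uncommon_cutoff < 1")


DEFAULT_THRESHOLDS = RarityThresholds()


def classify_fraction(
    fraction: float, thresholds: RarityThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify a reference frequency: 'common', 'uncommon', or 'rare'.

    The boundary fraction exactly at the cutoff is common ("appearing in
    >= 10% of reference sequences"); rare is a sub-class of uncommon.
    """
    if fraction >= thresholds.uncommon_cutoff:
        return "common"
    if fraction < thresholds.rare_cutoff:
        return "rare"
    return "uncommon"


def classify_residue(
    reference: ConsensusMatrix,
    position: int,
    residue: str,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Rarity class of ``residue`` at ``position`` under the reference.

    A residue never observed in the reference (fraction 0) is rare.
    """
    return classify_fraction(reference.fraction(position, residue), thresholds)


def uncommon_mask(
    reference: ConsensusMatrix,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """(127, 21) boolean mask: True where a symbol is uncommon."""
    return reference.fractions < thresholds.uncommon_cutoff


@dataclass(frozen=True)
class ProfileEntry:
    position: int
    residue: str
    frequency: float
    rarity: str


@dataclass(frozen=True)
class FrequencyProfile:
    """Reference frequencies of every residue of one query sequence."""

    sequence_id: str
    reference_label: str
    entries: tuple[ProfileEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_POSITIONS:
            raise ValueError("profile must have 127 entries")

    def at(self, position: int) -> ProfileEntry:
        return self.entries[position - 1]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.entries])

    def uncommon_positions(self) -> list[int]:
        return [e.position for e in self.entries if e.rarity != "common"]


def frequency_profile(
    seq: AlignedLightChain,
    reference: ConsensusMatrix,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> FrequencyProfile:
    """How often each residue of ``seq`` occurs in the reference cohort.

    One entry per scaffold position (gap included); low values flag
    residues that are unusual for this germline gene in the polyclonal
    repertoire and may merit biophysical follow-up.
    """
    if seq.gene != reference.gene:
        raise ValueError(f"gene mismatch: {seq.gene} vs {reference.gene}")
    fractions = reference.fractions
    codes = seq.codes
    entries = []
    for pos in range(N_POSITIONS):
        frac = float(fractions[pos, codes[pos]])
        entries.append(
            ProfileEntry(
                position=pos + 1,
                residue=ALPHABET[codes[pos]],
                frequency=frac,
                rarity=classify_fraction(frac, thresholds),
            )
        )
    return FrequencyProfile(
        sequence_id=seq.id, reference_label=reference.label, entries=tuple(entries)
    )


@dataclass(frozen=True)
class PositionCarrierCounts:
    """Per-position number of sequences carrying an uncommon residue."""

    gene: str
    cohort: str
    n: int
    carriers: np.ndarray  # (127,) ints

    def __post_init__(self) -> None:
        carriers = np.asarray(self.carriers, dtype=np.int64)
        object.__setattr__(self, "carriers", carriers)
        if carriers.shape != (N_POSITIONS,):
            raise ValueError("carriers must have length 127")
        if (carriers < 0).any() or (carriers > self.n).any():
            raise ValueError("carriers must lie in [0, n]")

    def at(self, position: int) -> int:
        return int(self.carriers[position - 1])


def count_uncommon_carriers(
    seq_set: SequenceSet,
    reference: ConsensusMatrix,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> PositionCarrierCounts:
    """Count, per position, the sequences whose residue is uncommon."""
    if seq_set.gene != reference.gene:
        raise ValueError(f"gene mismatch: {seq_set.gene} vs {reference.gene}")
    mask = uncommon_mask(reference, thresholds)  # (127, 21)
    # mask lookup per (sequence, position) cell, then column sums
    carrier = mask[np.arange(N_POSITIONS)[None, :], seq_set.matrix]
    return PositionCarrierCounts(
        gene=seq_set.gene,
        cohort=seq_set.cohort,
        n=seq_set.n,
        carriers=carrier.sum(axis=0),
    )


def rarity_histogram(
    seq_set: SequenceSet,
    reference: ConsensusMatrix,
    bins: int | np.ndarray = 50,
    include_gaps: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of reference frequencies of all residues in a set.

    One observation per (sequence, position) cell — 127 * n in total
    when gaps are included; with ``include_gaps=False``, cells where the
    sequence carries a gap are dropped.  Returns (counts, bin_edges) as
    from ``numpy.histogram`` over [0, 1].
    """
    if seq_set.gene != reference.gene:
        raise ValueError(f"gene mismatch: {seq_set.gene} vs {reference.gene}")
    fractions = reference.fractions
    values = fractions[np.arange(N_POSITIONS)[None, :], seq_set.matrix]
    if not include_gaps:
        values = values[seq_set.matrix != ALPHABET.index("-")]
    return np.histogram(values.ravel(), bins=bins, range=(0.0, 1.0))
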