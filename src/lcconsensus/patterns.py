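"""Published residue-change patterns and their evaluation.

Light-chain residue changes reported as amyloidogenic in the literature
are written in a compact grammar anchored on IMGT positions:

* ``X37D``  — gain of D at 37 from any other germline residue;
* ``ST20X`` — loss of a germline serine/threonine at 20 to any other
  residue (``X`` = any residue other than that specified);
* ``K56DE`` — exact change of the germline K at 56 to D or E;
* ``R25G``  — exact change, single target residue;
* ``P115PP`` — insertion of a second proline next to the germline CDR3
  proline, requiring occupancy of the germline gap at 110-113;
* ``ANY52`` — any uncommon residue at position 52 (delegates to the
  rarity classifier).

Gain and loss patterns span all germline genes where the change is
possible: genes already carrying the gained residue, or lacking the
lost one, are ineligible and contribute neither carriers nor
denominator.  Exact patterns are scoped to the gene they were described
in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .consensus import ConsensusMatrix
from .enrichment import (
    DEFAULT_CONFIG,
    CarrierTable,
    EnrichmentConfig,
    EnrichmentResult,
    enrichment_result,
)
from .rarity import DEFAULT_THRESHOLDS, RarityThresholds, classify_residue
from .scaffold import (
    AMINO_ACIDS,
    GAP,
    N_POSITIONS,
    AlignedLightChain,
    GermlineAllele,
    GermlineRegistry,
    SequenceSet,
)

__all__ = [
    "ResidueChangePattern",
    "PatternCount",
    "parse_pattern",
    "eligible_genes",
    "sequence_matches",
    "detect_p115pp",
    "count_pattern",
    "pattern_enrichment",
    "load_published_changes",
]


@dataclass(frozen=True)
class ResidueChangePattern:
    """A gain/loss/exact/any-uncommon/proline-insertion query.

    ``residues`` is the gained set (gain), the germline set being lost
    (loss), or the exact target set; ``germline_residues`` records the
    anchor residue(s) named on the left of an exact label.
    ``gene_scope`` restricts eligibility to listed genes; None means all
    genes in the registry (gain/loss rules still apply).
    """

    kind: str  # gain | loss | exact | any_uncommon | insertion_PP
    position: int
    residues: frozenset[str] = frozenset()
    germline_residues: frozenset[str] = frozenset()
    gene_scope: tuple[str, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss", "exact", "any_uncommon", "insertion_PP"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not 1 <= self.position <= N_POSITIONS:
            raise ValueError(f"position {self.position} outside scaffold")
        if self.kind in ("gain", "exact") and not self.residues:
            raise ValueError(f"{self.kind} pattern needs target residues")
        if self.kind == "loss" and not self.residues:
            raise ValueError("loss pattern needs the germline residues being lost")

    def scoped(self, genes: tuple[str, ...] | list[str]) -> "ResidueChangePattern":
        return ResidueChangePattern(
            kind=self.kind,
            position=self.position,
            residues=self.residues,
            germline_residues=self.germline_residues,
            gene_scope=tuple(genes),
            label=self.label,
        )


_LABEL_RE = re.compile(r"^([A-Z]*?)(\d+)([A-Z]+)$")


def parse_pattern(label: str) -> ResidueChangePattern:
    """Parse a canonical pattern label into a ResidueChangePattern.

    ``ANY<pos>`` denotes any uncommon residue at the position;
    ``P<pos>PP`` the CDR3 proline insertion; a trailing ``X`` a loss; a
    leading ``X`` a gain; anything else an exact germline-to-target
    change (multi-letter sides are residue alternatives, e.g. ST, DE).
    """
    label = label.strip().upper()
    m = re.match(r"^ANY(\d+)$", label)
    if m:
        return ResidueChangePattern(
            kind="any_uncommon", position=int(m.group(1)), label=label
        )
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable pattern label {label!r}")
    left, pos_s, right = m.groups()
    position = int(pos_s)
    if left == "P" and right == "PP":
        return ResidueChangePattern(
            kind="insertion_PP",
            position=position,
            residues=frozenset("P"),
            germline_residues=frozenset("P"),
            label=label,
        )
    for side, name in ((left, "left"), (right, "right")):
        bad = set(side) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"pattern {label!r}: invalid {name} residues {bad}")
    if right == "X":
        if not left or "X" in left:
            raise ValueError(f"loss pattern {label!r} needs germline residues")
        return ResidueChangePattern(
            kind="loss",
            position=position,
            residues=frozenset(left),
            germline_residues=frozenset(left),
            label=label,
        )
    if left in ("", "X"):
        if "X" in right:
            raise ValueError(f"gain pattern {label!r} has X in gained set")
        return ResidueChangePattern(
            kind="gain", position=position, residues=frozenset(right), label=label
        )
    if "X" in left or "X" in right:
        raise ValueError(f"unparseable pattern label {label!r}")
    return ResidueChangePattern(
        kind="exact",
        position=position,
        residues=frozenset(right),
        germline_residues=frozenset(left),
        label=label,
    )


def eligible_genes(
    pattern: ResidueChangePattern, registry: GermlineRegistry
) -> list[str]:
    """Genes where the pattern's residue change is possible.

    Judged on each gene's reference allele: gain patterns exclude genes
    already carrying a gained residue at the position; loss patterns
    require the germline residue to be in the lost set.  An explicit
    gene_scope intersects with these rules.
    """
    candidates = (
        [g for g in pattern.gene_scope] if pattern.gene_scope else registry.genes
    )
    candidates = [g for g in candidates if g in registry.entries]
    if pattern.kind in ("exact", "any_uncommon", "insertion_PP"):
        return sorted(candidates)
    out = []
    for gene in candidates:
        germ = registry.reference(gene).residue_at(pattern.position)
        if pattern.kind == "gain" and germ not in pattern.residues:
            out.append(gene)
        elif pattern.kind == "loss" and germ in pattern.residues:
            out.append(gene)
    return sorted(out)


def detect_p115pp(
    seq: AlignedLightChain,
    germline: GermlineAllele,
    insertion_window: tuple[int, int] = (110, 113),
    anchor_window: tuple[int, int] = (113, 117),
) -> bool:
    """CDR3 proline-insertion call.

    True iff (i) at least one germline-gap slot in the insertion window
    is occupied by a residue, and (ii) two consecutive occupied scaffold
    slots in the anchor window both carry proline.  Adjacency skips gap
    slots, since IMGT insertion slots need not be physically adjacent
    on the scaffold.
    """
    lo, hi = insertion_window
    inserted = any(
        seq.residue_at(p) != GAP and germline.residue_at(p) == GAP
        for p in range(lo, hi + 1)
    )
    if not inserted:
        return False
    alo, ahi = anchor_window
    occupied = [
        seq.residue_at(p) for p in range(alo, ahi + 1) if seq.residue_at(p) != GAP
    ]
    return any(x == "P" and y == "P" for x, y in zip(occupied, occupied[1:]))


def sequence_matches(
    pattern: ResidueChangePattern,
    seq: AlignedLightChain,
    germline: GermlineAllele,
    reference: ConsensusMatrix | None = None,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
    gap_counts_as_loss: bool = True,
) -> bool:
    """Does one aligned sequence carry the pattern's residue change?

    Gap semantics: an observed gap counts as losing the germline residue
    (switchable via ``gap_counts_as_loss``) but never as gaining a
    residue.  ``any_uncommon`` patterns need the rarity ``reference``.
    """
    observed = seq.residue_at(pattern.position)
    germ = germline.residue_at(pattern.position)
    if pattern.kind == "gain":
        return observed != GAP and observed in pattern.residues and germ not in pattern.residues
    if pattern.kind == "loss":
        if germ not in pattern.residues:
            return False
        if observed == GAP:
            return gap_counts_as_loss
        return observed not in pattern.residues
    if pattern.kind == "exact":
        return observed in pattern.residues
    if pattern.kind == "insertion_PP":
        return detect_p115pp(seq, germline)
    if pattern.kind == "any_uncommon":
        if reference is None:
            raise ValueError("any_uncommon patterns need a reference matrix")
        return (
            classify_residue(reference, pattern.position, observed, thresholds)
            != "common"
        )
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class PatternCount:
    """Carriers of one pattern within one cohort, over eligible genes."""

    pattern: ResidueChangePattern
    cohort: str
    carriers: int
    eligible_n: int
    per_gene: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.eligible_n:
            raise ValueError("carriers must lie in [0, eligible_n]")
        if self.per_gene:
            totals = tuple(map(sum, zip(*self.per_gene.values())))
            if totals != (self.carriers, self.eligible_n):
                raise ValueError("per-gene breakdown must sum to totals")


def count_pattern(
    pattern: ResidueChangePattern,
    sets: list[SequenceSet],
    registry: GermlineRegistry,
    references: dict[str, ConsensusMatrix] | None = None,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, PatternCount]:
    """Count pattern carriers per cohort over the eligible genes only.

    ``sets`` must be gene-segregated; carriers and denominators
    aggregate across every set whose gene is pattern-eligible.
    ``references`` maps gene to the rarity reference matrix and is
    required only for any_uncommon patterns.
    """
    eligible = set(eligible_genes(pattern, registry))
    by_cohort: dict[str, dict[str, list[int]]] = {}
    for seq_set in sets:
        if seq_set.gene not in eligible:
            continue
        germ = registry.reference(seq_set.gene)
        reference = references.get(seq_set.gene) if references else None
        matched = sum(
            sequence_matches(
                pattern, chain, germ, reference=reference, thresholds=thresholds
            )
            for chain in seq_set
        )
        per_gene = by_cohort.setdefault(seq_set.cohort, {})
        entry = per_gene.setdefault(seq_set.gene, [0, 0])
        entry[0] += matched
        entry[1] += seq_set.n
    return {
        cohort: PatternCount(
            pattern=pattern,
            cohort=cohort,
            carriers=sum(v[0] for v in genes.values()),
            eligible_n=sum(v[1] for v in genes.values()),
            per_gene={g: (v[0], v[1]) for g, v in genes.items()},
        )
        for cohort, genes in by_cohort.items()
    }


def pattern_enrichment(
    pattern: ResidueChangePattern,
    target: PatternCount,
    comparator: PatternCount,
    config: EnrichmentConfig = DEFAULT_CONFIG,
) -> EnrichmentResult:
    """Enrichment of a pattern between two cohorts counted on identical
    eligibility."""
    if target.pattern.label != comparator.pattern.label:
        raise ValueError("pattern mismatch between counts")
    table = CarrierTable(
        a=target.carriers,
        n1=target.eligible_n,
        c=comparator.carriers,
        n2=comparator.eligible_n,
    )
    return enrichment_result(
        f"{pattern.label}:{target.cohort} vs {comparator.cohort}", table, config
    )


def load_published_changes() -> pd.DataFrame:
    """Published amyloidogenic residue-change carrier counts.

    Packaged regression fixture: per pattern, the carrier counts in the
    AL, MM and polyclonal (OAS) cohorts and the published enrichment
    ratios for the AL-vs-MM and AL-vs-OAS comparisons, as printed.
    gene_scope ``ALL_KV`` marks gain/loss patterns evaluated across all
    eligible kappa genes; other rows are gene-specific exact changes.
    """
    with resources.files("lcconsensus.data").joinpath(
        "published_changes.tsv"
    ).open() as fh:
        # ratio columns stay strings so their printed precision survives
        return pd.read_csv(
            fh, sep="\t", dtype={"or_al_mm": str, "or_al_oas": str}
        )
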