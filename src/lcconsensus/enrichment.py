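"""Carrier-count enrichment statistics between light-chain cohorts.

The central statistic compares how often a residue feature (a specific
residue change, or any uncommon residue at a position) is carried in two
cohorts, from a 2x2 table of carriers vs non-carriers.  To avoid
division by zero, 0.1 is added to each of the four cells before the
ratio is formed.  The default ``ratio_form`` is the ratio of corrected
carrier proportions,

    [(a + 0.1) / (n1 + 0.2)] / [(c + 0.1) / (n2 + 0.2)],

which is what the enrichment values reported in this field's carrier
tables correspond to even when labelled "OR"; the textbook cross-product
odds ratio is available as an option.  Confidence intervals and p-values
come from a normal (Wald) approximation on the log ratio, and
multiple-testing control uses the Benjamini-Hochberg FDR step-up.

``UncommonPositionScan`` is the model object for the per-position scan
of a target cohort against a comparator: construct it from sequence
sets, call :meth:`~UncommonPositionScan.fit`, and read estimates,
intervals, q-values and exclusion flags off the returned
:class:`PositionScanResults` (``summary()`` gives a table).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusMatrix, build_consensus
from .rarity import (
    DEFAULT_THRESHOLDS,
    PositionCarrierCounts,
    RarityThresholds,
    count_uncommon_carriers,
    uncommon_mask,
)
from .scaffold import (
    ALPHABET,
    GAP,
    N_POSITIONS,
    DEFAULT_SCAFFOLD,
    GermlineAllele,
    GermlineRegistry,
    ImgtScaffold,
    SequenceSet,
)

__all__ = [
    "CarrierTable",
    "EnrichmentConfig",
    "EnrichmentResult",
    "corrected_ratio",
    "wald_test",
    "fdr_adjust",
    "enrichment_result",
    "UncommonPositionScan",
    "PositionScanResults",
    "counts_from_consensus",
    "apply_artifact_filter",
    "allele_stratify",
    "allele_differing_positions",
]


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier counts: a of n1 in cohort 1, c of n2 in cohort 2."""

    a: int
    n1: int
    c: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n2):
            raise ValueError("carriers must lie within cohort sizes")

    def swapped(self) -> "CarrierTable":
        return CarrierTable(a=self.c, n1=self.n2, c=self.a, n2=self.n1)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Statistical settings for carrier-table enrichment.

    correction: additive count added to each of the four cells.
    ci_level:   two-sided confidence level (z from the normal quantile).
    ratio_form: 'proportion_ratio' (default) or 'odds_ratio'.
    se_form:    'proportion' (log ratio-of-proportions SE, default) or
                'woolf' (classic log odds-ratio SE).
    fdr_family: label of the multiple-testing family this result joins.
    """

    correction: float = 0.1
    ci_level: float = 0.95
    ratio_form: str = "proportion_ratio"
    se_form: str = "proportion"
    fdr_family: str = "default"

    def __post_init__(self) -> None:
        if self.correction < 0:
            raise ValueError("correction must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.ratio_form not in ("proportion_ratio", "odds_ratio"):
            raise ValueError(f"unknown ratio_form {self.ratio_form!r}")
        if self.se_form not in ("proportion", "woolf"):
            raise ValueError(f"unknown se_form {self.se_form!r}")

    @property
    def z(self) -> float:
        return float(norm.ppf(0.5 + self.ci_level / 2))


DEFAULT_CONFIG = EnrichmentConfig()


def _corrected_cells(
    table: CarrierTable, delta: float
) -> tuple[float, float, float, float]:
    return (
        table.a + delta,
        table.n1 - table.a + delta,
        table.c + delta,
        table.n2 - table.c + delta,
    )


def corrected_ratio(
    table: CarrierTable, config: EnrichmentConfig = DEFAULT_CONFIG
) -> float:
    """Enrichment ratio with the additive count correction applied.

    In 'proportion_ratio' form this is the ratio of corrected carrier
    proportions; in 'odds_ratio' form the corrected cross-product ratio.
    With correction 0 and positive cells both reduce to the uncorrected
    classical statistics.
    """
    a, b, c, d = _corrected_cells(table, config.correction)
    if config.ratio_form == "proportion_ratio":
        return (a / (a + b)) / (c / (c + d))
    return (a * d) / (b * c)


def wald_test(
    table: CarrierTable, config: EnrichmentConfig = DEFAULT_CONFIG
) -> tuple[float, float, float, float]:
    """Normal-approximation inference on the log enrichment ratio.

    Returns (log_se, ci_low, ci_high, p).  The default SE is the log
    ratio-of-proportions form sqrt(1/a - 1/n1 + 1/c - 1/n2) on corrected
    cells; 'woolf' gives the classic log odds-ratio SE
    sqrt(1/a + 1/b + 1/c + 1/d).
    """
    a, b, c, d = _corrected_cells(table, config.correction)
    if config.se_form == "woolf":
        log_se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    else:
        log_se = float(np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)))
    log_ratio = float(np.log(corrected_ratio(table, config)))
    half = config.z * log_se
    ci_low = float(np.exp(log_ratio - half))
    ci_high = float(np.exp(log_ratio + half))
    p = float(2 * norm.sf(abs(log_ratio) / log_se)) if log_se > 0 else 1.0
    return log_se, ci_low, ci_high, min(p, 1.0)


def fdr_adjust(p_values, families=None) -> np.ndarray:
    """Benjamini-Hochberg q-values, computed within each family.

    ``families`` is an optional sequence of group labels the same length
    as ``p_values``; the step-up is applied separately per group.  NaN
    p-values (e.g. excluded positions) propagate as NaN q-values and do
    not count toward any family's test count.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    if families is None:
        families = np.zeros(p.shape, dtype=int)
    families = np.asarray(families)
    for fam in np.unique(families):
        idx = np.flatnonzero((families == fam) & ~np.isnan(p))
        if idx.size:
            q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    """One carrier-table comparison with its ratio, CI, p and q."""

    identifier: str
    table: CarrierTable
    ratio: float
    log_se: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None


def enrichment_result(
    identifier: str,
    table: CarrierTable,
    config: EnrichmentConfig = DEFAULT_CONFIG,
) -> EnrichmentResult:
    """Compute ratio, CI and p for one carrier table (q left unset)."""
    ratio = corrected_ratio(table, config)
    log_se, ci_low, ci_high, p = wald_test(table, config)
    return EnrichmentResult(
        identifier=identifier,
        table=table,
        ratio=ratio,
        log_se=log_se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
    )


def counts_from_consensus(
    matrix: ConsensusMatrix, thresholds: RarityThresholds, reference: ConsensusMatrix
) -> PositionCarrierCounts:
    """Reconstruct uncommon-carrier counts from a consensus matrix.

    Large comparator cohorts may be supplied as a consensus matrix with
    its n rather than as explicit sequences; carrier counts are the
    column sums of the count matrix over uncommon symbols.
    """
    mask = uncommon_mask(reference, thresholds)
    carriers = (matrix.counts * mask).sum(axis=1)
    return PositionCarrierCounts(
        gene=matrix.gene, cohort=matrix.cohort, n=matrix.n_sequences, carriers=carriers
    )


class UncommonPositionScan:
    """Model: per-position uncommon-residue enrichment, target vs comparator.

    Parameters
    ----------
    target:
        The cohort of interest (e.g. the amyloidosis-associated set).
    comparator:
        Either another :class:`SequenceSet` or a :class:`ConsensusMatrix`
        built from one (for very large cohorts whose sequences are not
        kept in memory).
    reference:
        Consensus matrix defining which residues are uncommon (normally
        the polyclonal cohort for the same gene; often the comparator).
    germline:
        Reference germline allele; positions whose germline residue is a
        gap are flagged not-plotted, and the germline-only artifact
        filter needs the germline residue at each position.
    """

    def __init__(
        self,
        target: SequenceSet,
        comparator: SequenceSet | ConsensusMatrix,
        reference: ConsensusMatrix,
        germline: GermlineAllele,
        config: EnrichmentConfig = DEFAULT_CONFIG,
        thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
        scaffold: ImgtScaffold = DEFAULT_SCAFFOLD,
        apply_artifact_filter: bool = True,
    ) -> None:
        genes = {target.gene, comparator.gene, reference.gene, germline.gene}
        if len(genes) != 1:
            raise ValueError(f"gene mismatch across scan inputs: {sorted(genes)}")
        self.target = target
        self.comparator = comparator
        self.reference = reference
        self.germline = germline
        self.config = config
        self.thresholds = thresholds
        self.scaffold = scaffold
        self.apply_artifact_filter = apply_artifact_filter

    def _comparator_counts(self) -> PositionCarrierCounts:
        if isinstance(self.comparator, ConsensusMatrix):
            return counts_from_consensus(
                self.comparator, self.thresholds, self.reference
            )
        return count_uncommon_carriers(
            self.comparator, self.reference, self.thresholds
        )

    def fit(self) -> "PositionScanResults":
        target_counts = count_uncommon_carriers(
            self.target, self.reference, self.thresholds
        )
        comp_counts = self._comparator_counts()
        comparison = f"{self.target.cohort} vs {comp_counts.cohort}"

        germline_codes = self.germline.codes
        target_matrix = self.target.matrix
        results: list[EnrichmentResult] = []
        for pos in range(1, N_POSITIONS + 1):
            table = CarrierTable(
                a=target_counts.at(pos),
                n1=target_counts.n,
                c=comp_counts.at(pos),
                n2=comp_counts.n,
            )
            res = enrichment_result(
                f"{self.target.gene}:{pos}:{comparison}", table, self.config
            )
            excluded, reason = False, None
            if germline_codes[pos - 1] == ALPHABET.index(GAP):
                excluded, reason = True, "germline gap"
            elif (
                self.apply_artifact_filter
                and res.ratio > 1
                and bool(
                    (target_matrix[:, pos - 1] == germline_codes[pos - 1]).all()
                )
            ):
                # positive ratio driven purely by the germline residue
                # being uncommon in a huge comparator: an artifact of the
                # sample-size imbalance, not a disease signal
                excluded, reason = True, "germline-only artifact"
            if excluded:
                results.append(
                    replace(res, excluded=True, exclusion_reason=reason, q=np.nan)
                )
            else:
                results.append(res)

        p = np.array([np.nan if r.excluded else r.p for r in results])
        q = fdr_adjust(p)
        results = [
            r if r.excluded else replace(r, q=float(qv))
            for r, qv in zip(results, q)
        ]
        return PositionScanResults(
            gene=self.target.gene,
            comparison=comparison,
            results=results,
            config=self.config,
            thresholds=self.thresholds,
            scaffold=self.scaffold,
            n_target=target_counts.n,
            n_comparator=comp_counts.n,
        )


@dataclass
class PositionScanResults:
    """Fitted per-position enrichment scan.

    ``frame`` exposes everything as a DataFrame (one row per scaffold
    position); ``enriched_positions``/``depleted_positions`` apply the
    q < alpha significance label without filtering the stored results.
    """

    gene: str
    comparison: str
    results: list[EnrichmentResult]
    config: EnrichmentConfig
    thresholds: RarityThresholds
    scaffold: ImgtScaffold
    n_target: int
    n_comparator: int
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            rows = []
            for pos, r in enumerate(self.results, start=1):
                rows.append(
                    {
                        "gene": self.gene,
                        "position": pos,
                        "region": self.scaffold.region_of(pos),
                        "a": r.table.a,
                        "n1": r.table.n1,
                        "c": r.table.c,
                        "n2": r.table.n2,
                        "ratio": r.ratio,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p": np.nan if r.excluded else r.p,
                        "q": r.q if r.q is not None else np.nan,
                        "excluded": r.excluded,
                        "reason": r.exclusion_reason or "",
                    }
                )
            self._frame = pd.DataFrame(rows)
        return self._frame

    def at(self, position: int) -> EnrichmentResult:
        return self.results[position - 1]

    def enriched_positions(self, alpha: float = 0.05) -> list[int]:
        return [
            pos
            for pos, r in enumerate(self.results, start=1)
            if not r.excluded and r.ratio > 1 and r.q is not None and r.q < alpha
        ]

    def depleted_positions(self, alpha: float = 0.05) -> list[int]:
        return [
            pos
            for pos, r in enumerate(self.results, start=1)
            if not r.excluded and r.ratio < 1 and r.q is not None and r.q < alpha
        ]

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            f"Uncommon-residue position scan: {self.gene}, {self.comparison}",
            f"  n_target={self.n_target}  n_comparator={self.n_comparator}  "
            f"correction={self.config.correction}  "
            f"ratio_form={self.config.ratio_form}",
            f"  enriched (q<{alpha}): {self.enriched_positions(alpha) or 'none'}",
            f"  depleted (q<{alpha}): {self.depleted_positions(alpha) or 'none'}",
            "",
        ]
        frame = self.frame.copy()
        shown = frame[~frame["excluded"]]
        lines.append(
            shown.to_string(
                index=False,
                columns=[
                    "position", "region", "a", "n1", "c", "n2",
                    "ratio", "ci_low", "ci_high", "p", "q",
                ],
                float_format=lambda v: f"{v:.4g}",
            )
        )
        n_excluded = int(frame["excluded"].sum())
        lines.append(f"\n{n_excluded} positions excluded (germline gap or artifact)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def apply_artifact_filter(
    scan: PositionScanResults,
    target: SequenceSet,
    germline: GermlineAllele,
) -> PositionScanResults:
    """Exclude germline-only artifact positions from a fitted scan.

    A position with ratio > 1 where every target sequence carries
    exactly the germline residue owes its positive ratio to the germline
    residue being uncommon in a much larger comparator — a sample-size
    artifact, not enrichment.  Such positions are marked excluded and
    q-values are recomputed over the surviving family.  Scans fitted
    with ``apply_artifact_filter=True`` (the default) have this built in;
    this standalone form serves scans fitted without it.
    """
    germline_codes = germline.codes
    results = []
    for pos, r in enumerate(scan.results, start=1):
        if (
            not r.excluded
            and r.ratio > 1
            and bool((target.matrix[:, pos - 1] == germline_codes[pos - 1]).all())
        ):
            r = replace(
                r, excluded=True, exclusion_reason="germline-only artifact", q=np.nan
            )
        results.append(r)
    p = np.array([np.nan if r.excluded else r.p for r in results])
    q = fdr_adjust(p)
    results = [
        r if r.excluded else replace(r, q=float(qv)) for r, qv in zip(results, q)
    ]
    return PositionScanResults(
        gene=scan.gene,
        comparison=scan.comparison,
        results=results,
        config=scan.config,
        thresholds=scan.thresholds,
        scaffold=scan.scaffold,
        n_target=scan.n_target,
        n_comparator=scan.n_comparator,
    )


def allele_stratify(
    seq_set: SequenceSet, registry: GermlineRegistry, position: int
) -> pd.DataFrame:
    """Residue-by-allele contingency table at one position.

    Rows are assigned alleles (sequences without an assignment fall
    under 'unassigned'), columns are residues observed at the position;
    cell values are sequence counts.  Column marginals equal the
    consensus counts for the same set.
    """
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position {position} outside scaffold")
    alleles = [a if a else "unassigned" for a in seq_set.alleles]
    residues = [ALPHABET[c] for c in seq_set.matrix[:, position - 1]]
    frame = pd.crosstab(
        pd.Series(alleles, name="allele"), pd.Series(residues, name="residue")
    )
    return frame


def allele_differing_positions(alleles: list[GermlineAllele]) -> list[int]:
    """Positions where the alleles of one gene carry different residues.

    Fewer than two alleles can never disagree, so the list is empty.
    """
    if len(alleles) < 2:
        return []
    stacked = np.vstack([a.codes for a in alleles])
    differs = (stacked != stacked[0]).any(axis=0)
    return [int(p) + 1 for p in np.flatnonzero(differs)]
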