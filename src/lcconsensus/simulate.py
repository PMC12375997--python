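"""Synthetic light-chain repertoires with known ground truth.

Real inputs to this analysis are monoclonal (disease) and polyclonal
(healthy-repertoire) cohorts of IMGT-aligned V-L sequences.  This module
generates cohorts with the statistical structure the analysis assumes —
a gene-specific germline backbone, position-biased somatic residue
changes (a typical light chain accumulates roughly 5-15, so the default
mean is 10), optional allele polymorphism, and planted enrichment
effects whose truth is recorded — so that detection power and false-call
rates can be measured against a known answer.

All germline sequences produced here are synthetic: realistic in gap
structure (unoccupied slots at 58-64 and the CDR3 insertion slots
110-113) but not copies of any real allele.

Randomness is organised as named substreams keyed on (seed, stream id,
cohort), with one fixed-size block of draws per sequence index, so that
enlarging a cohort never reshuffles earlier sequences and identical
configs are byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .consensus import build_consensus
from .enrichment import (
    DEFAULT_CONFIG,
    EnrichmentConfig,
    UncommonPositionScan,
)
from .rarity import DEFAULT_THRESHOLDS, RarityThresholds
from .scaffold import (
    AMINO_ACIDS,
    ALPHABET,
    GAP,
    N_POSITIONS,
    GermlineAllele,
    GermlineRegistry,
    SequenceSet,
)

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SimulationTruth",
    "RecoveryReport",
    "make_synthetic_germline",
    "make_synthetic_registry",
    "make_mean_changes_profile",
    "simulate_repertoire",
    "plant_allele_polymorphism",
    "end_to_end_recovery",
]

GAP_CODE = ALPHABET.index(GAP)

#: IMGT slots unoccupied in typical human light chains (synthetic default).
DEFAULT_GAP_POSITIONS: tuple[int, ...] = tuple(range(58, 65)) + tuple(range(110, 114))


def _cohort_key(cohort: str) -> int:
    # stable across processes, unlike hash()
    return zlib.crc32(cohort.encode()) & 0x7FFFFFFF


def make_synthetic_germline(
    gene: str,
    seed: int,
    allele_id: str = "*01",
    gap_positions: tuple[int, ...] = DEFAULT_GAP_POSITIONS,
) -> GermlineAllele:
    """Generate a synthetic germline allele on the 127-position scaffold.

    Residues are drawn uniformly at random; the stated positions are
    gaps.  Synthetic stand-in for a real germline reference.
    """
    rng = np.random.default_rng([seed, _cohort_key(gene), _cohort_key(allele_id)])
    residues = list(rng.choice(list(AMINO_ACIDS), size=N_POSITIONS))
    for pos in gap_positions:
        residues[pos - 1] = GAP
    return GermlineAllele(gene=gene, allele_id=allele_id, residues="".join(residues))


def make_synthetic_registry(
    genes: list[str], seed: int, reference_allele_policy: str = "*01"
) -> GermlineRegistry:
    """A registry of synthetic reference alleles, one per gene."""
    registry = GermlineRegistry(reference_allele_policy=reference_allele_policy)
    for gene in genes:
        registry.add(make_synthetic_germline(gene, seed, reference_allele_policy))
    return registry


def make_mean_changes_profile(
    germline: GermlineAllele,
    target_mean: float = 10.0,
    hotspot_positions: tuple[int, ...] = (),
    hotspot_weight: float = 1.0,
) -> np.ndarray:
    """Per-position mutation rates summing to the target mean.

    Rates are uniform over the germline's occupied positions, with
    hotspot positions up-weighted by ``hotspot_weight`` before the whole
    profile is scaled so the expected number of residue changes per
    sequence equals ``target_mean``.  Germline-gap positions get rate 0.
    """
    if target_mean < 0:
        raise ValueError("target_mean must be >= 0")
    occupied = np.array([r != GAP for r in germline.residues])
    weights = occupied.astype(float)
    for pos in hotspot_positions:
        if not occupied[pos - 1]:
            raise ValueError(f"hotspot position {pos} is a germline gap")
        weights[pos - 1] = hotspot_weight
    total = weights.sum()
    if total == 0 and target_mean > 0:
        raise ValueError("no occupied positions to distribute changes over")
    rates = weights * (target_mean / total) if total else weights
    if (rates > 1).any():
        raise ValueError("infeasible profile: some per-position rate exceeds 1")
    return rates


@dataclass(frozen=True)
class PlantedEffect:
    """A known enrichment effect planted into selected cohorts.

    Carriers of one of ``residues`` at ``position`` appear at rate
    min(1, multiplier x base rate), where the base rate is the
    position's neutral mutation rate; non-carriers keep the germline
    residue there.  Multiplier 1 therefore reproduces the neutral
    carrier prevalence (null equivalence); cohorts not listed in
    ``cohorts`` mutate the position neutrally.
    """

    position: int
    residues: tuple[str, ...]
    multiplier: float
    cohorts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.position <= N_POSITIONS:
            raise ValueError(f"position {self.position} outside scaffold")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if not self.residues or any(r not in AMINO_ACIDS for r in self.residues):
            raise ValueError("effect residues must be amino acids")

    @property
    def label(self) -> str:
        return f"{''.join(self.residues)}@{self.position}x{self.multiplier:g}"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one cohort reproducibly.

    ``extra_alleles`` carries polymorphic alleles with their draw
    probabilities; the reference germline takes the remaining mass.
    ``gap_probability`` is the chance a somatic change deletes the
    residue (draws a gap) instead of substituting one of the 19
    non-germline amino acids uniformly.
    """

    germline: GermlineAllele
    cohort: str
    n_sequences: int
    seed: int
    mutation_rates: np.ndarray | None = None  # (127,), defaults to mean 10
    gap_probability: float = 0.02
    extra_alleles: tuple[tuple[GermlineAllele, float], ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap_probability must be in [0, 1)")
        extra_mass = sum(f for _, f in self.extra_alleles)
        if any(f < 0 for _, f in self.extra_alleles) or extra_mass > 1:
            raise ValueError("allele frequencies must be >= 0 and sum to <= 1")
        for allele, _ in self.extra_alleles:
            if allele.gene != self.germline.gene:
                raise ValueError("extra alleles must belong to the germline's gene")
        planted_positions = [e.position for e in self.planted_effects]
        if len(set(planted_positions)) != len(planted_positions):
            raise ValueError("planted effects must target distinct positions")
        rates = (
            make_mean_changes_profile(self.germline)
            if self.mutation_rates is None
            else np.asarray(self.mutation_rates, dtype=float)
        )
        if rates.shape != (N_POSITIONS,) or (rates < 0).any() or (rates > 1).any():
            raise ValueError("mutation_rates must be 127 probabilities")
        object.__setattr__(self, "mutation_rates", rates)

    @property
    def registry(self) -> GermlineRegistry:
        registry = GermlineRegistry()
        registry.add(self.germline)
        for allele, _ in self.extra_alleles:
            registry.add(allele)
        return registry


@dataclass
class SimulationTruth:
    """Ground truth for one simulated cohort.

    ``mutated_positions[i]`` lists positions where sequence i differs
    from its drawn allele's germline; ``planted_carriers`` flags, per
    effect label, which sequences were forced to carry the effect
    residue; ``carrier_rates`` is the realised per-position fraction of
    sequences differing from their drawn allele.
    """

    alleles: list[str]
    mutated_positions: list[list[int]]
    planted_carriers: dict[str, np.ndarray]
    carrier_rates: np.ndarray


def _stream(config: SimulationConfig, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, stream_id, _cohort_key(config.cohort)]
    )


def simulate_repertoire(
    config: SimulationConfig,
) -> tuple[SequenceSet, SimulationTruth]:
    """Draw one cohort: allele, neutral changes, then planted effects.

    Per sequence: (i) an allele is sampled from the configured
    frequencies; (ii) each occupied position mutates independently with
    its profile rate; (iii) a mutation substitutes one of the 19
    non-germline amino acids uniformly, or a gap with
    ``gap_probability``; (iv) at planted positions (in affected
    cohorts) the neutral draw is replaced by the forced-carrier
    mechanism described on :class:`PlantedEffect`.
    """
    n = config.n_sequences
    alleles = [config.germline] + [a for a, _ in config.extra_alleles]
    freqs = np.array(
        [1 - sum(f for _, f in config.extra_alleles)]
        + [f for _, f in config.extra_alleles]
    )
    allele_codes = np.vstack([a.codes for a in alleles])  # (k, 127)

    u_allele = _stream(config, 0).random(n)
    allele_idx = np.searchsorted(np.cumsum(freqs), u_allele, side="right")
    allele_idx = np.minimum(allele_idx, len(alleles) - 1)
    base = allele_codes[allele_idx]  # (n, 127)
    matrix = base.copy()

    rates = config.mutation_rates
    u_mut = _stream(config, 1).random((n, N_POSITIONS))
    u_sub = _stream(config, 2).random((n, N_POSITIONS))
    mutate = (u_mut < rates[None, :]) & (base != GAP_CODE)

    gp = config.gap_probability
    to_gap = mutate & (u_sub < gp)
    to_res = mutate & ~to_gap
    # uniform over the 19 amino acids other than the germline one:
    # rescale the remaining uniform mass and skip past the germline code
    rescaled = np.clip((u_sub - gp) / (1 - gp), 0, 1 - 1e-12)
    choice = np.floor(rescaled * 19).astype(np.uint8)
    choice = choice + (choice >= base)
    matrix[to_gap] = GAP_CODE
    matrix[to_res] = choice[to_res]

    planted_carriers: dict[str, np.ndarray] = {}
    rng_plant = _stream(config, 3)
    for effect in config.planted_effects:
        u_carry = rng_plant.random(n)
        u_residue = rng_plant.random(n)  # drawn unconditionally: fixed block size
        if config.cohort not in effect.cohorts:
            continue
        col = effect.position - 1
        p_eff = min(1.0, effect.multiplier * rates[col])
        carrier = u_carry < p_eff
        residue_codes = np.array(
            [ALPHABET.index(r) for r in effect.residues], dtype=np.uint8
        )
        drawn = residue_codes[
            np.floor(u_residue * len(residue_codes)).astype(int)
        ]
        matrix[:, col] = base[:, col]  # planted mechanism replaces neutral
        matrix[carrier, col] = drawn[carrier]
        planted_carriers[effect.label] = carrier

    ids = [f"{config.cohort}_{i:06d}" for i in range(n)]
    allele_labels = [alleles[i].allele_id for i in allele_idx]
    seq_set = SequenceSet(
        config.germline.gene, config.cohort, matrix, ids, allele_labels
    )

    differs = matrix != base
    truth = SimulationTruth(
        alleles=allele_labels,
        mutated_positions=[
            (np.flatnonzero(differs[i]) + 1).tolist() for i in range(n)
        ],
        planted_carriers=planted_carriers,
        carrier_rates=differs.mean(axis=0),
    )
    return seq_set, truth


def plant_allele_polymorphism(
    config: SimulationConfig,
    position: int,
    residues: tuple[str, ...],
    frequencies: tuple[float, ...],
) -> SimulationConfig:
    """Extend a config with polymorphic alleles differing at one position.

    Each (residue, frequency) pair becomes a new allele (*02, *03, ...)
    identical to the reference germline except at ``position``; the
    reference keeps the remaining probability mass.
    """
    if len(residues) != len(frequencies):
        raise ValueError("residues and frequencies must align")
    if any(e.position == position for e in config.planted_effects):
        raise ValueError(f"position {position} already carries a planted effect")
    existing = len(config.extra_alleles)
    new_alleles = list(config.extra_alleles)
    for k, (residue, freq) in enumerate(zip(residues, frequencies)):
        if residue not in AMINO_ACIDS:
            raise ValueError(f"polymorphic residue {residue!r} is not an amino acid")
        seq = list(config.germline.residues)
        seq[position - 1] = residue
        allele = GermlineAllele(
            gene=config.germline.gene,
            allele_id=f"*{existing + k + 2:02d}",
            residues="".join(seq),
        )
        new_alleles.append((allele, freq))
    return replace(config, extra_alleles=tuple(new_alleles))


@dataclass
class RecoveryReport:
    """Outcome of an end-to-end planted-effect recovery run."""

    gene: str
    planted: list[dict]  # per effect: position, multiplier, ratio, q, detected
    false_positive_positions: list[int]
    n_positions_tested: int
    alpha: float

    @property
    def false_call_rate(self) -> float:
        if self.n_positions_tested == 0:
            return 0.0
        return len(self.false_positive_positions) / self.n_positions_tested

    @property
    def all_detected(self) -> bool:
        return all(e["detected"] for e in self.planted)


def end_to_end_recovery(
    config: SimulationConfig,
    n_reference: int = 20_000,
    reference_cohort: str = "OAS",
    alpha: float = 0.05,
    enrichment_config: EnrichmentConfig = DEFAULT_CONFIG,
    thresholds: RarityThresholds = DEFAULT_THRESHOLDS,
) -> RecoveryReport:
    """Simulate target + reference cohorts, scan, and score recovery.

    The reference cohort is drawn from the same neutral process (planted
    effects restricted to other cohorts do not apply) and serves as both
    the rarity reference and the comparator.  Detection means q < alpha
    with ratio > 1 at the planted position; any other non-excluded
    position with q < alpha counts as a false call.
    """
    target_set, _ = simulate_repertoire(config)
    ref_config = replace(
        config, cohort=reference_cohort, n_sequences=n_reference
    )
    ref_set, _ = simulate_repertoire(ref_config)
    reference = build_consensus(ref_set)
    scan = UncommonPositionScan(
        target=target_set,
        comparator=reference,
        reference=reference,
        germline=config.germline,
        config=enrichment_config,
        thresholds=thresholds,
    ).fit()

    planted_positions = {e.position for e in config.planted_effects}
    planted_rows = []
    for effect in config.planted_effects:
        res = scan.at(effect.position)
        detected = (
            not res.excluded
            and res.q is not None
            and not np.isnan(res.q)
            and res.q < alpha
            and res.ratio > 1
        )
        planted_rows.append(
            {
                "position": effect.position,
                "multiplier": effect.multiplier,
                "ratio": res.ratio,
                "q": res.q,
                "detected": detected,
            }
        )
    false_calls = []
    n_tested = 0
    for pos, res in enumerate(scan.results, start=1):
        if res.excluded or pos in planted_positions:
            continue
        n_tested += 1
        if res.q is not None and not np.isnan(res.q) and res.q < alpha:
            false_calls.append(pos)
    return RecoveryReport(
        gene=config.germline.gene,
        planted=planted_rows,
        false_positive_positions=false_calls,
        n_positions_tested=n_tested,
        alpha=alpha,
    )
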