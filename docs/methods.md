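# Methods

## The scaffold and its data model

All sequences live on the IMGT unique-numbering scaffold for light-chain
V domains: 127 ordered positions, of which any given sequence occupies a
subset, the remainder being gaps. The gap is a first-class 21st symbol
alongside the 20 amino acids, so counting, classification and
enrichment all see deletions and insertions the same way they see
substitutions. Region annotations follow the IMGT convention — FR1 1–26,
CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4
118–127 — shipped as an overridable configuration table since published
analyses occasionally shift CDR boundaries by a position or two.

The package does **not** align or number sequences; it consumes
pre-numbered input (127-column gapped FASTA or per-position numbered
tables in the style of antibody-numbering tools). Inclusion filters are
applied at ingestion: wrong scaffold length, any symbol outside the
21-letter alphabet (ambiguity codes included), and over-length CDR3
insertions are rejected with recorded reasons rather than raised, so a
QC report reconciles every input record. Paralogous distal-locus IGKV
gene names (e.g. `IGKV1D-33`) are normalised to the proximal locus at
ingestion. "Residue change", not "mutation", is used throughout because
only protein sequences are compared and germline vs somatic origin is
not distinguished.

## Consensus matrices

For one germline gene and one cohort, the consensus matrix holds the
count and fraction of sequences carrying each symbol at each position
(rows sum to the cohort size exactly; fractions are counts/n, so
serialisation stores counts and is lossless). Derived comparisons:

- **Difference matrices**: entry-wise subtraction of fractions; rows sum
  to zero by construction.
- **Per-position Gini coefficient** of the 21-entry fraction vector,
  measuring residue-wise diversity: 0 for all symbols equally frequent,
  1 for a single residue in every sequence. The sample-corrected
  estimator (mean absolute difference scaled by n/(n−1)) is the
  default because the uncorrected form tops out at 20/21 for a point
  mass; the uncorrected variant is available via `corrected=False`.
- **Position-wise Pearson ρ** between the two cohorts' 21-entry residue
  distributions at each position (ρ = 1 for identical distributions).
  Positions where either distribution is exactly uniform have no
  defined correlation and return NaN; variances below 1e-20 are treated
  as zero to absorb rounding noise in the fractions. A secondary
  residue-wise mode correlates the 127-position profiles of each
  symbol.
- **Euclidean (Frobenius) distance** over all 127 × 21 fraction cells,
  equal to the total magnitude of the difference matrix. Distances are
  computed on fractions (not counts) so cohorts of different sizes are
  comparable; clustering uses complete linkage by default (the common
  default of standard hierarchical-clustering implementations), with
  average and single linkage as options, and exports newick.
- **Logo data**: per position, the letter heights of all residues except
  the single most frequent one, which is removed so the display is not
  dominated by the germline residue; heights are raw fractions, not
  information content. Ties for most-frequent are broken toward the
  lowest alphabet index, deterministically.

## Uncommon residues

Rarity is judged against a reference consensus matrix — in the intended
use, the polyclonal-repertoire matrix for the same germline gene. A
residue (or gap) observed at a position is *common* if its reference
fraction is ≥ 0.10, *uncommon* below 0.10, and additionally *rare*
below 0.01; a residue never seen in the reference is rare. The boundary
fraction exactly at a cutoff is the more common class (≥, not >). The
thresholds are explicit parameters; the API takes the reference matrix
explicitly so synthetic cohorts can stand in. Because gaps are
classified like residues, a germline-gap position is normally common
(for the gap) and an insertion there registers as uncommon.

Frequency profiles list, for one query sequence, the reference fraction
and rarity class of its residue at every position. Carrier counts give,
per position, how many sequences of a set carry an uncommon residue;
the rarity histogram pools the reference frequencies of all
(sequence, position) cells, gaps included by default (a flag drops
them).

## Enrichment statistics

Every comparison reduces to a 2 × 2 carrier table: `a` of `n₁` target
sequences and `c` of `n₂` comparator sequences carry the feature. With
0.1 added to each of the four cells (carriers and non-carriers in both
cohorts — hence +0.2 on each total), the default statistic is the ratio
of corrected carrier proportions,

    ratio = [(a + 0.1)/(n₁ + 0.2)] / [(c + 0.1)/(n₂ + 0.2)].

This functional form, not the textbook cross-product odds ratio, is
what reproduces the enrichment values reported in this field's carrier
tables (which conventionally label them "OR"); the cross-product form
is available via `ratio_form="odds_ratio"`. The correction makes
zero-cell tables finite, and the statistic converges to the uncorrected
ratio as the correction shrinks with all cells positive. Swapping the
cohorts inverts the proportion-ratio exactly.

Inference is a normal approximation on the log ratio. The standard
error defaults to the log ratio-of-proportions form
√(1/a′ − 1/n₁′ + 1/c′ − 1/n₂′) on corrected cells, with the classic
Woolf log-odds SE as an option; the source values this package
reproduces pin down the ratio's functional form but not the SE's, so
p-values and intervals should be read as approximate while ratios are
exact. Confidence intervals use the exact normal quantile
(1.959964 at 95 %); p-values are two-sided throughout. Significance
labels are annotations, never filters — all results are emitted.

Multiple testing uses the Benjamini–Hochberg step-up within a family.
For position scans the family is the set of positions for one
(gene × comparison) that survive exclusion; for pattern tables it is
the table. Two exclusion rules precede FDR in a scan:

1. **Germline gap**: positions where the germline residue is a gap are
   flagged not-plotted (their "carriers" are dominated by ordinary
   sequence-length variation).
2. **Germline-only artifact**: a position with ratio > 1 where *every*
   target sequence carries exactly the germline residue owes its
   positive ratio solely to the germline residue being uncommon in a
   much larger comparator — a sample-size artifact, not enrichment —
   and is excluded with a recorded reason.

`UncommonPositionScan` packages the scan as a model object: constructed
from a target set, a comparator (another set, or a consensus matrix
with its n when the cohort is too large to keep as sequences — counts
reconstructed from the matrix are exact because the matrix stores
integer counts), the rarity reference, and the germline; `fit()`
returns a results object carrying per-position tables, ratios,
intervals, p/q values and exclusion flags, with `summary()` and
`to_tsv()`.

## Residue-change patterns

Published amyloidogenic changes are written as a small grammar:
`X37D` (gain of D from any other germline residue), `ST20X` (loss of a
germline S/T to any other residue), `K56DE` (exact change of germline K
to D or E), `R25G` (exact single change), `P115PP` (CDR3 proline
insertion) and `ANY52` (any uncommon residue at 52, delegated to the
rarity classifier). Gain and loss patterns span all germline genes
where the change is possible — genes already carrying a gained residue,
or lacking the lost one, are excluded from both numerator and
denominator, judged on each gene's reference allele (*01 by default).
Denominators are therefore derived from eligibility, never hard-coded.
Gap semantics: an observed gap counts as a loss (a deletion is "any
residue other than the specified one"; switchable) but never as a gain.

The proline-insertion call requires (i) occupancy of at least one
germline-gap slot in the CDR3 insertion window 110–113 and (ii) two
consecutive *occupied* slots in the anchor window 113–117 both carrying
proline — adjacency skips gap slots because IMGT insertion slots need
not be physically adjacent on the scaffold. Both windows are
configurable.

The packaged fixture `data/published_changes.tsv` carries the published
carrier counts and printed enrichment ratios of 48 residue-change rows;
the regression suite verifies that the corrected-proportion ratio
reproduces every printed value at its printed precision.

## Synthetic repertoires

The generator emulates what the analysis assumes about real cohorts: a
germline backbone per gene (synthetic sequences with the canonical gap
structure — unoccupied slots at 58–64 and CDR3 110–113 — not copies of
real alleles), independent per-position residue changes, and optional
allele polymorphism and planted effects.

Defaults, with rationale:

- **Mean residue changes per sequence: 10**, spread uniformly over the
  germline's occupied positions (a typical somatically mutated LC
  carries roughly 5–15 changes; 10 is the midpoint). Hotspot positions
  can be up-weighted; the profile is rescaled so the expected total
  stays at the target, and any per-position rate above 1 is a
  configuration error.
- **Substitution model**: a change replaces the germline residue with
  one of the 19 other amino acids uniformly, or a gap with probability
  0.02. Real somatic hypermutation has strong gene- and
  motif-specific substitution spectra; modelling them is out of scope,
  so passing simulation tests demonstrates the statistics' calibration
  under exchangeable noise, not under realistic hypermutation bias.
- **Planted effects** act on carrier prevalence, matching the
  carrier-count statistics the scan measures: at a planted position,
  sequences of affected cohorts carry the effect residue with
  probability min(1, multiplier × base rate) where the base rate is the
  position's neutral mutation rate, and non-carriers keep the germline
  residue there. A multiplier of 1 therefore reproduces the neutral
  carrier prevalence exactly (null equivalence), and the planted
  multiplier is directly the expected carrier-rate ratio against an
  unaffected cohort (until the cap binds).
- **Allele polymorphism** adds alleles differing from the reference at
  one position, drawn per sequence with configured frequencies and
  propagated to the sequence's allele label.
- **Randomness**: named substreams keyed on (seed, stream id, cohort
  checksum), with fixed-size draw blocks per sequence index, so
  enlarging a cohort never reshuffles earlier sequences, identical
  configs are byte-identical, and different cohorts of one study are
  independent under one seed.

`end_to_end_recovery` closes the loop: simulate target and reference
cohorts, build the reference consensus, scan, and report per planted
position the ratio estimate, q-value and detection flag, plus the
false-call rate over non-planted positions.

## Calibration study sizes

The replicated simulation tests use a target cohort of 200 against a
reference of 20,000 (10,000 for the effect-ordering study) — sizes
representative of a modestly sampled disease cohort against a deep
repertoire survey, and small enough for 100–200 replicates to run as an
ordinary test suite. At these sizes the null false-call fraction stays
at or below the 5 % FDR target and a 10× planted carrier-rate excess is
detected in ≥ 95 % of replicates.

## Numerical choices and degenerate inputs

- Consensus rows are validated to sum exactly to n (integer counts);
  fraction row sums are exact to 1e-9.
- Gini of an all-zero vector is defined as 0.
- Correlation returns NaN (undefined), never a fabricated value, at
  zero-variance positions.
- Empty sequence sets cannot build matrices; fewer than two matrices
  cannot cluster; one allele has no differing positions (empty list).
- Logo and argmax tie-breaks always resolve toward the lowest alphabet
  index.
- Rejections of input records are data (id + reason), not exceptions;
  malformed files (unreadable, empty, bad headers, inconsistent counts)
  raise.

## Known limitations

- The package consumes pre-numbered sequences; numbering/alignment
  errors upstream (misplaced CDR3 gaps in particular) propagate into
  insertion calls and carrier counts.
- The Wald SE form is a documented choice among close alternatives;
  intervals and p-values near zero cells are approximate.
- The synthetic generator's exchangeable substitution model understates
  the position- and residue-correlation structure of real repertoires;
  calibration results transfer to real data only to the extent that the
  carrier counts, not the residue identities, drive the statistics.
- Dendrograms carry no bootstrap support; nucleotide sequences,
  constant domains and heavy-chain pairing are out of scope.
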