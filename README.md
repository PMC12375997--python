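# lcconsensus

Consensus-matrix analysis of immunoglobulin light-chain (LC) repertoires,
for researchers studying AL amyloidosis — the disease in which a
monoclonal antibody light chain misfolds and deposits as amyloid fibrils.

In AL amyloidosis no single "amyloid mutation" exists: each patient's LC
carries its own handful of somatic residue changes. A useful way to ask
which changes matter is to compare each monoclonal LC against the healthy
polyclonal repertoire *for the same germline V gene*. This package
implements that comparison on the fixed 127-position IMGT numbering
scaffold:

- **Consensus matrices** — for a set of aligned LCs from one germline
  gene and one cohort (AL, multiple-myeloma comparator, or polyclonal
  repertoire), a 127 × 21 matrix of the count and fraction of sequences
  carrying each residue (20 amino acids + gap) at each position.
- **Uncommon residues** — a residue is *common* at a position if it
  appears in ≥ 10 % of the polyclonal reference for that gene,
  *uncommon* below 10 %, and *rare* below 1 %. Per-sequence **frequency
  profiles** report the reference frequency of every residue of a query
  LC, flagging candidates for biophysical follow-up.
- **Enrichment statistics** — for any residue feature (a published
  residue change such as `X86N` or `R25G`, or *any uncommon residue at
  position p*), a 2 × 2 carrier table `a/n₁` vs `c/n₂` is summarised by
  the corrected-proportion ratio

  ```
  ratio = [(a + 0.1) / (n₁ + 0.2)] / [(c + 0.1) / (n₂ + 0.2)]
  ```

  (0.1 added to every cell to avoid division by zero), with a normal
  (Wald) interval and p-value on the log ratio and Benjamini–Hochberg
  FDR control across positions. Positions with a positive ratio where
  the target cohort is germline-only are excluded as sample-size
  artifacts.
- **Matrix comparison** — difference matrices, per-position Gini
  diversity (sample-corrected, so a point mass scores exactly 1),
  position-wise Pearson ρ of residue distributions, Euclidean
  (Frobenius) distances, and hierarchical clustering with newick export.
- **Synthetic repertoires** — a seeded generator of germline-derived
  cohorts with position-biased residue changes (default mean 10 per
  sequence), allele polymorphism, and planted enrichment effects with
  recorded truth, used to measure false-call rates and detection power.

## Worked example

Carriers of glycine at IMGT position 25 among IGLV6-57 light chains:
33 of 137 in the AL cohort versus 5,958 of 90,110 in the polyclonal
reference.

```python
import lcconsensus as lc

table = lc.CarrierTable(a=33, n1=137, c=5958, n2=90110)
print(round(lc.corrected_ratio(table), 3))   # 3.649
log_se, lo, hi, p = lc.wald_test(table)       # CI (2.71, 4.91), p ~ 1e-17
```

G25 carriers are ~3.6× over-represented in the AL cohort, and the 95 %
interval excludes 1.

An end-to-end run on synthetic data with a known planted effect:

```python
from dataclasses import replace

germ = lc.make_synthetic_germline("IGSYN1-1", seed=1)
effect = lc.PlantedEffect(position=52, residues=("W",),
                          multiplier=10.0, cohorts=("AL",))
cfg = lc.SimulationConfig(germline=germ, cohort="AL",
                          n_sequences=200, seed=1,
                          planted_effects=(effect,))
al, _ = lc.simulate_repertoire(cfg)
oas, _ = lc.simulate_repertoire(replace(cfg, cohort="OAS", n_sequences=20000))
ref = lc.build_consensus(oas)
scan = lc.UncommonPositionScan(al, ref, ref, germ).fit()
print(scan.enriched_positions())   # [52, 67]
row = scan.at(52)
print(row.table.a, row.ratio, row.q)  # 172  9.73  0.0
```

The planted position 52 is recovered with a ratio estimate (9.73, CI
9.06–10.46) close to the planted 10× excess; position 67 in this single
run is a chance false call — the test suite's replicated simulations
show the average false-call fraction stays at or below the 5 % FDR
target. `scan.summary()` prints the full per-position table;
`scan.to_tsv(path)` writes it.

A `lcconsensus` console script chains the same stages from the shell
(`build-matrix`, `profile`, `scan`, `patterns`, `cluster`, `simulate`,
`recover`); see `lcconsensus --help`.

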