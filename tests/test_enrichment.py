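"""Carrier-table statistics: corrected ratios, Wald inference, FDR, scans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lcconsensus as lc
from lcconsensus.enrichment import counts_from_consensus, enrichment_result

from conftest import make_chain, mutated_copy


class TestCorrectedRatio:
    @pytest.mark.parametrize(
        "table,printed,digits",
        [
            ((33, 137, 5958, 90110), 3.65, 2),   # G25 carriers, AL vs polyclonal
            ((0, 32, 0, 19), 0.6, 1),            # double-zero numerator
            ((3, 68, 0, 132), 60.0, 0),          # zero comparator cell
            ((7, 23, 0, 5), 16.0, 0),            # zero, small n
            ((1, 192, 31514, 4295181), 0.78, 2),
        ],
    )
    def test_reproduces_printed_ratios(self, table, printed, digits):
        ratio = lc.corrected_ratio(lc.CarrierTable(*table))
        assert round(ratio, digits) == printed

    def test_equal_proportions_give_unity(self):
        for correction in (0.0, 0.1, 1.0):
            config = lc.EnrichmentConfig(correction=correction)
            assert lc.corrected_ratio(
                lc.CarrierTable(10, 100, 10, 100), config
            ) == pytest.approx(1.0)

    @given(
        st.integers(0, 50), st.integers(1, 50),
        st.integers(0, 5000), st.integers(1, 5000),
    )
    def test_cohort_swap_reciprocity(self, a, n1e, c, n2e):
        table = lc.CarrierTable(a, a + n1e, c, c + n2e)
        fwd = lc.corrected_ratio(table)
        rev = lc.corrected_ratio(table.swapped())
        assert fwd * rev == pytest.approx(1.0)

    def test_correction_vanishes_for_positive_cells(self):
        table = lc.CarrierTable(12, 100, 30, 400)
        uncorrected = (12 / 100) / (30 / 400)
        errors = [
            abs(
                lc.corrected_ratio(table, lc.EnrichmentConfig(correction=d))
                - uncorrected
            )
            for d in (0.1, 0.01, 0.001, 1e-6)
        ]
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] == pytest.approx(0.0, abs=1e-6)

    def test_odds_ratio_form(self):
        table = lc.CarrierTable(10, 100, 20, 400)
        config = lc.EnrichmentConfig(ratio_form="odds_ratio", correction=0.0)
        assert lc.corrected_ratio(table, config) == pytest.approx(
            (10 * 380) / (90 * 20)
        )

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            lc.CarrierTable(5, 4, 0, 10)
        with pytest.raises(ValueError):
            lc.CarrierTable(-1, 4, 0, 10)


class TestWald:
    def test_equal_proportions_give_p_one(self):
        log_se, ci_low, ci_high, p = lc.wald_test(lc.CarrierTable(10, 100, 10, 100))
        assert p == pytest.approx(1.0)

    @given(
        st.integers(0, 30), st.integers(1, 30),
        st.integers(0, 1000), st.integers(1, 1000),
    )
    def test_ci_brackets_ratio(self, a, n1e, c, n2e):
        table = lc.CarrierTable(a, a + n1e, c, c + n2e)
        ratio = lc.corrected_ratio(table)
        _, ci_low, ci_high, p = lc.wald_test(table)
        assert ci_low <= ratio <= ci_high
        assert 0 < p <= 1

    def test_doubling_cells_shrinks_log_se(self):
        small = lc.CarrierTable(5, 50, 20, 200)
        big = lc.CarrierTable(10, 100, 40, 400)
        assert lc.wald_test(big)[0] < lc.wald_test(small)[0]

    def test_woolf_se_option(self):
        table = lc.CarrierTable(5, 50, 20, 200)
        config = lc.EnrichmentConfig(se_form="woolf")
        a, b, c, d = 5.1, 45.1, 20.1, 180.1
        expected = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert lc.wald_test(table, config)[0] == pytest.approx(expected)


def bh_oracle(p_values):
    """Literal Benjamini-Hochberg step-up, for cross-checking."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        q[idx] = running_min
    return q


class TestFdr:
    def test_single_p_unchanged(self):
        assert lc.fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_up(self):
        q = lc.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_ps_unchanged(self):
        q = lc.fdr_adjust([0.2, 0.2, 0.2])
        assert q == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_matches_oracle_on_random_vectors(self, p_values):
        q = lc.fdr_adjust(p_values)
        assert q == pytest.approx(bh_oracle(p_values), abs=1e-12)
        assert (q >= np.asarray(p_values) - 1e-12).all()

    def test_families_adjusted_separately(self):
        p = [0.01, 0.02, 0.01, 0.02]
        fams = ["x", "x", "y", "y"]
        q = lc.fdr_adjust(p, fams)
        assert q == pytest.approx([0.02, 0.02, 0.02, 0.02])

    def test_nan_propagates_without_counting(self):
        q = lc.fdr_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m=2, not 3


class TestPositionScan:
    def test_consensus_comparator_matches_explicit_set(
        self, small_cohort, reference_cohort, reference_matrix, germline
    ):
        seq_set, _, _ = small_cohort
        via_set = lc.UncommonPositionScan(
            seq_set, reference_cohort, reference_matrix, germline
        ).fit()
        via_matrix = lc.UncommonPositionScan(
            seq_set, reference_matrix, reference_matrix, germline
        ).fit()
        assert np.allclose(
            via_set.frame["ratio"], via_matrix.frame["ratio"], equal_nan=True
        )
        assert (via_set.frame["a"] == via_matrix.frame["a"]).all()
        assert (via_set.frame["c"] == via_matrix.frame["c"]).all()

    def test_planted_excess_detected_with_plausible_ratio(self, germline):
        effect = lc.PlantedEffect(
            position=52, residues=("W",), multiplier=8.0, cohorts=("AL",)
        )
        config = lc.SimulationConfig(
            germline=germline, cohort="AL", n_sequences=300, seed=31,
            planted_effects=(effect,),
        )
        report = lc.end_to_end_recovery(config, n_reference=10000)
        (row,) = report.planted
        assert row["detected"]
        # estimate within a generous window of the planted multiplier
        assert 4 < row["ratio"] < 16

    def test_germline_gap_positions_flagged(
        self, small_cohort, reference_matrix, germline
    ):
        seq_set, _, _ = small_cohort
        scan = lc.UncommonPositionScan(
            seq_set, reference_matrix, reference_matrix, germline
        ).fit()
        res = scan.at(111)
        assert res.excluded and res.exclusion_reason == "germline gap"

    def test_summary_mentions_comparison(
        self, small_cohort, reference_matrix, germline
    ):
        seq_set, _, _ = small_cohort
        scan = lc.UncommonPositionScan(
            seq_set, reference_matrix, reference_matrix, germline
        ).fit()
        text = scan.summary()
        assert "AL vs OAS" in text and germline.gene in text

    def test_counts_from_consensus_reconstruction(
        self, reference_cohort, reference_matrix
    ):
        direct = lc.count_uncommon_carriers(reference_cohort, reference_matrix)
        from_matrix = counts_from_consensus(
            reference_matrix, lc.RarityThresholds(), reference_matrix
        )
        assert (direct.carriers == from_matrix.carriers).all()


class TestArtifactFilter:
    def build_scan(self, germline, reference, target_set, filtered=True):
        return lc.UncommonPositionScan(
            target_set, reference, reference, germline,
            apply_artifact_filter=filtered,
        ).fit()

    def make_reference_with_uncommon_germline(self, germline, position):
        """Reference cohort where the germline residue is uncommon at
        one position (most reference sequences mutated there)."""
        n = 1000
        base = np.tile(germline.codes, (n, 1))
        germ_code = germline.codes[position - 1]
        replacement = (germ_code + 1) % 20
        rng = np.random.default_rng(5)
        mutate = rng.random(n) < 0.95
        base[mutate, position - 1] = replacement
        ref_set = lc.SequenceSet(
            germline.gene, "OAS", base, [f"r{i}" for i in range(n)]
        )
        return lc.build_consensus(ref_set)

    def test_germline_only_positive_position_excluded(self, germline):
        position = 30
        reference = self.make_reference_with_uncommon_germline(germline, position)
        chains = [
            make_chain(germline.residues, id=f"s{i}", gene=germline.gene)
            for i in range(20)
        ]
        target = lc.SequenceSet.from_chains(germline.gene, "AL", chains)
        scan = self.build_scan(germline, reference, target)
        res = scan.at(position)
        assert res.ratio > 1  # all-germline target vs mostly-mutated reference
        assert res.excluded
        assert res.exclusion_reason == "germline-only artifact"

    def test_one_nongermline_carrier_escapes_filter(self, germline):
        position = 30
        reference = self.make_reference_with_uncommon_germline(germline, position)
        chains = [
            make_chain(germline.residues, id=f"s{i}", gene=germline.gene)
            for i in range(19)
        ]
        rare = next(
            r for r in lc.AMINO_ACIDS
            if reference.fraction(position, r) < 0.10
            and r != germline.residue_at(position)
        )
        chains.append(mutated_copy(germline, {position: rare}, id="carrier"))
        target = lc.SequenceSet.from_chains(germline.gene, "AL", chains)
        scan = self.build_scan(germline, reference, target)
        res = scan.at(position)
        assert not res.excluded

    def test_ratio_below_one_never_excluded_by_artifact_rule(
        self, small_cohort, reference_matrix, germline
    ):
        seq_set, _, _ = small_cohort
        scan = self.build_scan(germline, reference_matrix, seq_set)
        for res in scan.results:
            if res.exclusion_reason == "germline-only artifact":
                assert res.ratio > 1

    def test_standalone_filter_matches_builtin(
        self, germline
    ):
        position = 30
        reference = self.make_reference_with_uncommon_germline(germline, position)
        chains = [
            make_chain(germline.residues, id=f"s{i}", gene=germline.gene)
            for i in range(20)
        ]
        target = lc.SequenceSet.from_chains(germline.gene, "AL", chains)
        unfiltered = self.build_scan(germline, reference, target, filtered=False)
        assert not unfiltered.at(position).excluded
        filtered = lc.apply_artifact_filter(unfiltered, target, germline)
        builtin = self.build_scan(germline, reference, target, filtered=True)
        assert filtered.at(position).excluded
        assert [r.excluded for r in filtered.results] == [
            r.excluded for r in builtin.results
        ]


class TestAlleleOperations:
    def test_stratification_recovers_constructed_counts(self, germline):
        position = 25
        germ_r = mutated_copy(germline, {position: "R"})
        chains = []
        for i in range(33):
            chains.append(
                mutated_copy(
                    germline, {position: "G"}, id=f"g{i}", allele="*02"
                )
            )
        for i in range(99):
            chains.append(
                mutated_copy(
                    germline, {position: "R"}, id=f"r{i}", allele="*01"
                )
            )
        seq_set = lc.SequenceSet.from_chains(germline.gene, "AL", chains)
        registry = lc.GermlineRegistry()
        registry.add(germline)
        table = lc.allele_stratify(seq_set, registry, position)
        assert table.loc["*02", "G"] == 33
        assert table.loc["*01", "R"] == 99
        # marginals reconcile with the consensus counts
        consensus = lc.build_consensus(seq_set)
        for residue in table.columns:
            assert table[residue].sum() == consensus.counts[
                position - 1, lc.ALPHABET.index(residue)
            ]

    def test_missing_allele_grouped_as_unassigned(self, germline):
        chains = [
            make_chain(germline.residues, id="s0", gene=germline.gene),
        ]
        seq_set = lc.SequenceSet.from_chains(germline.gene, "AL", chains)
        registry = lc.GermlineRegistry()
        registry.add(germline)
        table = lc.allele_stratify(seq_set, registry, 25)
        assert list(table.index) == ["unassigned"]

    def test_allele_differing_positions(self, germline):
        residues = list(germline.residues)
        residues[24] = "G" if residues[24] != "G" else "A"
        allele2 = lc.GermlineAllele(
            gene=germline.gene, allele_id="*02", residues="".join(residues)
        )
        assert lc.allele_differing_positions([germline, allele2]) == [25]
        assert lc.allele_differing_positions([germline, germline]) == []
        residues3 = list(allele2.residues)
        residues3[39] = "W" if residues3[39] != "W" else "F"
        allele3 = lc.GermlineAllele(
            gene=germline.gene, allele_id="*03", residues="".join(residues3)
        )
        assert lc.allele_differing_positions(
            [germline, allele2, allele3]
        ) == [25, 40]
        assert lc.allele_differing_positions([germline]) == []
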