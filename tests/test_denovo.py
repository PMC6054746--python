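"""De novo expected counts, Poisson enrichment, trio inheritance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import poisson_upper_tail_bruteforce
from rvburden.denovo import (
    BASES,
    CODON_TABLE,
    MappableCodingSequence,
    TrinucRateTable,
    annotate_cds,
    classify_inheritance,
    expected_count,
    expected_count_table,
    poisson_enrichment,
)
from rvburden.qc import Genotype


class TestRateTable:
    def test_uniform_table_has_192_entries(self):
        t = TrinucRateTable.uniform(1e-8)
        assert len(list(t.items())) == 64 * 3
        assert t.total() == pytest.approx(192e-8)

    def test_rejects_negative_or_malformed(self):
        with pytest.raises(ValueError):
            TrinucRateTable({("A", "C", "G", "T"): -1e-9})
        with pytest.raises(ValueError):
            TrinucRateTable({("A", "C", "G", "C"): 1e-9})  # ref == alt

    def test_tsv_round_trip(self, toy_rate_table, tmp_path):
        path = tmp_path / "rates.tsv"
        toy_rate_table.to_tsv(path)
        back = TrinucRateTable.from_tsv(path)
        assert back.rate("A", "C", "G", "T") == toy_rate_table.rate("A", "C", "G", "T")
        assert back.total() == pytest.approx(toy_rate_table.total())


class TestAnnotateCds:
    def test_known_substitutions(self, toy_cds):
        # codon 2 AAA (K): AAA->TAA is a premature stopgain
        assert toy_cds.annotation[(3, "T")] == "LGD"
        # AAA->AAG stays lysine: synonymous
        assert toy_cds.annotation[(5, "G")] == "synonymous"
        # AAA->ACA is K->T missense
        assert toy_cds.annotation[(4, "C")] == "missense"

    def test_final_stop_codon_changes_are_not_lgd(self, toy_cds):
        # last codon TAA: TAA->TGA retains a stop (stop-retained counts as
        # synonymous), TAA->CAA is a stop loss ("other")
        assert toy_cds.annotation[(25, "G")] == "synonymous"
        assert toy_cds.annotation[(24, "C")] == "other"

    def test_every_substitution_annotated(self, toy_cds):
        assert len(toy_cds.annotation) == 3 * len(toy_cds.sequence)

    def test_non_triplet_length_rejected(self):
        with pytest.raises(ValueError):
            annotate_cds("X", "ATGA")


class TestExpectedCount:
    def test_uniform_closed_form(self):
        """Uniform rate r over L fully annotated positions: m0 = 2*n*3*L*r."""
        r, n_trios = 2e-8, 60
        seq = annotate_cds("G", "ATGAAATGCGGATTTCACCCGTGGTAA", flank5="C", flank3="G")
        L = len(seq.sequence)
        m0 = expected_count(TrinucRateTable.uniform(r), seq, n_trios, "all")
        assert m0 == pytest.approx(2 * n_trios * 3 * L * r)

    def test_class_partition(self, toy_rate_table, toy_cds):
        parts = expected_count_table(toy_rate_table, [toy_cds], 60).set_index("variant_class")["m0"]
        assert parts[["synonymous", "missense", "LGD", "other"]].sum() == pytest.approx(parts["all"])

    def test_matches_exhaustive_hand_enumeration(self, toy_rate_table, toy_cds):
        """Brute-force oracle: loop all positions x alts, translate codons."""
        n_trios = 10
        seq = toy_cds.sequence
        by_class = {"synonymous": 0.0, "missense": 0.0, "LGD": 0.0, "other": 0.0}
        flanked = "C" + seq + "G"
        n_codons = len(seq) // 3
        for pos in range(len(seq)):
            five, ref, three = flanked[pos], seq[pos], flanked[pos + 2]
            ci = pos // 3
            codon = seq[3 * ci : 3 * ci + 3]
            for alt in BASES:
                if alt == ref:
                    continue
                mutant = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
                aa, new_aa = CODON_TABLE[codon], CODON_TABLE[mutant]
                if new_aa == aa:
                    cls = "synonymous"
                elif new_aa == "*":
                    cls = "LGD" if ci < n_codons - 1 else "other"
                elif aa == "*":
                    cls = "other"
                else:
                    cls = "missense"
                by_class[cls] += toy_rate_table.rate(five, ref, three, alt)
        for cls, total in by_class.items():
            assert expected_count(toy_rate_table, toy_cds, n_trios, cls) == pytest.approx(
                2 * n_trios * total
            )

    def test_linearity_in_trios_and_additivity_over_blocks(self, toy_rate_table, toy_cds):
        m0_10 = expected_count(toy_rate_table, toy_cds, 10)
        m0_30 = expected_count(toy_rate_table, toy_cds, 30)
        assert m0_30 == pytest.approx(3 * m0_10)
        other = annotate_cds("G2", "ATGCCCGGGTTTTAA", flank5="A", flank3="A")
        both = expected_count(toy_rate_table, [toy_cds, other], 10)
        assert both == pytest.approx(m0_10 + expected_count(toy_rate_table, other, 10))

    def test_unmappable_positions_excluded(self, toy_rate_table, toy_cds):
        mask = np.ones(len(toy_cds.sequence), dtype=bool)
        mask[:3] = False
        masked = MappableCodingSequence(
            toy_cds.gene, toy_cds.sequence, toy_cds.annotation,
            toy_cds.flank5, toy_cds.flank3, mask,
        )
        assert expected_count(toy_rate_table, masked, 10) < expected_count(
            toy_rate_table, toy_cds, 10
        )

    def test_edge_without_flank_skipped(self, toy_rate_table):
        seq = annotate_cds("G", "ATGAAATAA")  # default flanks "N": edges skipped
        full = annotate_cds("G", "ATGAAATAA", flank5="A", flank3="A")
        assert expected_count(toy_rate_table, seq, 10) < expected_count(toy_rate_table, full, 10)


class TestPoissonEnrichment:
    def test_zero_observed_gives_p_one(self):
        assert poisson_enrichment(0, 2.5).p_value == 1.0

    def test_five_vs_one_hand_summable(self):
        import math

        expected = 1 - sum(math.exp(-1) / math.factorial(k) for k in range(5))
        r = poisson_enrichment(5, 1.0)
        assert r.p_value == pytest.approx(expected)
        assert r.enrichment == pytest.approx(5.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_enrichment(3, 0.0)
        with pytest.raises(ValueError):
            poisson_enrichment(-1, 1.0)

    @given(m1=st.integers(0, 40), m0=st.floats(0.01, 20))
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, m1, m0):
        r = poisson_enrichment(m1, m0)
        assert r.p_value == pytest.approx(
            poisson_upper_tail_bruteforce(m1, m0), rel=1e-9, abs=1e-12
        )


class TestClassifyInheritance:
    def test_de_novo(self):
        call = classify_inheritance(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF)
        assert call.status == "de_novo" and not call.mendelian_violation

    def test_paternal_inheritance(self):
        call = classify_inheritance(Genotype.HET, Genotype.HOM_REF, Genotype.HET)
        assert call.status == "inherited" and call.detail == "paternal"

    def test_maternal_inheritance(self):
        call = classify_inheritance(Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_REF)
        assert call.status == "inherited" and call.detail == "maternal"

    def test_missing_father_hom_ref_mother_is_paternal_or_de_novo(self):
        call = classify_inheritance(Genotype.HET, Genotype.HOM_REF, Genotype.MISSING)
        assert call.status == "unknown"
        assert call.detail == "paternal or de novo"

    def test_missing_mother_carrier_father_is_inherited(self):
        call = classify_inheritance(Genotype.HET, Genotype.MISSING, Genotype.HET)
        assert call.status == "inherited" and call.detail == "paternal"

    def test_hom_alt_child_single_carrier_parent_flagged(self):
        call = classify_inheritance(Genotype.HOM_ALT, Genotype.HET, Genotype.HOM_REF)
        assert call.mendelian_violation

    def test_non_carrier_child(self):
        assert classify_inheritance(
            Genotype.HOM_REF, Genotype.HET, Genotype.HET
        ).status == "unknown"


class TestSimulationCalibration:
    def test_cohorts_from_rate_table_give_enrichment_near_one(self, toy_rate_table, toy_cds):
        """Trio cohorts generated from the rate table itself should show
        enrichment ~1 within 2 SE in >= 95% of seeds."""
        from rvburden.simulate import SyntheticTrioSpec, generate_trios

        # scale rates so m0 is comfortably nonzero at 60 trios
        scaled = TrinucRateTable(
            {k: v * 2e4 for k, v in toy_rate_table.items()}
        )
        m0 = expected_count(scaled, toy_cds, 60, "all")
        assert m0 > 5
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            events = generate_trios(
                SyntheticTrioSpec(n_trios=60, rate_table=scaled, cds=[toy_cds], seed=seed)
            )
            m1 = len(events)
            se = np.sqrt(m0)
            if abs(m1 - m0) <= 2 * se:
                ok += 1
        assert ok >= int(0.9 * n_seeds)

    def test_p_values_calibrated_under_null(self, toy_rate_table, toy_cds):
        from rvburden.simulate import SyntheticTrioSpec, generate_trios

        scaled = TrinucRateTable({k: v * 2e4 for k, v in toy_rate_table.items()})
        m0 = expected_count(scaled, toy_cds, 60, "all")
        pvals = []
        for seed in range(200):
            events = generate_trios(
                SyntheticTrioSpec(n_trios=60, rate_table=scaled, cds=[toy_cds], seed=seed)
            )
            pvals.append(poisson_enrichment(len(events), m0).p_value)
        pvals = np.array(pvals)
        # conservative discrete test: sub-uniform at conventional levels
        assert (pvals < 0.05).mean() <= 0.10
        assert pvals.mean() > 0.35
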