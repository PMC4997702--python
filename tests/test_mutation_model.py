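"""Spectrum enumeration, Pr(AAS|N), gene rate summaries and calibration."""

import logging

import numpy as np
import pytest
from Bio.Seq import Seq

from dnmload.io import ConservationTrack, GeneModel, MutationEvent
from dnmload.rates import (
    calibrate_rates,
    annotate_event,
    enumerate_spectrum,
    gene_rate_summary,
    null_aas_distribution,
    uniform_rate_table,
)

R0 = 1.2e-8


def make_gene(seq, gene_id="g", strand="+", start=1, chrom="c"):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_intervals=((start, start + len(seq) - 1),),
        cds_seq=seq,
        flank5="A",
        flank3="A",
    )


@pytest.fixture(scope="module")
def atg_spectrum():
    return enumerate_spectrum(make_gene("ATG"), uniform_rate_table(R0))


class TestEnumerateSpectrum:
    def test_atg_has_nine_entries(self, atg_spectrum):
        assert len(atg_spectrum.entries) == 9

    def test_atg_to_ata_is_missense_m_to_i(self, atg_spectrum):
        row = atg_spectrum.entries.query("offset == 2 and alt == 'A'").iloc[0]
        assert row["consequence"] == "missense"
        assert (row["aa_ref"], row["aa_alt"]) == ("M", "I")

    def test_uniform_table_gives_m_three_r0(self, atg_spectrum):
        assert atg_spectrum.m == pytest.approx(3 * R0)

    def test_hand_summed_rates(self, fixtures):
        """Independent context-lookup summation over a 30-bp slice."""
        gene = make_gene(fixtures.gene.cds_seq[:30])
        spec = enumerate_spectrum(gene, fixtures.rate_table)
        seq = "A" + gene.cds_seq + "A"  # flanks
        total = 0.0
        for i in range(30):
            ctx = seq[i : i + 3]
            for alt in "ACGT":
                if alt != ctx[1]:
                    total += fixtures.rate_table.rates[(ctx, alt)]
        assert spec.entries["rate"].sum() == pytest.approx(total, rel=1e-12)

    def test_exhaustive_no_duplicates(self, engine):
        ent = engine.spectrum.entries
        assert len(ent) == 3 * engine.spectrum.L
        assert not ent.duplicated(["offset", "alt"]).any()
        assert (ent["rate"] > 0).all()

    def test_strand_invariance(self, fixtures):
        """A minus-strand twin gene yields the identical spectrum."""
        seq = fixtures.gene.cds_seq[:60]
        plus = enumerate_spectrum(make_gene(seq), fixtures.rate_table)
        minus_gene = GeneModel(
            gene_id="twin",
            chrom="c",
            strand="-",
            cds_intervals=((1, 60),),
            cds_seq=seq,  # coding strand, as read_gene_models would produce
            flank5="A",
            flank3="A",
        )
        minus = enumerate_spectrum(minus_gene, fixtures.rate_table)
        cols = ["offset", "ref", "alt", "rate", "consequence", "aa_ref", "aa_alt"]
        assert plus.entries[cols].equals(minus.entries[cols])

    def test_splice_rate_from_dinucleotide_count(self, fixtures):
        gene = GeneModel(
            gene_id="g2",
            chrom="c",
            strand="+",
            cds_intervals=((1, 30), (101, 130)),
            cds_seq=fixtures.gene.cds_seq[:60],
            flank5="A",
            flank3="A",
        )
        spec = enumerate_spectrum(gene, fixtures.rate_table, splice_site_multiplier=2.0)
        assert spec.splice_rate == pytest.approx(2.0 * spec.m * 2)


class TestNullDistribution:
    def test_mass_sums_to_one(self, engine):
        assert engine.null_dist.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_marginal_matches_rate_fractions(self, atg_spectrum):
        dist = null_aas_distribution(atg_spectrum, np.array([0.0, 1.0]))
        ent = atg_spectrum.entries
        total = ent["rate"].sum()
        for csq in ("missense", "nonsense", "synonymous"):
            want = ent.loc[ent["consequence"] == csq, "rate"].sum() / total
            cats = [
                i
                for i, (c, r, a) in enumerate(
                    zip(ent["consequence"], ent["aa_ref"], ent["aa_alt"])
                )
                if c == csq
            ]
            got = dist.mass[np.unique(dist.entry_cells[cats])].sum() if cats else 0.0
            assert got == pytest.approx(want, abs=1e-12)

    def test_atg_missense_probability_by_brute_force(self, atg_spectrum):
        """Exhaustive enumeration of the 9 substitutions of codon ATG."""
        from dnmload.rates import CODON_TO_AA

        n_missense = 0
        for pos in range(3):
            for alt in "ACGT":
                if alt == "ATG"[pos]:
                    continue
                alt_codon = "ATG"[:pos] + alt + "ATG"[pos + 1 :]
                aa = CODON_TO_AA[alt_codon]
                if aa not in ("M", "*"):
                    n_missense += 1
        dist = null_aas_distribution(atg_spectrum, np.array([0.0, 1.0]))
        mis_cells = [
            dist.entry_cells[i]
            for i, c in enumerate(atg_spectrum.entries["consequence"])
            if c == "missense"
        ]
        got = dist.mass[np.unique(mis_cells)].sum()
        assert got == pytest.approx(n_missense / 9, abs=1e-12)

    def test_bad_bin_edges_rejected(self, atg_spectrum):
        with pytest.raises(ValueError):
            null_aas_distribution(atg_spectrum, np.array([0.2, 1.0]))


class TestGeneRateSummary:
    def test_uniform_arithmetic(self):
        seq = "ATG" + "AAA" * 664 + "TAA"  # 1998 bp, no internal stops
        spec = enumerate_spectrum(make_gene(seq), uniform_rate_table(1.2e-8))
        summ = gene_rate_summary(spec)
        assert summ.m == pytest.approx(3.6e-8)
        assert summ.n == 2 * 1998
        assert summ.expected_count_per_individual == pytest.approx(summ.n * summ.m)

    def test_doubling_rates_doubles_expectation(self):
        seq = "ATGAAATTTTAA"
        s1 = enumerate_spectrum(make_gene(seq), uniform_rate_table(R0))
        s2 = enumerate_spectrum(make_gene(seq), uniform_rate_table(2 * R0))
        assert gene_rate_summary(s2).m == pytest.approx(2 * gene_rate_summary(s1).m)
        assert gene_rate_summary(s2).expected_count_per_individual == pytest.approx(
            2 * gene_rate_summary(s1).expected_count_per_individual
        )


class TestCalibration:
    def _events(self, n_snv, n_indel):
        evs = [
            MutationEvent(f"s{i}", "g", "c", 5, "A", "T") for i in range(n_snv)
        ]
        evs += [
            MutationEvent(f"i{i}", "g", "c", 5, "A", "AT") for i in range(n_indel)
        ]
        return evs

    def test_observed_equals_expected(self):
        cal = calibrate_rates(self._events(100, 10), 100, 1.0, 0.1)
        assert cal.snv_scale == pytest.approx(1.0)
        assert cal.indel_scale == pytest.approx(1.0)

    def test_arithmetic(self):
        cal = calibrate_rates(self._events(150, 0), 100, 1.0, 0.0)
        assert cal.snv_scale == pytest.approx(1.5)

    def test_zero_indels_logged(self, caplog):
        with caplog.at_level(logging.WARNING):
            cal = calibrate_rates(self._events(10, 0), 10, 1.0, 0.5)
        assert cal.indel_scale == 0.0
        assert "indel" in caplog.text

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rates(self._events(1, 0), 1, 0.0)


class TestAnnotateEvent:
    def test_snv_lookup_matches_spectrum(self, fixtures, engine):
        gene, spec = fixtures.gene, engine.spectrum
        row = spec.entries.iloc[40]
        pos = gene.cds_intervals[0][0] + int(row["offset"])
        ev = MutationEvent("s", gene.gene_id, gene.chrom, pos, row["ref"], row["alt"])
        ann = annotate_event(gene, spec, ev, fixtures.cons_track)
        assert ann.consequence == row["consequence"]
        assert ann.aa_ref == row["aa_ref"] and ann.aa_alt == row["aa_alt"]
        assert ann.cons_score == pytest.approx(row["cons_score"])

    def test_deletion_is_frameshift(self, fixtures, engine):
        gene = fixtures.gene
        pos = gene.cds_intervals[0][0] + 3
        ref = gene.cds_seq[3:6]
        ev = MutationEvent("s", gene.gene_id, gene.chrom, pos, ref[:3], ref[0])
        ann = annotate_event(gene, engine.spectrum, ev, fixtures.cons_track)
        assert ann.consequence == "frameshift_indel"

    def test_ref_mismatch_rejected(self, fixtures, engine):
        gene = fixtures.gene
        pos = gene.cds_intervals[0][0]
        wrong = "A" if gene.cds_seq[0] != "A" else "C"
        ev = MutationEvent("s", gene.gene_id, gene.chrom, pos, wrong, "G" if wrong != "G" else "T")
        with pytest.raises(ValueError, match="does not match"):
            annotate_event(gene, engine.spectrum, ev, fixtures.cons_track)

    def test_outside_footprint_rejected(self, fixtures, engine):
        gene = fixtures.gene
        ev = MutationEvent("s", gene.gene_id, gene.chrom, 5, "A", "T")
        with pytest.raises(ValueError, match="outside"):
            annotate_event(gene, engine.spectrum, ev, fixtures.cons_track)
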