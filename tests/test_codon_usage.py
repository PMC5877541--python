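"""Codon extraction, start/stop classification, and RSCU arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofeatures import (
    FeatureTable,
    GeneFeature,
    classify_start,
    classify_stop,
    count_codons,
    extract_codons,
    rscu_from_counts,
    start_stop_report,
    synonymous_families,
)
from mitofeatures.codon_usage import CodonError, format_rscu
from mitofeatures.data import load_reference_codon_usage


class TestFamilies:
    def test_invertebrate_mito_code_family_sizes(self):
        fams = synonymous_families()
        sizes = {label: len(codons) for label, codons in fams.items()}
        assert sizes["S"] == 8  # UCN + AGN serine
        assert sizes["L"] == 6  # UUR + CUN leucine
        assert sizes["*"] == 2  # UAA/UAG only (UGA is Trp)
        assert sizes["M"] == 2 and sizes["W"] == 2

    def test_split_serine_switch(self):
        fams = synonymous_families(split_serine=True)
        assert len(fams["S-TCN"]) == 4 and len(fams["S-AGN"]) == 4


class TestExtractCodons:
    def _pcg(self, name, size, direction="J"):
        return GeneFeature(name=name, direction=direction, start=101,
                           end=100 + size, start_codon="ATG", stop_codon="T-")

    def test_incomplete_stop_remainder_lengths(self):
        # a 688-nt CDS leaves a single-base T fragment (the COII pattern)
        genome = "G" * 100 + "ATG" + "AAA" * 228 + "T" + "G" * 100
        codons, remainder = extract_codons(genome, self._pcg("COII", 688))
        assert len(codons) == 229 and remainder == "T"

    def test_1735nt_cds_has_578_codons(self):
        # the ND5 pattern: 1735 = 578 codons + 1
        genome = "C" * 100 + "GTG" + "AAA" * 577 + "T" + "C" * 100
        codons, remainder = extract_codons(genome, self._pcg("ND5", 1735))
        assert len(codons) == 578 and len(remainder) == 1

    def test_nine_nt_cds_has_no_remainder(self):
        genome = "G" * 100 + "ATGAAATAA" + "G" * 100
        codons, remainder = extract_codons(genome, self._pcg("ND3", 9))
        assert codons == ["ATG", "AAA", "TAA"] and remainder == ""

    def test_minus_strand_cds_is_reverse_complemented(self):
        import mitofeatures.composition as comp
        cds = "ATGAAATAA"
        genome = "G" * 100 + comp.reverse_complement(cds) + "G" * 100
        codons, _ = extract_codons(genome, self._pcg("ND1", 9, direction="N"))
        assert codons == ["ATG", "AAA", "TAA"]

    def test_too_short_cds_is_an_error(self):
        with pytest.raises(CodonError, match="short"):
            extract_codons("A" * 300, self._pcg("ATP8", 5))

    def test_non_pcg_rejected(self):
        rrna = GeneFeature(name="lrRNA", direction="N", start=1, end=100)
        with pytest.raises(CodonError):
            extract_codons("A" * 300, rrna)


class TestStartStopClasses:
    @pytest.mark.parametrize("codon,klass", [
        ("ATT", "ATN-standard"), ("ATG", "ATN-standard"), ("ATA", "ATN-standard"),
        ("GTG", "GTG-alternative"), ("TTG", "TTG-alternative"), ("CCC", "other"),
    ])
    def test_start_classes(self, codon, klass):
        assert classify_start(codon) == klass

    @pytest.mark.parametrize("codon,klass", [
        ("TAA", "TAA"), ("UAG", "TAG"), ("T", "incomplete-T"),
        ("TA", "incomplete-TA"), ("T-", "incomplete-T"), ("AAA", "other"),
    ])
    def test_stop_classes(self, codon, klass):
        assert classify_stop(codon) == klass

    def test_empty_codon_is_an_error(self):
        with pytest.raises(CodonError):
            classify_start("")

    def test_default_genome_start_stop_report(self, default_genome):
        genome, table, _ = default_genome
        report = {r.gene: r for r in start_stop_report(genome, table)}
        assert report["ND5"].start_class == "GTG-alternative"
        assert report["ND1"].start_class == "TTG-alternative"
        assert report["COII"].stop_class == "incomplete-T"
        assert report["ND5"].stop_class == "incomplete-T"
        standard = [g for g, r in report.items() if r.start_class == "ATN-standard"]
        assert len(standard) == 11


class TestCounting:
    def test_single_gene_genome_counts(self):
        genome = "ATGAAATAA"
        table = FeatureTable(features=[
            GeneFeature(name="ND2", direction="J", start=1, end=9,
                        start_codon="ATG", stop_codon="TAA"),
        ])
        usage = count_codons(genome, table)
        assert usage.records["ATG"].n_j == 1
        assert usage.records["AAA"].n_j == 1
        assert usage.records["TAA"].n_j == 1
        assert usage.records["TAA"].n_n == 0

    def test_generator_ground_truth_reproduced(self, default_genome):
        """Every codon count must equal the generator's own tally."""
        from collections import Counter

        genome, table, truth = default_genome
        usage = count_codons(genome, table)
        expected = Counter()
        expected_j = Counter()
        for gene, info in truth.codons.items():
            expected.update(info["counts"])
            if info["strand"] == "J":
                expected_j.update(info["counts"])
        for codon, record in usage.records.items():
            assert record.n == expected.get(codon, 0)
            assert record.n_j == expected_j.get(codon, 0)

    def test_published_stop_census_on_default_layout(self, default_genome):
        """Thirteen PCGs: nine UAA stops, two UAG, two incomplete."""
        genome, table, _ = default_genome
        usage = count_codons(genome, table)
        assert usage.records["TAA"].n == 9
        assert usage.records["TAG"].n == 2

    def test_ambiguous_codons_skipped_and_tallied(self):
        genome = "ATGANATAA"
        table = FeatureTable(features=[
            GeneFeature(name="ND2", direction="J", start=1, end=9,
                        start_codon="ATG", stop_codon="TAA"),
        ])
        usage = count_codons(genome, table)
        assert usage.skipped_ambiguous == 1


class TestRSCU:
    def test_published_leucine_family(self):
        counts = {"UUA": 280, "UUG": 108, "CUU": 67, "CUC": 67, "CUA": 112, "CUG": 12}
        rscu = rscu_from_counts(counts)
        assert round(rscu["TTA"], 2) == 2.60

    def test_published_eightfold_serine_family(self):
        counts = {"UCU": 94, "UCC": 30, "UCA": 63, "UCG": 15,
                  "AGU": 49, "AGC": 18, "AGA": 52, "AGG": 3}
        assert round(rscu_from_counts(counts)["TCT"], 2) == 2.32

    def test_uniform_family_is_all_ones(self):
        rscu = rscu_from_counts({"GGU": 5, "GGC": 5, "GGA": 5, "GGG": 5})
        assert all(v == pytest.approx(1.0) for c, v in rscu.items() if c.startswith("GG"))

    def test_zero_family_yields_null(self):
        rscu = rscu_from_counts({"GGU": 0, "GGC": 0, "GGA": 0, "GGG": 0})
        assert all(rscu[c] is None for c in ("GGT", "GGC", "GGA", "GGG"))

    def test_every_published_value_reproduced_at_two_decimals(self):
        """All 64 rows x 3 strand classes of the printed codon-usage table."""
        df = load_reference_codon_usage()
        for ncol, rcol in (("n", "rscu"), ("n_j", "rscu_j"), ("n_n", "rscu_n")):
            rscu = rscu_from_counts(dict(zip(df.codon, df[ncol])))
            for _, row in df.iterrows():
                value = rscu[row.codon.replace("U", "T")]
                assert value == pytest.approx(row[rcol], abs=0.005 + 1e-9), (
                    f"{row.codon} {ncol}"
                )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_family_sums_equal_family_size(self, data):
        """Sum of RSCU over any fully observed family equals its size."""
        fams = synonymous_families()
        counts = {}
        for codons in fams.values():
            for c in codons:
                counts[c] = data.draw(st.integers(min_value=1, max_value=500))
        rscu = rscu_from_counts(counts)
        for codons in fams.values():
            assert sum(rscu[c] for c in codons) == pytest.approx(len(codons), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.integers(min_value=1, max_value=100), min_size=6, max_size=6),
        k=st.integers(min_value=2, max_value=20),
    )
    def test_scale_invariance_within_a_family(self, base, k):
        leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
        r1 = rscu_from_counts(dict(zip(leu, base)))
        r2 = rscu_from_counts(dict(zip(leu, [k * n for n in base])))
        for c in leu:
            assert r1[c] == pytest.approx(r2[c], abs=1e-9)

    @pytest.mark.parametrize("value,text", [(2.6006, "2.6"), (1.0031, "1"), (0.0, "0")])
    def test_report_formatting_trims_trailing_zeros(self, value, text):
        assert format_rscu(value) == text
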