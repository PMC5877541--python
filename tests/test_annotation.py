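"""Feature-table parsing, coordinate arithmetic and gene-order comparison."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitofeatures import (
    FeatureTable,
    FeatureTableError,
    GeneFeature,
    check_bicistron_motif,
    compare_gene_order,
    genome_length,
    junction_ledger,
    parse_feature_table,
    read_genbank_features,
    summarize_junctions,
)
from mitofeatures.annotation import FeatureParseError
from mitofeatures.data import reference_feature_table_path, reference_intergenic_column
from mitofeatures.genes import ANCESTRAL_INSECT_ORDER, GeneNameError, normalize_gene_name


class TestParsing:
    def test_reference_table_parses_with_thousands_separators(self, reference_table):
        assert len(reference_table) == 38
        assert reference_table["tRNA-Ile"].size == 67
        assert reference_table["CR"].end == 16146

    def test_single_base_feature_has_size_one(self):
        f = GeneFeature(name="ND2", direction="J", start=5, end=5)
        assert f.size == 1

    @pytest.mark.parametrize(
        "name,canonical",
        [
            ("cox1", "COI"), ("CytB", "CytB"), ("12S", "srRNA"),
            ("16s", "lrRNA"), ("trnL1", "tRNA-Leu(UUR)"),
            ("tRNA-Ser(UCN)", "tRNA-Ser(UCN)"), ("D-loop", "CR"),
        ],
    )
    def test_gene_name_aliases(self, name, canonical):
        assert normalize_gene_name(name) == canonical

    def test_untagged_leucine_trna_is_rejected(self):
        with pytest.raises(GeneNameError, match="ambiguous"):
            normalize_gene_name("tRNA-Leu")

    def test_end_before_start_is_a_validation_error(self):
        with pytest.raises(FeatureTableError, match="end"):
            GeneFeature(name="ND2", direction="J", start=10, end=5)

    def test_malformed_coordinate_names_the_row(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\tdirection\tstart\tend\nND2\tF\tabc\t100\n")
        with pytest.raises(FeatureParseError, match="ND2"):
            parse_feature_table(bad)

    def test_duplicate_gene_names_rejected(self):
        features = [
            GeneFeature(name="ND2", direction="J", start=1, end=300),
            GeneFeature(name="ND2", direction="J", start=301, end=600),
        ]
        with pytest.raises(FeatureTableError, match="duplicate"):
            FeatureTable(features=features)

    def test_unsorted_table_instructs_to_sort(self):
        features = [
            GeneFeature(name="ND2", direction="J", start=500, end=900),
            GeneFeature(name="COI", direction="J", start=1, end=300),
        ]
        with pytest.raises(FeatureTableError, match="sort"):
            FeatureTable(features=features)

    def test_genbank_reader_roundtrip(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        record = SeqRecord(Seq("A" * 500), id="synthetic", name="synthetic",
                           description="synthetic test record")
        record.annotations["molecule_type"] = "DNA"
        record.features = [
            SeqFeature(FeatureLocation(0, 300, strand=1), type="CDS",
                       qualifiers={"gene": ["ND2"]}),
            SeqFeature(FeatureLocation(300, 370, strand=-1), type="tRNA",
                       qualifiers={"product": ["trnL1"]}),
            SeqFeature(FeatureLocation(370, 500), type="D-loop", qualifiers={}),
        ]
        path = tmp_path / "mini.gb"
        SeqIO.write(record, str(path), "genbank")
        table = read_genbank_features(path)
        assert [f.name for f in table.features] == ["ND2", "tRNA-Leu(UUR)", "CR"]
        assert table["ND2"].start == 1 and table["ND2"].end == 300
        assert table["tRNA-Leu(UUR)"].direction == "N"


class TestJunctionLedger:
    def test_reproduces_published_intergenic_column(self, reference_table):
        ledger = [r for r in junction_ledger(reference_table) if not r.circular]
        printed = reference_intergenic_column()[1:]
        assert [r.gap for r in ledger] == printed

    def test_published_spacer_and_overlap_summary(self, reference_table):
        summary = summarize_junctions(junction_ledger(reference_table))
        assert (summary.spacer_count, summary.spacer_total, summary.spacer_max) == (14, 76, 20)
        assert (summary.overlap_count, summary.overlap_total, summary.overlap_max) == (11, 41, 8)

    def test_spacer_attribution_note_is_flagged(self, reference_table):
        summary = summarize_junctions(junction_ledger(reference_table))
        assert any("tRNA-Ser(UCN)" in note for note in summary.notes)

    def test_circular_junction_closes_the_molecule(self, reference_table):
        wrap = junction_ledger(reference_table)[-1]
        assert wrap.circular and (wrap.upstream, wrap.downstream) == ("CR", "tRNA-Ile")
        assert wrap.gap == 0

    def test_abutting_features_have_zero_gap(self):
        table = FeatureTable(features=[
            GeneFeature(name="ND2", direction="J", start=1, end=100),
            GeneFeature(name="COI", direction="J", start=101, end=400),
        ])
        records = junction_ledger(table, include_circular=False)
        assert [r.gap for r in records] == [0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        sizes=st.lists(st.integers(min_value=50, max_value=500), min_size=2, max_size=8),
        gaps=st.lists(st.integers(min_value=0, max_value=30), min_size=8, max_size=8),
    )
    def test_length_conservation_on_gapped_tilings(self, sizes, gaps):
        """Sum of sizes plus spacers equals the implied genome length."""
        names = ["ND2", "COI", "COII", "ND3", "ND4", "ND5", "ND6", "CytB"]
        features, pos = [], 1
        for name, size in zip(names, sizes):
            features.append(GeneFeature(name=name, direction="J", start=pos, end=pos + size - 1))
            pos += size + gaps[len(features) - 1]
        table = FeatureTable(features=features)
        summary = summarize_junctions(junction_ledger(table, include_circular=False))
        assert (
            sum(f.size for f in features) + summary.spacer_total - summary.overlap_total
            == genome_length(table)
        )


class TestGeneOrder:
    def test_reference_matches_ancestral_arrangement(self, reference_table):
        cmp = compare_gene_order(reference_table)
        assert cmp.identical and not cmp.mismatches
        assert cmp.shared_junctions == 37

    def test_comparison_is_reflexive(self, reference_table):
        cmp = compare_gene_order(reference_table, reference_table.gene_order())
        assert cmp.identical

    def test_swapping_two_trnas_gives_two_mismatches(self, reference_table):
        order = list(ANCESTRAL_INSECT_ORDER)
        i, j = 0, 2  # tRNA-Ile <-> tRNA-Met
        order[i], order[j] = order[j], order[i]
        cmp = compare_gene_order(reference_table, order)
        assert not cmp.identical and len(cmp.mismatches) == 2

    def test_strand_flip_breaks_identity(self, reference_table):
        order = list(ANCESTRAL_INSECT_ORDER)
        name, strand = order[3]
        order[3] = (name, "N" if strand == "J" else "J")
        assert not compare_gene_order(reference_table, order).identical

    def test_missing_genes_are_listed_not_dropped(self):
        table = FeatureTable(features=[
            GeneFeature(name="ND2", direction="J", start=1, end=100),
        ])
        cmp = compare_gene_order(table, [("COI", "J")])
        assert cmp.missing_from_reference == ("ND2",)
        assert cmp.extra_in_reference == ("COI",)


class TestBicistron:
    def _mini(self, overlap_seq, strand="J"):
        # ATP8 1..30 and ATP6 24..60 overlap by 7 (positions 24..30)
        genome = list("A" * 60)
        genome[23:30] = overlap_seq if strand == "J" else reversed(
            [{"A": "T", "T": "A", "G": "C", "C": "G"}[c] for c in overlap_seq]
        )
        table = FeatureTable(features=[
            GeneFeature(name="ATP8", direction=strand, start=1, end=30),
            GeneFeature(name="ATP6", direction=strand, start=24, end=60),
        ])
        return "".join(genome), table

    @pytest.mark.parametrize("motif,match", [
        ("ATGATAA", True), ("ATGTTAA", True), ("ATGCCAA", False),
    ])
    def test_seven_base_overlap_motif(self, motif, match):
        genome, table = self._mini(motif)
        result = check_bicistron_motif(genome, table, ("ATP8", "ATP6"))
        assert result.motif == motif and result.matches is match

    def test_minus_strand_motif_read_in_gene_sense(self):
        genome, table = self._mini("ATGTTAA", strand="N")
        result = check_bicistron_motif(genome, table, ("ATP8", "ATP6"))
        assert result.motif == "ATGTTAA" and result.matches

    def test_non_canonical_overlap_reported_not_raised(self):
        table = FeatureTable(features=[
            GeneFeature(name="ATP8", direction="J", start=1, end=30),
            GeneFeature(name="ATP6", direction="J", start=28, end=60),
        ])
        result = check_bicistron_motif("A" * 60, table, ("ATP8", "ATP6"))
        assert not result.canonical_overlap and result.motif is None


def test_genome_length_of_empty_table_is_an_error():
    with pytest.raises(FeatureTableError):
        FeatureTable(features=[])


def test_genome_length_without_control_region():
    table = parse_feature_table(reference_feature_table_path())
    trimmed = FeatureTable(features=[f for f in table.features if f.name != "CR"])
    assert genome_length(trimmed) == 14897
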