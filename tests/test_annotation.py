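"""Annotation loading, unit derivation and spacer classification."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from selex_regmap.annotation import (
    GeneFeature,
    classify_spacer,
    derive_spacers,
    derive_units,
    load_annotation,
    read_spacer_table,
    read_unit_table,
    write_spacer_table,
    write_unit_table,
)
from selex_regmap.errors import GFFParseError, ValidationError

from conftest import make_genes

GFF_HEADER = "##gff-version 3\n##sequence-region chr 1 5000\n"


def gff_line(gid, start, end, strand, attrs=""):
    return f"chr\tsrc\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid};Name={gid}{attrs}\n"


class TestLoadAnnotation:
    def test_coordinates_become_zero_based_half_open(self):
        ann = load_annotation(io.StringIO(GFF_HEADER + gff_line("a", 1, 300, "+")))
        (g,) = ann.genes
        assert (g.start, g.end, g.strand) == (0, 300, "+")
        assert ann.genome_length == 5000

    def test_empty_annotation_is_one_genome_wide_spacer(self):
        ann = load_annotation(io.StringIO(GFF_HEADER), genome_length=5000)
        assert ann.units == []
        assert len(ann.spacers) == 1
        s = ann.spacers[0]
        assert (s.start, s.end, s.cls) == (0, 5000, None)

    def test_toy_genome_with_categories(self):
        # Two divergent pairs; categories attached from the map.
        text = GFF_HEADER + "".join(
            [
                gff_line("g1", 101, 400, "-"),
                gff_line("g2", 601, 900, "+"),
                gff_line("g3", 1101, 1400, "-"),
                gff_line("g4", 1601, 1900, "+"),
            ]
        )
        cats = {"g1": {"transporter"}, "g4": {"rRNA", "transcription_factor"}}
        ann = load_annotation(io.StringIO(text), category_map=cats)
        assert [g.id for g in ann.genes] == ["g1", "g2", "g3", "g4"]
        assert ann.genes_by_id["g1"].categories == frozenset({"transporter"})
        assert ann.genes_by_id["g4"].categories == frozenset(
            {"rRNA", "transcription_factor"}
        )
        assert ann.genes_by_id["g2"].categories == frozenset()
        # divergent / convergent / divergent spacer sequence
        assert [s.cls for s in ann.spacers if s.cls] == ["A", "C", "A"]

    def test_malformed_line_reports_line_number(self):
        text = GFF_HEADER + gff_line("a", 1, 300, "+") + "chr\tonly\tthree\n"
        with pytest.raises(GFFParseError, match="line 4"):
            load_annotation(io.StringIO(text))

    def test_non_integer_coordinates_rejected(self):
        bad = "chr\tsrc\tgene\tx\t300\t.\t+\t.\tID=a\n"
        with pytest.raises(GFFParseError, match="line 3"):
            load_annotation(io.StringIO(GFF_HEADER + bad))

    def test_duplicate_gene_id_rejected(self):
        text = GFF_HEADER + gff_line("a", 1, 300, "+") + gff_line("a", 401, 700, "+")
        with pytest.raises(ValidationError):
            load_annotation(io.StringIO(text))

    def test_operon_attribute_groups_genes(self):
        text = GFF_HEADER + "".join(
            [
                gff_line("a", 1, 300, "+", ";operon=op1"),
                gff_line("b", 401, 700, "+", ";operon=op1"),
                gff_line("c", 1001, 1300, "-"),
            ]
        )
        ann = load_annotation(io.StringIO(text))
        assert {u.unit_id: u.gene_ids for u in ann.units} == {
            "op1": ("a", "b"),
            "c": ("c",),
        }


class TestDeriveUnits:
    @pytest.mark.parametrize(
        "strands,gap,threshold,expected_units",
        [
            (["+", "+"], 10, 50, 1),
            (["+", "+"], 200, 50, 2),
            (["+", "-"], 10, 50, 2),  # strand switch always splits
        ],
    )
    def test_gap_rule(self, strands, gap, threshold, expected_units):
        genes = make_genes(strands, gap=gap)
        units = derive_units(genes, max_intra_operon_gap=threshold)
        assert len(units) == expected_units
        assert all(g.unit_id is not None for g in genes)

    def test_mixed_strand_triple_merges_same_strand_run(self):
        genes = make_genes(["+", "+", "-"], gap=20)
        units = derive_units(genes, max_intra_operon_gap=50)
        assert [u.gene_ids for u in units] == [("g1", "g2"), ("g3",)]

    def test_operon_map_is_verbatim(self):
        genes = make_genes(["+", "+"], gap=10)  # gap rule would merge these
        units = derive_units(genes, operon_map={"g1": "opA", "g2": "opB"})
        assert [u.unit_id for u in units] == ["opA", "opB"]

    def test_operon_map_unknown_gene_rejected(self):
        with pytest.raises(ValidationError, match="unknown gene"):
            derive_units(make_genes(["+"]), operon_map={"nope": "op1"})

    def test_operon_spanning_both_strands_rejected(self):
        genes = make_genes(["+", "-"], gap=10)
        with pytest.raises(ValidationError, match="both strands"):
            derive_units(genes, operon_map={"g1": "op1", "g2": "op1"})


class TestClassifySpacer:
    def test_truth_table_exhaustive(self):
        table = {
            ("-", "+"): "A",
            ("+", "+"): "B",
            ("-", "-"): "B",
            ("+", "-"): "C",
        }
        for pair, expected in table.items():
            assert classify_spacer(*pair) == expected
        classes = [classify_spacer(*p) for p in table]
        assert sorted(classes) == ["A", "B", "B", "C"]

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValidationError):
            classify_spacer("+", ".")


class TestDeriveSpacers:
    def test_single_unit_linear_genome_has_two_unclassifiable_flanks(self):
        units = derive_units(make_genes(["+"]))
        spacers = derive_spacers(units, 1000, circular=False)
        assert [s.cls for s in spacers] == [None, None]
        assert spacers[0].left_unit is None and spacers[-1].right_unit is None

    def test_divergent_pair_gives_one_class_a_spacer(self):
        units = derive_units(make_genes(["-", "+"]))
        spacers = derive_spacers(units, 2000, circular=False)
        internal = [s for s in spacers if s.cls]
        assert len(internal) == 1 and internal[0].cls == "A"

    def test_circular_alternating_units_match_pairwise_scan(self):
        strands = ["+", "-", "+", "-", "+", "-"]
        genes = make_genes(strands)
        units = derive_units(genes)
        spacers = derive_spacers(units, genes[-1].end + 100, circular=True)
        # brute-force oracle: classify every adjacent pair, wrapping around
        expected = [
            classify_spacer(strands[i], strands[(i + 1) % len(strands)])
            for i in range(len(strands))
        ]
        assert [s.cls for s in spacers] == expected
        assert spacers[-1].wraps

    def test_zero_length_spacer_retained(self):
        genes = make_genes(["+", "-"], gap=0)
        units = derive_units(genes)
        spacers = derive_spacers(units, 2000, circular=False)
        internal = [s for s in spacers if s.cls]
        assert len(internal) == 1 and len(internal[0]) == 0

    def test_overlapping_units_rejected_naming_pair(self):
        g1 = GeneFeature("a", "a", 0, 500, "+")
        g2 = GeneFeature("b", "b", 400, 900, "-")
        units = derive_units([g1], max_intra_operon_gap=0) + derive_units(
            [g2], max_intra_operon_gap=0
        )
        with pytest.raises(ValidationError, match="overlap"):
            derive_spacers(units, 2000, circular=False)

    @given(
        strands=st.lists(st.sampled_from("+-"), min_size=2, max_size=12),
        circular=st.booleans(),
    )
    def test_internal_spacer_count_matches_adjacent_pairs(self, strands, circular):
        genes = make_genes(strands)
        units = derive_units(genes)
        spacers = derive_spacers(units, genes[-1].end + 100, circular)
        internal = [s for s in spacers if s.cls]
        assert len(internal) == (len(units) if circular else len(units) - 1)


def test_unit_and_spacer_tables_round_trip(tmp_path):
    genes = make_genes(["-", "+", "+", "-"])
    units = derive_units(genes)
    spacers = derive_spacers(units, genes[-1].end + 100, circular=False)
    write_unit_table(units, tmp_path / "units.tsv")
    write_spacer_table(spacers, tmp_path / "spacers.tsv")
    assert read_unit_table(tmp_path / "units.tsv") == units
    assert read_spacer_table(tmp_path / "spacers.tsv") == list(spacers)
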