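"""Site location, target counting, coverage summaries and the TF network."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from selex_regmap.chip_signal import Peak
from selex_regmap.errors import ValidationError
from selex_regmap.target_prediction import (
    CategoryRow,
    OverlapStat,
    TargetCount,
    build_tf_network,
    count_targets,
    fold_expansion,
    locate_site,
    locate_sites,
    regulon_overlap,
    sites_table,
    summarize_categories,
)

from conftest import make_annotation


def peak_at(summit, pid="peak0001"):
    return Peak(pid, summit - 30, summit + 30, summit, 12.0, 1)


class TestLocateSite:
    def test_summit_inside_gene_is_orf_internal(self, divergent_pair):
        g = divergent_pair.genes[0]
        site = locate_site(peak_at(g.midpoint), divergent_pair)
        assert (site.location, site.host, site.candidate_targets) == ("ORF", g.id, ())

    def test_divergent_spacer_targets_both_flanking_units(self, divergent_pair):
        s = [sp for sp in divergent_pair.spacers if sp.cls == "A"][0]
        site = locate_site(peak_at((s.start + s.end) // 2), divergent_pair)
        assert site.location == "A"
        assert set(site.candidate_targets) == {s.left_unit, s.right_unit}

    @pytest.mark.parametrize(
        "strands,target_gene",
        [(["+", "+"], "g2"), (["-", "-"], "g1")],
    )
    def test_tandem_spacer_targets_downstream_unit(self, strands, target_gene):
        ann = make_annotation(strands)
        s = [sp for sp in ann.spacers if sp.cls == "B"][0]
        site = locate_site(peak_at((s.start + s.end) // 2), ann)
        assert site.location == "B"
        assert site.candidate_targets == (ann.genes_by_id[target_gene].unit_id,)

    def test_convergent_spacer_has_no_targets(self):
        ann = make_annotation(["+", "-"])
        s = [sp for sp in ann.spacers if sp.cls == "C"][0]
        site = locate_site(peak_at((s.start + s.end) // 2), ann)
        assert (site.location, site.candidate_targets) == ("C", ())

    def test_summit_on_gene_first_base_is_orf_internal(self, divergent_pair):
        # half-open convention: the first base belongs to the gene,
        # the base before it to the spacer
        g = divergent_pair.genes[1]
        assert locate_site(peak_at(g.start), divergent_pair).location == "ORF"
        assert locate_site(peak_at(g.start - 1), divergent_pair).location == "A"
        assert locate_site(peak_at(g.end - 1), divergent_pair).location == "ORF"
        assert locate_site(peak_at(g.end), divergent_pair).location == "edge"

    def test_terminal_flank_summit_is_edge_and_uncounted(self, divergent_pair):
        site = locate_site(peak_at(10), divergent_pair)
        assert site.location == "edge"
        assert count_targets([site]).total_sites == 0

    def test_summit_outside_genome_rejected(self, divergent_pair):
        with pytest.raises(ValidationError, match="outside genome"):
            locate_site(peak_at(divergent_pair.genome_length + 50), divergent_pair)

    def test_agrees_with_brute_force_scan(self):
        # linear scan over genes then spacers, on a mixed toy genome
        ann = make_annotation(["-", "+", "+", "-", "-", "+"])
        for pos in range(0, ann.genome_length, 37):
            site = locate_site(peak_at(pos), ann)
            hit_gene = next(
                (g for g in ann.genes if g.start <= pos < g.end), None
            )
            if hit_gene is not None:
                assert site.location == "ORF" and site.host == hit_gene.id
            else:
                hit_spacer = next(
                    s for s in ann.spacers if s.start <= pos < s.end
                )
                assert site.host == hit_spacer.spacer_id
                assert site.location == (hit_spacer.cls or "edge")


class TestCountTargets:
    def test_published_composition_brackets_the_regulon(self):
        tc = TargetCount(n_A=78, n_B=140, n_C=10, n_ORF=86)
        assert tc.total_sites == 314
        assert tc.spacer_sites == 228
        assert (tc.min_targets, tc.max_targets) == (218, 296)

    def test_zero_and_small_compositions(self):
        assert (TargetCount(0, 0, 0, 0).min_targets, TargetCount(0, 0, 0, 0).max_targets) == (0, 0)
        tc = TargetCount(5, 3, 2, 1)
        # brute force: min counts one unit per A+B site, max two per A site
        assert (tc.min_targets, tc.max_targets) == (5 + 3, 2 * 5 + 3)

    @given(
        st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500), st.integers(0, 500),
    )
    def test_bracket_width_equals_divergent_sites(self, a, b, c, orf):
        tc = TargetCount(a, b, c, orf)
        assert tc.max_targets - tc.min_targets == tc.n_A
        assert tc.total_sites == a + b + c + orf


class TestCoverageArithmetic:
    @pytest.mark.parametrize(
        "whole,identified,expected",
        [(43, 35, 81), (128, 114, 89), (85, 17, 20), (24, 6, 25), (21, 9, 43)],
    )
    def test_category_percent_round_half_up(self, whole, identified, expected):
        assert CategoryRow("x", whole, identified).percent == expected

    def test_overlap_percent(self):
        assert OverlapStat("chip", 130, 87).percent == 67
        assert OverlapStat("db", 10, 10).percent == 100
        assert OverlapStat("db", 10, 0).percent == 0

    def test_fold_expansion_one_decimal(self):
        assert fold_expansion(296, 130) == 2.3

    def test_summarize_categories_counts_distinct_tagged_genes(self):
        ann = make_annotation(
            ["-", "+", "+", "+"],
            categories={
                "g1": {"transporter"},
                "g2": {"transporter"},
                "g3": {"aa_metabolism"},
            },
        )
        # sites: divergent spacer (targets g1+g2) and tandem spacer (targets g3)
        spacers = [s for s in ann.spacers if s.cls]
        sites = locate_sites(
            [peak_at((s.start + s.end) // 2, f"p{i}") for i, s in enumerate(spacers[:2])],
            ann,
        )
        rows = summarize_categories(
            sites, ann, {"transporter": 2, "aa_metabolism": 4, "rRNA": 7}
        )
        by_cat = {r.category: r for r in rows}
        assert (by_cat["transporter"].identified, by_cat["transporter"].percent) == (2, 100)
        assert (by_cat["aa_metabolism"].identified, by_cat["aa_metabolism"].percent) == (1, 25)
        assert (by_cat["rRNA"].identified, by_cat["rRNA"].percent) == (0, 0)

    def test_zero_whole_set_rejected(self, divergent_pair):
        with pytest.raises(ValidationError, match="whole-set"):
            summarize_categories([], divergent_pair, {"rRNA": 0})

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            regulon_overlap({"a"}, [], "chip")

    def test_regulon_overlap_counts_intersection(self):
        stat = regulon_overlap({"a", "b", "c"}, ["b", "c", "d", "e"], "chip")
        assert (stat.reference_size, stat.overlap, stat.percent) == (4, 2, 50)


class TestTfNetwork:
    def test_no_tf_targets_gives_empty_edge_list(self, divergent_pair):
        divergent_pair.genes[0].categories = frozenset({"transcription_factor"})
        divergent_pair.genes_by_id["g1"].categories = frozenset(
            {"transcription_factor"}
        )
        assert build_tf_network([], divergent_pair, regulator="g1") == []

    def test_self_regulation_yields_self_loop(self):
        ann = make_annotation(
            ["-", "+"], categories={"g1": {"transcription_factor"}}
        )
        s = [sp for sp in ann.spacers if sp.cls == "A"][0]
        sites = locate_sites([peak_at((s.start + s.end) // 2)], ann)
        edges = build_tf_network(sites, ann, regulator="g1")
        assert ("g1", "g1") in edges

    def test_edges_deduplicated_across_supporting_sites(self):
        ann = make_annotation(
            ["-", "+", "+", "+"],
            categories={g: {"transcription_factor"} for g in ("g1", "g2", "g3", "g4")},
        )
        spacers = [s for s in ann.spacers if s.cls]
        sites = locate_sites(
            [peak_at((s.start + s.end) // 2, f"p{i}") for i, s in enumerate(spacers)],
            ann,
        )
        edges = build_tf_network(sites, ann, regulator="g1")
        # oracle: dedup over site -> gene pairs
        expected = sorted(
            {
                ("g1", gid)
                for site in sites
                for uid in site.candidate_targets
                for gid in ann.units_by_id[uid].gene_ids
            }
        )
        assert edges == expected

    def test_unknown_regulator_rejected(self, divergent_pair):
        with pytest.raises(ValidationError, match="regulator"):
            build_tf_network([], divergent_pair, regulator="ghost")


def test_partition_every_peak_gets_exactly_one_location(divergent_pair):
    peaks = [peak_at(p, f"pk{p}") for p in range(150, divergent_pair.genome_length - 150, 73)]
    sites = locate_sites(peaks, divergent_pair)
    assert len(sites) == len(peaks)
    tc = count_targets(sites)
    n_edge = sum(1 for s in sites if s.location == "edge")
    assert tc.total_sites + n_edge == len(peaks)


def test_sites_table_is_deterministic(divergent_pair):
    peaks = [peak_at(200), peak_at(500, "peak0002")]
    t1 = sites_table(locate_sites(peaks, divergent_pair)).to_csv(sep="\t")
    t2 = sites_table(locate_sites(peaks, divergent_pair)).to_csv(sep="\t")
    assert t1 == t2
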