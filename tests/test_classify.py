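import json

import pytest

from taxoplace.classify import (
    Placement,
    align_query,
    assign_from_placement,
    combine_placements,
    filter_placements,
    place_query,
    qc_coverage,
    read_jplace,
    write_jplace,
    QueryAlignment,
)
from taxoplace.nodelabels import propagate
from taxoplace.refprep import RegionSlice
from taxoplace.taxonomy import EMPTY, Lineage, RANKS, TaxonomyTable
from taxoplace.thresholds import ThresholdSet
from taxoplace.tree import RegionTree


@pytest.fixture()
def toy_reference():
    # 20-column toy region alignment with distinctive sequences
    seqs = {
        "t1": "ACGTACGTACGTACGTACGT",
        "t2": "ACGTACGTACGTACGTACGA",
        "t3": "TTTTGGGGCCCCAAAATTTT",
        "t4": "TTGTGGGGCCCCAAAATTTA",
    }
    return RegionSlice(0, 20, seqs)


class TestAlignQuery:
    def test_identical_query_full_coverage(self, toy_reference):
        qa = align_query("q", "ACGTACGTACGTACGTACGT", toy_reference, k=4)
        assert qa.template_id == "t1"
        assert qa.coverage == pytest.approx(1.0)
        assert qa.gapped == toy_reference.seqs["t1"]

    def test_truncated_query_coverage_fraction(self):
        template = "ACGGTTCAGGTCAGGACTGACGGTTCAGGTCAGGACTGAC" * 5  # 200 bp
        sl = RegionSlice(0, 200, {"t": template})
        qa = align_query("q", template[20:], sl, k=8)
        assert qa.coverage == pytest.approx(0.90)

    def test_insertion_resolved_into_template_gap_column(self):
        # template has a gap column; query carries one extra base there
        sl = RegionSlice(0, 9, {"t": "ACGT-ACGT"})
        qa = align_query("q", "ACGTTACGT", sl, k=4)
        assert len(qa.gapped) == 9          # width conserved
        assert qa.gapped == "ACGTTACGT"     # insertion occupies the gap
        assert qa.trimmed_bases == 0

    def test_insertion_without_gap_column_trimmed(self):
        sl = RegionSlice(0, 8, {"t": "ACGTACGT"})
        qa = align_query("q", "ACGTTTACGT", sl, k=4)
        assert len(qa.gapped) == 8
        assert qa.trimmed_bases > 0

    def test_reverse_complement_auto_flip(self):
        from taxoplace.refprep import reverse_complement
        # asymmetric template whose reverse complement shares no k-mers
        template = "AAACCGTTGAACGGTCAGTCCTTG"
        sl = RegionSlice(0, len(template), {"t": template})
        qa = align_query("q", reverse_complement(template), sl, k=6)
        assert qa.strand == "-"
        assert qa.template_id == "t"
        assert qa.gapped == template

    def test_empty_query_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            align_query("q", "----", toy_reference)


class TestCoverageQC:
    @pytest.mark.parametrize("cov,keep", [(0.79, False), (0.80, True),
                                          (1.0, True)])
    def test_boundary_inclusive(self, cov, keep):
        qa = QueryAlignment("q", "t", "ACGT", coverage=cov)
        assert qc_coverage(qa) is keep


class TestFilterPlacements:
    def test_half_of_best_rule(self):
        pls = [Placement("a", 0.6), Placement("b", 0.35), Placement("c", 0.2)]
        assert [p.edge for p in filter_placements(pls)] == ["a", "b"]

    def test_single_placement_kept(self):
        assert filter_placements([Placement("a", 0.01)]) == \
            [Placement("a", 0.01)]

    def test_boundary_inclusive(self):
        pls = [Placement("a", 0.5), Placement("b", 0.25)]
        assert filter_placements(pls) == pls


def five_tip_tree():
    tax = TaxonomyTable({
        t: Lineage.from_names(["D", "P", "C", "O", "F", g, f"{g} s{t}"])
        for t, g in
        [("A", "G1"), ("B", "G1"), ("C", "G2"), ("D", "G2"), ("E", "G2")]
    })
    return RegionTree.from_newick(
        "((A:0.1,B:0.2)N1:0.05,(C:0.1,(D:0.1,E:0.1)N2:0.2)N3:0.1)root;", tax
    )


class TestJplace:
    def test_parse_orders_by_lwr(self):
        rt = five_tip_tree()
        doc_text = write_jplace(rt, {
            "q": [Placement("A", 0.4, 0.01, 0.0),
                  Placement("N2", 0.6, 0.02, 0.05)],
        })
        mapped = read_jplace(doc_text).map_placements(rt)
        assert [p.lwr for p in mapped["q"]] == [0.6, 0.4]
        assert mapped["q"][0].edge == "N2"

    def test_roundtrip_identity_on_used_fields(self):
        rt = five_tip_tree()
        pls = {
            "q1": [Placement("A", 0.7, 0.01, 0.02),
                   Placement("N3", 0.3, 0.05, 0.0)],
            "q2": [Placement("E", 1.0, 0.0, 0.0)],
        }
        text = write_jplace(rt, pls)
        once = read_jplace(text).map_placements(rt)
        text2 = write_jplace(rt, once)
        twice = read_jplace(text2).map_placements(rt)
        assert once == twice == pls

    def test_edge_numbers_map_to_child_nodes(self):
        """Hand-written jplace v3 against the 5-tip tree: edge numbers
        resolve to the child node of each edge by tip-set identity."""
        rt = five_tip_tree()
        doc = read_jplace(json.dumps({
            "version": 3,
            "tree": "((A:0.1{0},B:0.2{1}):0.05{2},(C:0.1{3},"
                    "(D:0.1{4},E:0.1{5}):0.2{6}):0.1{7});",
            "fields": ["edge_num", "like_weight_ratio", "pendant_length",
                       "distal_length"],
            "placements": [
                {"p": [[6, 0.9, 0.01, 0.0]], "n": ["q"]},
            ],
        }))
        mapped = doc.map_placements(rt)
        assert mapped["q"][0].edge == "N2"   # clade {D, E}

    def test_unknown_edge_topology_rejected(self):
        rt = five_tip_tree()
        doc = read_jplace(json.dumps({
            "version": 3,
            "tree": "((A:0.1{0},C:0.2{1}):0.05{2},(B:0.1{3},"
                    "(D:0.1{4},E:0.1{5}):0.2{6}):0.1{7});",
            "fields": ["edge_num", "like_weight_ratio"],
            "placements": [{"p": [[2, 1.0]], "n": ["q"]}],
        }))
        with pytest.raises(Exception, match="edge"):
            doc.map_placements(rt)

    def test_missing_required_key_rejected(self):
        with pytest.raises(Exception, match="placements"):
            read_jplace(json.dumps({"version": 3, "tree": "(A);",
                                    "fields": ["edge_num"]}))


class TestInternalPlacement:
    def test_exact_match_single_placement_lwr_one(self, toy_reference):
        tax = TaxonomyTable({
            t: Lineage.from_names(["D", "P", "C", "O", "F", "G", f"G {t}"])
            for t in toy_reference.ids
        })
        rt = RegionTree.from_newick(
            "((t1:0.01,t2:0.01):0.3,(t3:0.01,t4:0.01):0.3);", tax)
        qa = align_query("q", toy_reference.seqs["t3"], toy_reference, k=4)
        pls = place_query(qa, rt, toy_reference)
        assert pls == [Placement("t3", 1.0, 0.0, 0.0)]

    def test_nearest_tip_wins(self):
        # query one substitution from t1, >= 5 from everything else
        seqs = {
            "t1": "ACGTACGTACGTACGTACGTACGTACGT",
            "t2": "ACGTACGTACGTACGTACGTTGCAGGCA",
            "t3": "TTTTGGGGCCCCAAAATTTTGGGGCCCC",
            "t4": "TTGTGGGGCCCCAAAATTTAGGGGCCCC",
            "t5": "GGGGTTTTAAAACCCCGGGGTTTTAAAA",
            "t6": "GGGGTTTTAAAACCCCGGGATTTTAAAC",
        }
        sl = RegionSlice(0, 28, seqs)
        tax = TaxonomyTable({
            t: Lineage.from_names(["D", "P", "C", "O", "F", "G", f"G {t}"])
            for t in seqs
        })
        rt = RegionTree.from_newick(
            "(((t1:0.01,t2:0.01):0.2,(t3:0.01,t4:0.01):0.2):0.05,"
            "(t5:0.01,t6:0.01):0.25);", tax)
        query = "ACGTACGTACGTACGTACGTACGTACGA"  # t1 with last base changed
        qa = align_query("q", query, sl, k=4)
        pls = place_query(qa, rt, sl)
        assert pls[0].edge == "t1"
        assert pls[0].pendant > 0


def micro_labeling_tree():
    """Two intermingled species under one node, a clean species, and an
    outgroup; flat thresholds for readable arithmetic."""
    lin = lambda g, s: ["D", "P", "C", "O", "F", g, s]
    tax = TaxonomyTable({
        "m1": Lineage.from_names(lin("G1", "G1 s1")),
        "m2": Lineage.from_names(lin("G1", "G1 s2")),
        "p1": Lineage.from_names(lin("G1", "G1 s3")),
        "p2": Lineage.from_names(lin("G1", "G1 s3")),
        "out": Lineage.from_names(lin("G9", "G9 s9")),
    })
    rt = RegionTree.from_newick(
        "(((m1:0.005,m2:0.005)MIX:0.05,(p1:0.005,p2:0.005)PURE:0.05)"
        "GEN:0.3,out:0.5)root;",
        tax,
    )
    ts = ThresholdSet({"Domain": 2.0, "Phylum": 1.8, "Class": 1.6,
                       "Order": 1.4, "Family": 1.0, "Genus": 0.2,
                       "Species": 0.05}, multiplier=1.0)
    return rt, ts, propagate(rt, ts)


class TestAssignment:
    def test_zero_distance_query_gets_full_lineage(self):
        rt, ts, lab = micro_labeling_tree()
        labels, level, node = assign_from_placement(
            Placement("p1", 1.0, 0.0, 0.0), lab, ts, rt)
        assert level == 6 and node == "p1"
        assert labels[6] == {"G1 s3"} and labels[5] == {"G1"}

    def test_between_thresholds_assigns_genus_only(self):
        rt, ts, lab = micro_labeling_tree()
        # pendant 0.1: beyond the species threshold, within genus
        labels, level, node = assign_from_placement(
            Placement("p1", 1.0, 0.1, 0.0), lab, ts, rt)
        assert level == 5
        assert labels[5] == {"G1"} and labels[6] == EMPTY

    def test_ambiguous_index_node_yields_species_set(self):
        rt, ts, lab = micro_labeling_tree()
        labels, level, node = assign_from_placement(
            Placement("MIX", 1.0, 0.01, 0.0), lab, ts, rt)
        assert level == 6 and node == "MIX"
        assert labels[6] == {"G1 s1", "G1 s2"}

    def test_unassignable_far_query(self):
        rt, ts, lab = micro_labeling_tree()
        labels, level, node = assign_from_placement(
            Placement("out", 1.0, 5.0, 0.0), lab, ts, rt)
        assert level is None
        assert all(s == EMPTY for s in labels)

    def test_distal_offset_included_in_distance(self):
        rt, ts, lab = micro_labeling_tree()
        # pendant 0.04 alone is inside the species threshold; adding a
        # distal offset of 0.02 pushes the query out of it
        near = assign_from_placement(Placement("PURE", 1.0, 0.04, 0.0),
                                     lab, ts, rt)
        far = assign_from_placement(Placement("PURE", 1.0, 0.04, 0.02),
                                    lab, ts, rt)
        assert near[1] == 6 and far[1] == 5
        off = assign_from_placement(Placement("PURE", 1.0, 0.04, 0.02),
                                    lab, ts, rt, include_distal=False)
        assert off[1] == 6


class TestCombine:
    def rec(self, labels_by_rank, level, node="n"):
        labels = tuple(labels_by_rank.get(r, EMPTY) for r in range(7))
        return labels, level, node

    def test_modal_level_union_of_species_sets(self):
        per = [
            self.rec({5: {"G1"}, 6: {"s1"}}, 6),
            self.rec({5: {"G1"}, 6: {"s2"}}, 6),
            self.rec({5: {"G1"}}, 5),
        ]
        out = combine_placements("q", per)
        assert out.resolved_rank == 6
        assert out.labels[6] == {"s1", "s2"}
        assert out.labels[5] == {"G1"}

    def test_union_renders_joined(self):
        from taxoplace.taxonomy import render_labels
        per = [self.rec({6: {"s1"}}, 6), self.rec({6: {"s2"}}, 6)]
        out = combine_placements("q", per)
        assert render_labels(out.labels[6]) == "s1;s2"

    def test_level_tie_breaks_coarser(self):
        per = [self.rec({5: {"G1"}, 6: {"s1"}}, 6),
               self.rec({5: {"G1"}}, 5)]
        out = combine_placements("q", per)
        assert out.resolved_rank == 5
        assert out.labels[6] == EMPTY

    def test_all_unassigned(self):
        per = [self.rec({}, None, None)]
        out = combine_placements("q", per)
        assert out.resolved_rank is None and not out.assigned

    def test_union_monotone_in_placements(self):
        per = [self.rec({6: {"s1"}}, 6), self.rec({6: {"s2"}}, 6)]
        base = combine_placements("q", per)
        more = combine_placements("q", per + [self.rec({6: {"s3"}}, 6)])
        assert base.labels[6] <= more.labels[6]
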