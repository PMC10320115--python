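"""Rule DSL parsing and cluster formation, checked against brute force."""

import numpy as np
import pytest

from bgcminer.errors import ParseError, ValidationError
from bgcminer.genome_io import AnnotatedRecord, CdsFeature
from bgcminer.profile_detection import ProfileHit
from bgcminer.rule_engine import (
    ConditionNode,
    DetectionRule,
    Protocluster,
    evaluate_rule,
    form_protoclusters,
    format_rule,
    gap_distance,
    merge_into_regions,
    parse_rule,
    parse_rules,
)
from conftest import make_cds, random_hits, random_record
import oracles


def leaf(p):
    return ConditionNode("leaf", profile=p)


HEADER = "RULE toy CATEGORY PKS CUTOFF 20 NEIGHBOURHOOD 10 CONDITIONS "


class TestParser:
    def test_simple_conjunction(self):
        rule = parse_rule(HEADER + "A and B")
        assert rule.name == "toy" and rule.category == "PKS"
        assert rule.cutoff_kb == 20 and rule.neighbourhood_kb == 10
        assert rule.condition == ConditionNode("and", children=(leaf("A"), leaf("B")))

    def test_and_binds_tighter_than_or(self):
        rule = parse_rule(HEADER + "A or B and C")
        assert rule.condition == ConditionNode(
            "or",
            children=(
                leaf("A"),
                ConditionNode("and", children=(leaf("B"), leaf("C"))),
            ),
        )

    def test_cds_scope_and_minimum(self):
        rule = parse_rule(HEADER + "cds(A and B) and minimum(2, [X, Y, Z])")
        cds_node, min_node = rule.condition.children
        assert cds_node.kind == "cds"
        assert cds_node.children[0] == ConditionNode(
            "and", children=(leaf("A"), leaf("B"))
        )
        assert min_node == ConditionNode("minimum", n=2, options=("X", "Y", "Z"))

    def test_not_and_parentheses(self):
        rule = parse_rule(HEADER + "not (A or B) and C")
        assert rule.condition.kind == "and"
        assert rule.condition.children[0].kind == "not"

    def test_syntax_error_reports_position(self):
        with pytest.raises(ParseError, match="column"):
            parse_rule(HEADER + "A and and B")

    def test_minimum_count_exceeding_options_rejected(self):
        with pytest.raises(ValidationError):
            parse_rule(HEADER + "minimum(4, [X, Y])")

    def test_cds_may_not_contain_minimum(self):
        with pytest.raises(ValidationError):
            parse_rule(HEADER + "cds(minimum(1, [X]))")

    def test_rule_file_with_comments_and_multiple_rules(self):
        text = (
            "# demo rules\n"
            "RULE one CATEGORY A CUTOFF 10 NEIGHBOURHOOD 5\nCONDITIONS P1\n"
            "RULE two CATEGORY B CUTOFF 20 NEIGHBOURHOOD 0\nCONDITIONS P2 and P3\n"
        )
        rules = parse_rules(text)
        assert [r.name for r in rules] == ["one", "two"]

    @pytest.mark.parametrize(
        "expr",
        [
            "A and B",
            "A or B and C",
            "(A or B) and C",
            "not A and not (B or C)",
            "cds(A and (B or C)) and minimum(2, [X, Y, Z]) or D",
            "not not A",
            "minimum(1, [AMP-binding])",
        ],
    )
    def test_format_parse_roundtrip(self, expr):
        rule = parse_rule(HEADER + expr)
        assert parse_rule(format_rule(rule)) == rule


class TestEvaluateRule:
    def make_two_gene_record(self, gap_bp):
        g1 = make_cds("geneX", 1000, 2000)
        g2 = make_cds("geneY", 2000 + gap_bp, 3000 + gap_bp)
        return AnnotatedRecord("r", "A" * (4000 + gap_bp), [g1, g2])

    def test_partners_within_cutoff_are_both_core(self):
        record = self.make_two_gene_record(5_000)
        rule = parse_rule(HEADER + "A and B")
        hits = [ProfileHit("geneX", "A", 50.0), ProfileHit("geneY", "B", 50.0)]
        assert evaluate_rule(rule, record, hits) == {"geneX", "geneY"}

    def test_partners_beyond_cutoff_are_not_core(self):
        record = self.make_two_gene_record(25_000)
        rule = parse_rule(HEADER + "A and B")
        hits = [ProfileHit("geneX", "A", 50.0), ProfileHit("geneY", "B", 50.0)]
        assert evaluate_rule(rule, record, hits) == set()

    def test_cds_scope_requires_single_gene(self):
        record = self.make_two_gene_record(5_000)
        rule = parse_rule(HEADER + "cds(A and B)")
        split = [ProfileHit("geneX", "A", 1.0), ProfileHit("geneY", "B", 1.0)]
        assert evaluate_rule(rule, record, split) == set()
        together = split + [ProfileHit("geneX", "B", 1.0)]
        assert evaluate_rule(rule, record, together) == {"geneX", "geneY"}

    @pytest.mark.parametrize(
        "expr",
        [
            "P1 and P2",
            "P1 or P2 and P3",
            "cds(P1 and P2)",
            "minimum(2, [P1, P2, P3])",
            "P1 and not P4",
            "cds(P1 and P2) and minimum(1, [P3, P4])",
        ],
    )
    def test_matches_brute_force_on_random_genomes(self, expr):
        rule = parse_rule(HEADER + expr)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            record = random_record(rng)
            hits = random_hits(rng, record)
            assert evaluate_rule(rule, record, hits) == oracles.brute_core_set(
                rule, record, hits
            ), f"seed {seed}, rule {expr}"

    def test_enlarging_cutoff_never_shrinks_core(self):
        base = parse_rule(HEADER + "P1 and minimum(2, [P2, P3, P4])")
        for seed in range(50):
            rng = np.random.default_rng(seed)
            record = random_record(rng)
            hits = random_hits(rng, record)
            previous = set()
            for cutoff in (1, 5, 20, 60):
                rule = DetectionRule(
                    base.name, base.category, cutoff, base.neighbourhood_kb,
                    base.condition,
                )
                core = evaluate_rule(rule, record, hits)
                assert previous <= core
                previous = core

    def test_adding_hits_never_removes_core_without_not(self):
        rule = parse_rule(HEADER + "P1 and P2")
        for seed in range(50):
            rng = np.random.default_rng(seed)
            record = random_record(rng)
            hits = random_hits(rng, record)
            core_before = evaluate_rule(rule, record, hits)
            extra = random_hits(rng, record, profiles=("P1", "P2"))
            core_after = evaluate_rule(rule, record, hits + extra)
            assert core_before <= core_after


class TestFormProtoclusters:
    def test_neighbourhood_clamped_to_contig(self):
        record = AnnotatedRecord("r", "A" * 15_000, [make_cds("g", 10_000, 11_000)])
        rule = parse_rule(HEADER + "A")
        (proto,) = form_protoclusters({"g"}, rule, record)
        assert (proto.start, proto.end) == (0, 15_000)
        assert (proto.core_start, proto.core_end) == (10_000, 11_000)

    def test_distant_cores_split_into_two_protoclusters(self):
        record = AnnotatedRecord(
            "r", "A" * 40_000,
            [make_cds("g1", 0, 1_000), make_cds("g2", 30_000, 31_000)],
        )
        rule = parse_rule(HEADER + "A")
        protos = form_protoclusters({"g1", "g2"}, rule, record)
        assert [p.core_cds for p in protos] == [("g1",), ("g2",)]

    def test_partition_matches_graph_components(self):
        rule = parse_rule(HEADER + "P1")
        for seed in range(150):
            rng = np.random.default_rng(1_000 + seed)
            record = random_record(rng)
            core = {
                f.locus_tag for f in record.features if rng.random() < 0.7
            }
            protos = form_protoclusters(core, rule, record)
            got = {frozenset(p.core_cds) for p in protos}
            feats = [record.get_feature(t) for t in core]
            assert got == oracles.brute_chain_partition(feats, rule.cutoff_bp)


class TestMergeIntoRegions:
    def proto(self, rule_name, start, end):
        return Protocluster(rule_name, start + 1, end - 1, start, end, ("x",))

    def test_overlapping_protoclusters_merge_with_sorted_products(self):
        regions = merge_into_regions(
            [self.proto("T1PKS", 0, 5_000), self.proto("NRPS", 4_000, 9_000)]
        )
        (region,) = regions
        assert (region.start, region.end) == (0, 9_000)
        assert region.products == ("NRPS", "T1PKS")

    def test_disjoint_spans_stay_separate(self):
        regions = merge_into_regions(
            [self.proto("a", 0, 1_000), self.proto("b", 5_000, 6_000)]
        )
        assert len(regions) == 2

    def test_abutting_spans_do_not_merge(self):
        regions = merge_into_regions(
            [self.proto("a", 0, 5_000), self.proto("b", 5_000, 9_000)]
        )
        assert len(regions) == 2

    def test_groupings_match_union_find(self):
        for seed in range(150):
            rng = np.random.default_rng(9_000 + seed)
            protos = []
            for i in range(int(rng.integers(1, 10))):
                start = int(rng.integers(0, 50_000))
                end = start + int(rng.integers(2_000, 20_000))
                protos.append(self.proto(f"rule{i}", start, end))
            regions = merge_into_regions(protos)
            got = {
                frozenset((p.start, p.end, p.rule_name) for p in r.protoclusters)
                for r in regions
            }
            expected = {
                frozenset((protos[i].start, protos[i].end, protos[i].rule_name) for i in comp)
                for comp in oracles.brute_region_groups(protos)
            }
            assert got == expected
            # spans of distinct regions never overlap
            spans = sorted((r.start, r.end) for r in regions)
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def test_gap_distance_zero_when_overlapping():
    a = make_cds("a", 100, 400)
    b = make_cds("b", 300, 600)
    assert gap_distance(a, b) == 0
    c = make_cds("c", 1_000, 1_300)
    assert gap_distance(a, c) == 600
    assert gap_distance(c, a) == 600
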