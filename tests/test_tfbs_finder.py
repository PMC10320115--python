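"""PWM construction, tiering, scanning and genomic-context annotation."""

import math

import numpy as np
import pytest

from bgcminer.errors import DegenerateMatrixError, ValidationError
from bgcminer.fixtures import (
    DEFAULT_TFBS_CONSENSUS,
    PlantedTfbs,
    SyntheticGenomeSpec,
    default_tfbs_pwm,
    generate_genome,
    generate_pwm,
)
from bgcminer.genome_io import AnnotatedRecord, CdsFeature
from bgcminer.tfbs_finder import (
    Pwm,
    TfbsHit,
    annotate_context,
    assign_confidence,
    build_pwm,
    load_pwms,
    scan_sequence,
    write_pwms,
)
from conftest import make_cds
import oracles


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def random_counts(rng, length):
    return rng.integers(1, 50, size=(length, 4))


class TestBuildPwm:
    def test_uniform_counts_give_zero_log_odds(self):
        pwm = build_pwm(np.full((6, 4), 25), "flat")
        assert np.allclose(pwm.log_odds, 0.0)
        assert pwm.max_score == 0.0

    def test_single_row_matches_hand_formula(self):
        pwm = build_pwm([[99, 0, 0, 0]], "one", pseudocount=1.0)
        # log2( (count + p*bg) / (N + p) / bg )
        expected_a = math.log2((99 + 0.25) / 100 / 0.25)
        expected_other = math.log2(0.25 / 100 / 0.25)
        assert abs(pwm.log_odds[0, 0] - expected_a) < 1e-12
        for col in (1, 2, 3):
            assert abs(pwm.log_odds[0, col] - expected_other) < 1e-12

    def test_log_odds_matrix_matches_cellwise_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = random_counts(rng, int(rng.integers(4, 15)))
            pwm = build_pwm(counts, "x", pseudocount=0.7)
            assert np.allclose(
                pwm.log_odds, oracles.brute_log_odds(counts, pseudocount=0.7)
            )

    def test_smaller_pseudocount_raises_consensus_log_odds(self):
        scores = [
            build_pwm([[99, 0, 0, 0]], "m", pseudocount=p).log_odds[0, 0]
            for p in (4.0, 1.0, 0.25, 0.01)
        ]
        assert scores == sorted(scores)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            build_pwm([[5, -1, 0, 0]], "bad")

    def test_jaspar_roundtrip(self, tmp_path):
        pwm = generate_pwm("ACGTACGT", information=0.8, name="demo")
        path = tmp_path / "pwms.txt"
        write_pwms([pwm], path)
        (loaded,) = load_pwms(path)
        assert loaded.name == "demo"
        assert np.array_equal(loaded.counts, pwm.counts)


class TestAssignConfidence:
    def test_max_score_is_strong(self):
        pwm = default_tfbs_pwm()
        assert assign_confidence(pwm.max_score, pwm) == "strong"

    def test_boundary_maps_to_higher_tier(self):
        pwm = default_tfbs_pwm()
        exactly_medium = pwm.min_score + 0.75 * (pwm.max_score - pwm.min_score)
        assert assign_confidence(exactly_medium, pwm) == "medium"

    def test_below_weak_is_suppressed(self):
        pwm = default_tfbs_pwm()
        assert assign_confidence(pwm.min_score, pwm) is None

    def test_random_scores_match_threshold_recomputation(self):
        pwm = default_tfbs_pwm()
        rng = np.random.default_rng(11)
        span = pwm.max_score - pwm.min_score
        for score in pwm.min_score + span * rng.uniform(-0.2, 1.2, size=1000):
            assert assign_confidence(float(score), pwm) == oracles.brute_tier(
                score, pwm.min_score, pwm.max_score, pwm.tier_fractions
            )

    def test_degenerate_matrix_is_an_error(self):
        flat = build_pwm(np.full((4, 4), 10), "flat")
        with pytest.raises(DegenerateMatrixError):
            assign_confidence(0.0, flat)


class TestScanSequence:
    def test_planted_consensus_scores_max_on_forward_strand(self):
        rng = np.random.default_rng(5)
        pwm = default_tfbs_pwm()
        seq = random_dna(rng, 400) + DEFAULT_TFBS_CONSENSUS + random_dna(rng, 400)
        record = AnnotatedRecord("r", seq, [])
        hits = scan_sequence(record, pwm, min_tier="strong", annotate=False)
        assert any(
            h.start == 400 and h.strand == 1 and abs(h.score - pwm.max_score) < 1e-9
            for h in hits
        )

    def test_reverse_complement_mirrors_starts_and_flips_strands(self):
        rng = np.random.default_rng(6)
        pwm = generate_pwm("TTGACCGGA", information=0.7)
        seq = random_dna(rng, 300)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_sequence(AnnotatedRecord("a", seq, []), pwm, annotate=False)
        rev = scan_sequence(AnnotatedRecord("b", rc, []), pwm, annotate=False)
        L = pwm.length
        mirrored = {
            (len(seq) - L - h.start, -h.strand, round(h.score, 9)) for h in fwd
        }
        assert mirrored == {(h.start, h.strand, round(h.score, 9)) for h in rev}

    def test_matches_brute_force_window_scorer(self):
        rng = np.random.default_rng(8)
        pwm = build_pwm(random_counts(rng, 8), "rand8")
        seq = random_dna(rng, 2000)
        record = AnnotatedRecord("r", seq, [])
        hits = scan_sequence(record, pwm, min_tier="weak", annotate=False)
        brute = oracles.brute_scan(seq, pwm.log_odds.tolist())
        brute_hits = {
            (start, strand): score
            for (start, strand), score in brute.items()
            if oracles.brute_tier(score, pwm.min_score, pwm.max_score, pwm.tier_fractions)
        }
        assert {(h.start, h.strand) for h in hits} == set(brute_hits)
        for h in hits:
            assert abs(h.score - brute_hits[(h.start, h.strand)]) < 1e-9

    def test_windows_containing_n_are_dropped(self):
        pwm = generate_pwm("ACGTAC", information=1.0)
        seq = "ACGTAC" + "N" + "ACGTAC"
        hits = scan_sequence(AnnotatedRecord("r", seq, []), pwm, annotate=False)
        assert all("N" not in seq[h.start : h.start + 6] for h in hits)
        assert any(h.start == 0 for h in hits) and any(h.start == 7 for h in hits)

    def test_prepending_bases_shifts_hits_without_changing_scores(self):
        rng = np.random.default_rng(9)
        pwm = default_tfbs_pwm()
        seq = random_dna(rng, 1500) + DEFAULT_TFBS_CONSENSUS + random_dna(rng, 100)
        prefix = random_dna(rng, 7)
        base = scan_sequence(AnnotatedRecord("a", seq, []), pwm, annotate=False)
        shifted = scan_sequence(AnnotatedRecord("b", prefix + seq, []), pwm, annotate=False)
        shifted_set = {(h.start, h.strand, round(h.score, 9)) for h in shifted}
        for h in base:
            assert (h.start + 7, h.strand, round(h.score, 9)) in shifted_set

    def test_reported_scores_recompute_from_log_odds(self):
        rng = np.random.default_rng(10)
        pwm = default_tfbs_pwm()
        seq = random_dna(rng, 3000)
        record = AnnotatedRecord("r", seq, [])
        for h in scan_sequence(record, pwm, annotate=False):
            window = seq[h.start : h.start + pwm.length]
            if h.strand == -1:
                window = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            manual = sum(
                pwm.log_odds[i, "ACGT".index(b)] for i, b in enumerate(window)
            )
            assert abs(manual - h.score) < 1e-9


class TestAnnotateContext:
    def hit(self, start, length=8):
        return TfbsHit("p", start, length, 1, 10.0, "strong")

    def test_window_on_the_atg_is_overlaps_start_codon(self):
        # window starting 1 bp before a forward ATG covers codon bases 2-3
        record = AnnotatedRecord("r", "A" * 2000, [make_cds("zur", 500, 800, 1)])
        ann = annotate_context(self.hit(499), record)
        assert ann.category == "overlaps-start-codon"

    def test_divergent_flanks_within_limit_is_upstream_of_both(self):
        record = AnnotatedRecord(
            "r", "A" * 3000,
            [make_cds("left", 500, 1100, -1), make_cds("right", 1248, 1548, 1)],
        )
        ann = annotate_context(self.hit(1140), record)
        assert ann.category == "upstream-of-both"
        assert (ann.distance_left, ann.distance_right) == (40, 100)
        assert (ann.left_gene, ann.right_gene) == ("left", "right")

    def test_exhaustive_windows_match_hand_classifier(self):
        feats = [
            make_cds("geneL", 500, 1100, -1),
            make_cds("geneM", 1500, 1800, 1),
            make_cds("geneR", 2200, 2800, -1),
        ]
        record = AnnotatedRecord("r", "A" * 3000, feats)

        def expected(s):
            """Hand-written classification from the known toy geometry."""
            win = (s, s + 8)
            overlapped = [
                (name, cs, ce)
                for name, gs, ge, cs, ce in (
                    ("geneL", 500, 1100, 1097, 1100),  # - strand: codon at the end
                    ("geneM", 1500, 1800, 1500, 1503),
                    ("geneR", 2200, 2800, 2797, 2800),
                )
                if gs < win[1] and win[0] < ge
            ]
            if overlapped:
                for _, cs, ce in overlapped:
                    if cs < win[1] and win[0] < ce:
                        return "overlaps-start-codon"
                return "within-gene"
            if win[1] <= 500:
                return "contig-edge"
            if 1100 <= win[0] and win[1] <= 1500:  # divergent pair
                left_ok = win[0] - 1100 <= 300
                right_ok = 1500 - win[1] <= 300
                if left_ok and right_ok:
                    return "upstream-of-both"
                if left_ok or right_ok:
                    return "upstream-of-one"
                return "downstream-of-both"
            if 1800 <= win[0] and win[1] <= 2200:  # convergent pair
                return "downstream-of-both"
            return "contig-edge"  # s >= 2800

        for start in range(0, 3000 - 8 + 1):
            ann = annotate_context(self.hit(start), record)
            assert ann.category == expected(start), f"window start {start}"


class TestPlantedSiteRecovery:
    def test_planted_sites_recovered_at_strong_tier(self):
        pwm = default_tfbs_pwm()
        spec = SyntheticGenomeSpec(
            contig_length=40_000,
            n_background_genes=6,
            planted_tfbs=(
                PlantedTfbs("synthetic_regulator", 3_000, 1),
                PlantedTfbs("synthetic_regulator", 35_000, -1),
            ),
            seed=3,
        )
        record = generate_genome(spec).record
        hits = scan_sequence(record, pwm, min_tier="strong", annotate=False)
        found = {(h.start, h.strand) for h in hits}
        assert (3_000, 1) in found and (35_000, -1) in found

    def test_false_strong_calls_on_random_background_average_below_one(self):
        pwm = default_tfbs_pwm()
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(10_000 + seed)
            record = AnnotatedRecord("bg", random_dna(rng, 100_000), [])
            hits = scan_sequence(record, pwm, min_tier="strong", annotate=False)
            counts.append(sum(1 for h in hits if h.strand == 1))
            counts.append(sum(1 for h in hits if h.strand == -1))
        assert sum(counts) / len(counts) < 1.0
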