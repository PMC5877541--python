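"""Control-region element detection: poly runs, repeats, hairpins, CSBs."""

import numpy as np
import pytest

from mitofeatures import (
    detect_flanking_motifs,
    find_csbs,
    find_poly_runs,
    find_stem_loops,
    find_tandem_repeats,
    generate_control_region,
    generate_cr_alignment,
    segment_control_region,
)
from mitofeatures.composition import reverse_complement
from mitofeatures.synthetic import CRSpec, HairpinSpec, SpecError, _random_seq


class TestPolyRuns:
    def test_single_run_with_flanks(self):
        runs = find_poly_runs("GG" + "A" * 9 + "GG")
        assert [(r.base, r.start, r.end, r.length) for r in runs] == [("A", 3, 11, 9)]

    def test_run_below_threshold_not_reported(self):
        assert find_poly_runs("GG" + "A" * 6 + "GG", min_len=7) == []

    def test_planted_cr_run_census(self):
        """A CR planted with 2 poly-A + 1 poly-T + 1 poly-C yields exactly 4."""
        spec = CRSpec(
            leading_poly=(),
            remainder_poly=(("A", 8, 180), ("A", 7, 230), ("T", 9, 280), ("C", 7, 330)),
        )
        seq, truth = generate_control_region(spec, seed=21)
        runs = find_poly_runs(seq)
        assert [(r.base, r.start, r.end) for r in runs] == list(truth.poly_runs)

    def test_min_len_below_two_rejected(self):
        with pytest.raises(ValueError):
            find_poly_runs("AAAA", min_len=1)


class TestTandemRepeats:
    def test_pure_dinucleotide_array(self):
        hits = find_tandem_repeats("AT" * 10)
        assert [(h.period, h.copy_number, h.identity) for h in hits] == [(2, 10.0, 1.0)]

    def test_seven_mer_array_in_random_background(self):
        """Six complete + one partial 7-mer copy, the published CR pattern."""
        rng = np.random.default_rng(31)
        flank1 = _random_seq(rng, 150, probs=(0.25,) * 4, run_cap=10)
        flank2 = _random_seq(rng, 150, probs=(0.25,) * 4, run_cap=10)
        seq = flank1 + "ATTTAGA" * 6 + "ATTTA" + flank2
        hits = find_tandem_repeats(seq)
        top = max(hits, key=lambda h: h.score)
        assert top.period == 7
        assert top.copy_number == pytest.approx(6.7, abs=0.3)

    def test_planted_array_recovered_exactly_over_seeds(self):
        recovered = 0
        for seed in range(20):
            seq, truth = generate_control_region(CRSpec(), seed=seed)
            hits = find_tandem_repeats(seq)
            top = [h for h in hits if (h.start, h.end) == truth.repeat_block
                   and h.period == truth.period]
            recovered += bool(top)
        assert recovered >= 19

    def test_mutated_array_period_exact_copy_within_tolerance(self):
        ok = 0
        for seed in range(20):
            seq, truth = generate_control_region(
                CRSpec(unit_mutation_rate=0.10), seed=seed
            )
            hits = [h for h in find_tandem_repeats(seq)
                    if not (h.end < truth.repeat_block[0] or h.start > truth.repeat_block[1])]
            top = max(hits, key=lambda h: h.score)
            ok += (top.period == truth.period
                   and abs(top.copy_number - truth.copy_number) <= 0.3)
        assert ok >= 19

    def test_false_positive_rate_on_random_sequence(self):
        """Random 500-nt sequences rarely contain a significant array."""
        false_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            s = _random_seq(rng, 500, probs=(0.25,) * 4, run_cap=10)
            if find_tandem_repeats(s, min_copies=3, min_identity=0.9):
                false_calls += 1
        assert false_calls / 100 < 0.05

    def test_short_sequence_returns_empty(self):
        assert find_tandem_repeats("ACG") == []


class TestStemLoops:
    def _hairpin(self, stem5, loop, pairs_override=None):
        stem3 = reverse_complement(stem5)
        if pairs_override:
            stem3 = "".join(pairs_override.get(i, c) for i, c in enumerate(stem3))
        return stem5 + loop + stem3

    def test_perfect_inverted_repeat_found_at_planted_span(self):
        # 12-bp stem around an 8-nt loop inside a non-pairing background
        stem5 = "GATCGGTACGTC"
        hp = self._hairpin(stem5, "AACCTTAA")
        bg_l, bg_r = "CCTCTCCTCTCCTCTCCTCT", "TCTCCTCTCCTCTCCTCTCC"
        seq = bg_l + hp + bg_r
        hits = find_stem_loops(seq, min_stem=12, max_mismatch=0)
        assert len(hits) == 1
        sl = hits[0]
        assert sl.stem5 == (21, 32) and sl.loop == (33, 40) and sl.stem3 == (41, 52)
        assert sl.wc == 12 and sl.mismatch == 0

    def test_mismatch_budget_controls_detection(self):
        """One G-U plus one mismatch pass at budget 2, fail at budget 0."""
        stem5 = "GATCGGTACGTC"
        stem3 = list(reverse_complement(stem5))
        # pair 2 (stem5 'T') -> G-U wobble; pair 5 (stem5 'G') -> A mismatch
        stem3[len(stem3) - 1 - 2] = "G"
        stem3[len(stem3) - 1 - 5] = "A"
        seq = "CCTCTCCTCTCCTCTCCTCT" + stem5 + "AACCTTAA" + "".join(stem3) + "TCTCCTCTCC"
        with_budget = find_stem_loops(seq, min_stem=12, max_mismatch=2)
        strict = find_stem_loops(seq, min_stem=12, max_mismatch=0)
        assert any(sl.stem5 == (21, 32) for sl in with_budget)
        hit = next(sl for sl in with_budget if sl.stem5 == (21, 32))
        assert (hit.wc, hit.gu, hit.mismatch) == (10, 1, 1)
        assert not any(sl.stem5 == (21, 32) for sl in strict)

    def test_homopolymer_has_no_hairpins(self):
        assert find_stem_loops("A" * 80, min_stem=5) == []

    def test_planted_hairpins_recovered_from_generated_cr(self):
        recovered = 0
        for seed in range(15):
            seq, truth = generate_control_region(CRSpec(), seed=seed)
            hits = find_stem_loops(seq, min_stem=12, max_mismatch=0)
            spans = {(sl.stem5, sl.stem3) for sl in hits}
            if all(
                (tuple(t["stem5"]), tuple(t["stem3"])) in spans
                for t in truth.stem_loops
            ):
                recovered += 1
        assert recovered >= 14

    def test_genome_global_coordinates_via_offset(self):
        seq, truth = generate_control_region(CRSpec(), seed=2)
        sl = find_stem_loops(seq, min_stem=12, max_mismatch=0)[0]
        shifted = sl.shifted(14897)
        assert shifted.stem5[0] == sl.stem5[0] + 14897


class TestFlankingMotifs:
    def test_gant_downstream_detected(self):
        seq, truth = generate_control_region(CRSpec(), seed=9)
        hits = [detect_flanking_motifs(seq, sl)
                for sl in find_stem_loops(seq, min_stem=12, max_mismatch=0)]
        by_span = {sl.stem5: sl for sl in hits}
        t1, t2 = truth.stem_loops
        sl1 = by_span[tuple(t1["stem5"])]
        sl2 = by_span[tuple(t2["stem5"])]
        assert sl1.gant_3prime.present and sl2.gant_3prime.present
        assert not sl1.tata_5prime.present and sl2.tata_5prime.present
        assert sl2.tata_5prime.start == t2["tata"][0]

    def test_gant_requires_at_least_one_a(self):
        # downstream "GT" must not match the G(A)nT pattern
        sl = find_stem_loops(
            "CCTCTCCTCT" + "GATCGGTACGTC" + "AACCTTAA"
            + reverse_complement("GATCGGTACGTC") + "GTCCTCTCCT",
            min_stem=12, max_mismatch=0,
        )[0]
        annotated = detect_flanking_motifs(
            "CCTCTCCTCT" + "GATCGGTACGTC" + "AACCTTAA"
            + reverse_complement("GATCGGTACGTC") + "GTCCTCTCCT", sl
        )
        assert not annotated.gant_3prime.present


class TestCSBs:
    def test_identical_rows_give_one_full_block(self):
        rows = ["ACGTACGTACGTACGTACGT"] * 7
        blocks = find_csbs(rows, min_len=15)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (1, 20)
        assert blocks[0].mean_identity == 100.0

    def test_planted_blocks_recovered_in_divergent_background(self):
        names, rows, truth = generate_cr_alignment(7, planted_blocks=4, seed=17)
        blocks = find_csbs(rows, min_len=15, min_identity_class=75)
        assert len(blocks) == 4
        for block, (start, end, _) in zip(blocks, truth.blocks):
            assert abs(block.start - start) <= 2 and abs(block.end - end) <= 2
        assert [b.label for b in blocks] == ["CSB1", "CSB2", "CSB3", "CSB4"]

    def test_block_below_min_len_not_reported(self):
        names, rows, truth = generate_cr_alignment(
            7, planted_blocks=[(200, 14)], seed=4
        )
        blocks = find_csbs(rows, min_len=15, min_identity_class=75)
        assert all(not (b.start <= 200 <= b.end) for b in blocks)

    def test_taxon_order_permutation_invariance(self):
        names, rows, _ = generate_cr_alignment(7, planted_blocks=4, seed=23)
        forward = find_csbs(rows)
        shuffled = find_csbs(rows[::-1])
        assert [(b.start, b.end) for b in forward] == [(b.start, b.end) for b in shuffled]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            find_csbs(["ACGT", "ACG", "ACGT"])

    def test_fewer_than_three_rows_rejected(self):
        with pytest.raises(ValueError):
            find_csbs(["ACGT", "ACGT"])


class TestSegmentation:
    def test_planted_cr_segmentation_within_one_period(self):
        spec = CRSpec(remainder_len=392)  # the published leading/remainder sizes
        seq, truth = generate_control_region(spec, seed=13)
        seg = segment_control_region(seq)
        assert abs(seg.repeat_block[0] - truth.repeat_block[0]) <= truth.period
        assert abs(seg.repeat_block[1] - truth.repeat_block[1]) <= truth.period
        assert seg.leading[0] == 1
        assert seg.remainder[1] == len(seq)

    def test_spans_are_disjoint_and_cover_the_cr(self):
        seq, _ = generate_control_region(CRSpec(), seed=19)
        seg = segment_control_region(seq)
        spans = [s for s in (seg.leading, seg.repeat_block, seg.remainder) if s]
        flat = [p for span in spans for p in range(span[0], span[1] + 1)]
        assert flat == list(range(1, len(seq) + 1))

    def test_repeat_free_cr_is_all_leading(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 400, probs=(0.25,) * 4, run_cap=10)
        seg = segment_control_region(seq, min_copies=3.0, min_identity=0.95)
        if seg.repeat_block is None:
            assert seg.leading == (1, 400) and seg.remainder is None

    def test_empty_cr_rejected(self):
        with pytest.raises(ValueError):
            segment_control_region("")


class TestGeneratorPreconditions:
    def test_background_identity_of_one_rejected(self):
        with pytest.raises(SpecError):
            generate_cr_alignment(7, background_identity=1.0, seed=0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(SpecError):
            generate_cr_alignment(2, seed=0)

    def test_hairpin_must_fit_its_segment(self):
        with pytest.raises(SpecError, match="hairpin"):
            CRSpec(sl1=HairpinSpec(offset=730, stem=14, loop=8)).validate()
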