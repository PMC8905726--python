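"""Homology hits: defragmentation oracle, masking, copy-number accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steamerscan import hit_tools as ht
from steamerscan import simdata as sd
from steamerscan.evaluation import brute_force_merge


def _hits(spans, seq_id="chr", lib="lib"):
    return [ht.RepeatHit(lib, seq_id, s, e, "+", e - s, 90.0) for s, e in spans]


class TestConcatenateHits:
    def test_merge_below_gap(self):
        merged = ht.concatenate_hits(_hits([(100, 450), (900, 1300)]))
        assert [(m.start, m.end) for m in merged] == [(100, 1300)]
        assert merged[0].n_hits == 2
        assert merged[0].matched_bp == 350 + 400

    def test_short_span_removed(self):
        assert ht.concatenate_hits(_hits([(0, 250)])) == []

    def test_gap_exactly_500_not_merged(self):
        merged = ht.concatenate_hits(_hits([(0, 400), (900, 1400)]))
        assert [(m.start, m.end) for m in merged] == [(0, 400), (900, 1400)]
        # and each part is length-filtered independently
        merged = ht.concatenate_hits(_hits([(0, 200), (700, 1400)]))
        assert [(m.start, m.end) for m in merged] == [(700, 1400)]

    def test_gap_499_merged(self):
        merged = ht.concatenate_hits(_hits([(0, 400), (899, 1400)]))
        assert [(m.start, m.end) for m in merged] == [(0, 1400)]

    def test_negative_span_rejected(self):
        with pytest.raises(ht.ParameterError):
            ht.concatenate_hits([ht.RepeatHit("l", "c", 10, 10, "+", 1, 90.0)])

    def test_groups_are_independent_per_seq_and_library(self):
        hits = _hits([(0, 400)], seq_id="a") + _hits([(450, 900)], seq_id="b")
        merged = ht.concatenate_hits(hits)
        assert len(merged) == 2  # never merged across sequences

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20_000), st.integers(1, 1_500)),
            min_size=1, max_size=60,
        )
    )
    def test_matches_brute_force_oracle(self, raw):
        spans = [(s, s + ln) for s, ln in raw]
        merged = [(m.start, m.end) for m in ht.concatenate_hits(_hits(spans))]
        assert merged == brute_force_merge(spans)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 10_000), st.integers(1, 1_000)),
            min_size=1, max_size=40,
        ),
        st.integers(0, 400),
        st.integers(100, 600),
    )
    def test_threshold_monotonicity(self, raw, min_len, max_gap):
        spans = [(s, s + ln) for s, ln in raw]
        n = len(ht.concatenate_hits(_hits(spans), max_gap=max_gap, min_len=min_len))
        # lowering min_len never decreases the locus count
        n_lower = len(ht.concatenate_hits(_hits(spans), max_gap=max_gap,
                                          min_len=max(0, min_len - 100)))
        assert n_lower >= n
        # raising max_gap never increases it
        n_merged = len(ht.concatenate_hits(_hits(spans), max_gap=max_gap + 300,
                                           min_len=min_len))
        assert n_merged <= n


class TestMaskGenome:
    def test_no_hits_identity(self):
        g = {"chr": "ACGTacgtNN"}
        assert ht.mask_genome(g, []) == g

    def test_hard_mask_positions(self):
        g = {"chr": "A" * 30}
        out = ht.mask_genome(g, [ht.MergedHit("l", "chr", 10, 20, 1, 10)])
        assert out["chr"] == "A" * 10 + "N" * 10 + "A" * 10

    def test_soft_mask_preserves_sequence(self):
        g = {"chr": "ACGTACGTACGT"}
        out = ht.mask_genome(g, [ht.MergedHit("l", "chr", 4, 8, 1, 4)], soft=True)
        assert out["chr"] == "ACGTacgtACGT"
        assert out["chr"].upper() == g["chr"]

    def test_overlapping_spans_are_unioned(self):
        g = {"chr": "A" * 50}
        merged = [
            ht.MergedHit("l1", "chr", 10, 30, 1, 20),
            ht.MergedHit("l2", "chr", 20, 40, 1, 20),
        ]
        out = ht.mask_genome(g, merged)
        assert out["chr"].count("N") == 30
        assert ht.masked_bp(merged) == 30

    def test_masked_bp_matches_masked_positions(self):
        rng = np.random.default_rng(3)
        g = {"chr": "A" * 5_000}
        merged = []
        for _ in range(30):
            s = int(rng.integers(0, 4_500))
            merged.append(ht.MergedHit("l", "chr", s, s + int(rng.integers(1, 400)), 1, 1))
        out = ht.mask_genome(g, merged)
        assert out["chr"].count("N") == ht.masked_bp(merged)


class TestSimilaritySearch:
    def test_planted_copies_covered(self, small_element):
        spec, canonical, _ = small_element
        plan = [
            sd.Insertion(spec, 20_000, sd.MutationParams(substitution_rate=0.03, seed=1)),
            sd.Insertion(spec, 60_000, sd.MutationParams(substitution_rate=0.05, seed=2)),
        ]
        g, truth = sd.plant_genome(100_000, 0.4, plan, seed=5)
        hits = ht.similarity_search({"cons": canonical}, {"chr1": g})
        merged = ht.concatenate_hits(hits)
        for t in truth:
            cov = sum(max(0, min(m.end, t.end) - max(m.start, t.start)) for m in merged)
            assert cov >= 0.99 * (t.end - t.start)

    def test_reverse_complement_copy_found_on_minus_strand(self, small_element):
        spec, canonical, _ = small_element
        g, truth = sd.plant_genome(
            40_000, 0.4,
            [sd.Insertion(spec, 15_000, sd.MutationParams(revcomp=True))],
            seed=6,
        )
        hits = ht.similarity_search({"cons": canonical}, {"chr1": g})
        t = truth[0]
        minus = [h for h in hits if h.strand == "-"]
        assert minus, "minus-strand hit expected"
        best = max(minus, key=lambda h: h.end - h.start)
        assert best.start >= t.start - 10 and best.end <= t.end + 10

    def test_all_n_genome_is_empty(self, small_element):
        _, canonical, _ = small_element
        assert ht.similarity_search({"cons": canonical}, {"chr1": "N" * 10_000}) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ht.ParameterError):
            ht.similarity_search({}, {"chr1": "ACGT" * 100})


class TestCopyNumberReport:
    def test_binning_and_proportion(self):
        merged = (
            [ht.MergedHit("l", "c", i * 10_000, i * 10_000 + 5_000, 1, 5_000) for i in range(5)]
            + [ht.MergedHit("l", "c", 100_000 + i * 10_000, 100_000 + i * 10_000 + 2_500, 1, 2_500)
               for i in range(3)]
        )
        rep = ht.copy_number_report(["c1", "c2", "c3", "c4", "c5"], merged, 2_000_000)
        assert rep.n_full_size == 5
        assert rep.n_gt_4kb == 5
        assert rep.n_2_to_4kb == 3
        assert rep.n_total_loci == 8
        assert rep.bp_masked == 5 * 5_000 + 3 * 2_500
        assert rep.genomic_proportion == round(100 * rep.bp_masked / 2_000_000, 2)

    def test_proportion_formatting(self):
        merged = [ht.MergedHit("l", "c", 0, 20_000, 1, 20_000)]
        rep = ht.copy_number_report([], merged, 2_000_000)
        assert f"{rep.genomic_proportion:.2f}" == "1.00"

    def test_bin_boundaries(self):
        merged = [
            ht.MergedHit("l", "c", 0, 4_000, 1, 4_000),      # exactly 4 kb -> 2-4 bin
            ht.MergedHit("l", "c", 10_000, 14_001, 1, 4_001),  # >4 kb
            ht.MergedHit("l", "c", 20_000, 22_000, 1, 2_000),  # exactly 2 kb -> neither
        ]
        rep = ht.copy_number_report([], merged, 1_000_000)
        assert rep.n_gt_4kb == 1 and rep.n_2_to_4kb == 1 and rep.n_total_loci == 3

    def test_zero_report(self):
        rep = ht.copy_number_report([], [], 1_000_000)
        assert (rep.n_total_loci, rep.bp_masked, rep.avg_length) == (0, 0, 0)
        assert rep.genomic_proportion == 0.0
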