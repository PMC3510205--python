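import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from helpers import bf_merge, bf_positional, make_tags
from nucstate.genome import GeneModel, GenomicInterval
from nucstate.regulatory import (
    CandidateRegion,
    PeakRegion,
    call_peaks,
    conservation_enrichment,
    nucrna_regions,
    positional_classify,
    positional_fractions,
    sample_random_regions,
    subtract_transcribed,
    tf_overlap_enrichment,
)

SIZES = {"chr1": 100_000}


def _peak(start, end, chrom="chr1"):
    return PeakRegion(GenomicInterval(chrom, start, end), (start + end) // 2, 1.0, 1e-6)


class TestCallPeaks:
    def test_constructed_strand_imbalance_peak(self):
        x = 50_000
        rows = [("chr1", x - 100 + i % 40, x - 64 + i % 40, "+") for i in range(50)]
        rows += [("chr1", x + 64 + i % 40, x + 100 + i % 40, "-") for i in range(50)]
        # flat background so the Poisson test has a rate to work with
        rng = np.random.default_rng(0)
        for s in rng.integers(0, 99_000, 200):
            rows.append(("chr1", int(s), int(s) + 36, "+" if rng.random() < 0.5 else "-"))
        peaks = call_peaks(make_tags(rows, SIZES))
        hits = [p for p in peaks if p.interval.start <= x <= p.interval.end]
        assert len(hits) == 1
        assert x - 64 <= hits[0].summit <= x + 64

    def test_no_tags_no_peaks(self):
        assert call_peaks(make_tags([], SIZES)) == []

    def test_unstranded_input_rejected(self):
        rows = [("chr1", i * 100, i * 100 + 36, ".") for i in range(50)]
        with pytest.raises(ValueError, match="unstranded"):
            call_peaks(make_tags(rows, SIZES))

    def test_false_positive_rate_bounded_on_uniform_background(self):
        rng = np.random.default_rng(1)
        n = 20_000
        rows = [
            ("chr1", int(s), int(s) + 36, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 99_000, n)
        ]
        peaks = call_peaks(make_tags(rows, SIZES), p_cut=0.001)
        # tested summits number at most the sign changes (< n); expected
        # false peaks ~ p_cut * tests, allow generous slack
        assert len(peaks) <= max(5, 0.001 * n * 5)


class TestNucrnaRegions:
    def test_merged_but_too_short_is_discarded(self):
        tags = make_tags([("chr1", 0, 36, "+"), ("chr1", 100, 136, "+")], SIZES)
        assert nucrna_regions(tags) == []

    def test_abutting_tags_forming_long_region_kept(self):
        rows = [("chr1", i * 36, (i + 1) * 36, "+") for i in range(30)]
        (region,) = nucrna_regions(make_tags(rows, SIZES))
        assert (region.start, region.end) == (0, 1080)

    def test_empty_input(self):
        assert nucrna_regions(make_tags([], SIZES)) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.tuples(hst.integers(0, 3000), hst.integers(1, 60)),
            min_size=0, max_size=60,
        ),
        hst.integers(0, 200),
        hst.integers(1, 500),
    )
    def test_matches_merge_filter_oracle(self, raw, gap, min_size):
        rows = [("chr1", s, s + l, "+") for s, l in raw]
        got = [(r.start, r.end) for r in nucrna_regions(make_tags(rows, {"chr1": 4000}), gap, min_size)]
        assert got == bf_merge([(s, s + l) for s, l in raw], gap, min_size)


class TestSubtract:
    def test_containment_and_boundary(self):
        inside = _peak(100, 300)
        outside = _peak(1001, 1200)
        region = [GenomicInterval("chr1", 0, 1000)]
        kept = subtract_transcribed([inside, outside], region)
        assert kept == [outside]

    def test_identities(self):
        peaks = [_peak(0, 100), _peak(500, 600)]
        assert subtract_transcribed(peaks, []) == peaks
        assert subtract_transcribed([], [GenomicInterval("chr1", 0, 10)]) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.tuples(hst.integers(0, 900), hst.integers(1, 80)), max_size=20),
        hst.lists(hst.tuples(hst.integers(0, 900), hst.integers(1, 80)), max_size=20),
    )
    def test_matches_all_pairs_oracle(self, peak_raw, region_raw):
        peaks = [_peak(s, s + l) for s, l in peak_raw]
        regions = [GenomicInterval("chr1", s, s + l) for s, l in region_raw]
        kept = subtract_transcribed(peaks, regions)
        expect = [
            p for p in peaks
            if not any(p.interval.overlaps(r) for r in regions)
        ]
        assert kept == expect


class TestPositional:
    GENES = [
        GeneModel("gp", GenomicInterval("chr1", 20_000, 25_000, "+"),
                  (GenomicInterval("chr1", 20_000, 25_000),)),
        GeneModel("gm", GenomicInterval("chr1", 60_000, 65_000, "-"),
                  (GenomicInterval("chr1", 60_000, 65_000),)),
    ]

    def test_trivial_classes(self):
        cands = positional_classify(
            [_peak(20_050, 20_150),  # midpoint at TSS+100
             _peak(22_000, 22_100),  # body
             _peak(90_000, 90_100)],  # far from anything
            self.GENES,
        )
        assert [c.positional_class for c in cands] == ["TSS", "gene_body", "intergenic"]

    def test_minus_strand_upstream_is_past_span_end(self):
        # 5 kb 5' of the "-" gene's TSS (TSS at 64_999) -> beyond span end
        (cand,) = positional_classify([_peak(69_950, 70_050)], self.GENES)
        assert cand.positional_class == "upstream_10kb"
        (cand,) = positional_classify([_peak(55_950, 56_050)], self.GENES)
        assert cand.positional_class == "downstream_10kb"

    def test_empty_annotation_all_intergenic(self):
        cands = positional_classify([_peak(100, 200), _peak(500, 700)], [])
        assert {c.positional_class for c in cands} == {"intergenic"}

    def test_fractions_sum_to_one_and_order_invariant(self):
        peaks = [_peak(i * 997, i * 997 + 100) for i in range(50)]
        a = positional_fractions(positional_classify(peaks, self.GENES))
        b = positional_fractions(positional_classify(peaks[::-1], self.GENES))
        assert sum(a.values()) == pytest.approx(1.0)
        assert a == b

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hst.lists(hst.integers(0, 99_000), min_size=1, max_size=30))
    def test_matches_precedence_oracle(self, starts):
        peaks = [_peak(s, s + 100) for s in starts]
        cands = positional_classify(peaks, self.GENES)
        for cand in cands:
            mid = cand.peak.interval.midpoint
            assert cand.positional_class == bf_positional(mid, "chr1", self.GENES)


class TestConservation:
    def test_planted_conserved_candidates_enriched(self):
        rng = np.random.default_rng(0)
        cons = {"chr1": rng.uniform(0, 0.5, 100_000)}
        cands = []
        for i in range(10):
            mid = 5000 + i * 9000
            cons["chr1"][mid - 150:mid + 150] = 0.95
            cands.append(CandidateRegion(_peak(mid - 100, mid + 100)))
        r = conservation_enrichment(cands, cons, SIZES, seed=1)
        assert r.log_odds > 1.0
        assert r.p < 0.01
        assert all(0.2 < c.conserved_fraction < 0.4 for c in cands)

    def test_null_log_odds_near_zero(self):
        # same generating process for candidates and random regions; use a
        # cutoff inside the background range so both sides have mass
        rng = np.random.default_rng(3)
        los = []
        for seed in range(10):
            cons = {"chr1": rng.uniform(0, 0.5, 100_000)}
            cands = [
                CandidateRegion(_peak(int(s), int(s) + 200))
                for s in rng.integers(1000, 99_000, 10)
            ]
            r = conservation_enrichment(cands, cons, SIZES, cut=0.25, seed=seed)
            los.append(r.log_odds)
        assert abs(np.mean(los)) < 0.05

    def test_random_regions_avoid_exclusions(self):
        rng = np.random.default_rng(5)
        exclude = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 5000) for i in range(10)]
        regions = sample_random_regions(50, 1000, SIZES, exclude, rng)
        assert len(regions) == 50
        for r in regions:
            assert not any(r.overlaps(e) for e in exclude)


class TestTfOverlap:
    def test_hand_built_bins(self):
        # 10-bin genome of 1 kb bins; candidates cover bins 0-1, TF covers
        # bins 1-2 and 7
        sizes = {"chr1": 10_000}
        cands = [CandidateRegion(_peak(0, 1500))]
        tf = {"TFx": [GenomicInterval("chr1", 1200, 2800), GenomicInterval("chr1", 7100, 7200)]}
        per, combined, subset = tf_overlap_enrichment(cands, tf, sizes)
        t = per["TFx"].table
        assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 6)
        assert combined.log_odds == per["TFx"].log_odds
        assert subset == cands

    def test_tf_on_candidates_gives_large_positive_log_odds(self):
        sizes = {"chr1": 100_000}
        cands = [CandidateRegion(_peak(i * 9000 + 4000, i * 9000 + 4200)) for i in range(10)]
        tf = {"TFa": [c.peak.interval for c in cands]}
        per, combined, subset = tf_overlap_enrichment(cands, tf, sizes)
        assert combined.log_odds > 3
        assert len(subset) == 10

    def test_empty_tf_set_skipped(self):
        cands = [CandidateRegion(_peak(100, 300))]
        per, combined, subset = tf_overlap_enrichment(cands, {"TFempty": []}, SIZES)
        assert per == {}
        assert combined is None
        assert subset == []
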