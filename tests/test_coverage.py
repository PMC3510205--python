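import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from helpers import bf_count_overlaps, bf_coverage, make_tags, make_track
from nucstate.coverage import (
    TagCollection,
    build_coverage,
    exon_intron_summary,
    exonic_fraction,
    fold_enrichment,
    rpkm,
    window_scores,
)
from nucstate.genome import AlignedTag, GeneModel, GenomicInterval

SIZES = {"chr1": 1000}


class TestBuildCoverage:
    def test_single_tag(self):
        cov = make_tags([("chr1", 100, 136, "+")], SIZES).coverage()
        assert cov.depth["chr1"][100:136].tolist() == [1] * 36
        assert cov.depth["chr1"].sum() == 36

    def test_duplicate_tags_stack(self):
        cov = make_tags([("chr1", 10, 46, "+")] * 2, SIZES).coverage()
        assert cov.depth["chr1"][10:46].tolist() == [2] * 36

    def test_depth_mass_equals_aligned_bases(self, default_dataset):
        for lib, tags in default_dataset["libs"].items():
            cov = default_dataset["tracks"][lib]
            total_len = sum(
                (tags.chrom_arrays(c)[1] - tags.chrom_arrays(c)[0]).sum()
                for c in tags.chrom_sizes
            )
            assert cov.total_mass() == total_len

    def test_tag_beyond_chrom_end_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            make_tags([("chr1", 990, 1026, "+")], SIZES)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.tuples(hst.integers(0, 460), hst.integers(1, 40)),
            min_size=0, max_size=40,
        )
    )
    def test_matches_per_base_oracle(self, raw):
        rows = [("chr1", s, s + l, "+") for s, l in raw]
        cov = make_tags(rows, {"chr1": 500}).coverage()
        assert np.array_equal(cov.depth["chr1"], bf_coverage(rows, 500))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.tuples(hst.integers(0, 460), hst.integers(1, 40)),
            min_size=0, max_size=40,
        ),
        hst.integers(0, 450),
        hst.integers(1, 50),
    )
    def test_overlap_count_matches_all_pairs_oracle(self, raw, rstart, rlen):
        rows = [("chr1", s, s + l, "+") for s, l in raw]
        tags = make_tags(rows, {"chr1": 500})
        region = GenomicInterval("chr1", rstart, rstart + rlen)
        assert tags.count_overlapping(region) == bf_count_overlaps(rows, region)


class TestFoldEnrichment:
    def test_simple_ratio_without_pseudocount(self):
        sample = make_track({"chr1": [0, 30, 10, 0]}, 1_000_000)
        inp = make_track({"chr1": [10, 10, 10, 10]}, 1_000_000)
        region = GenomicInterval("chr1", 0, 4)
        assert fold_enrichment(sample, inp, region, "max", 0.0) == pytest.approx(3.0)

    def test_identical_tracks_give_one(self):
        t = make_track({"chr1": [3, 7, 1, 9]}, 500_000)
        region = GenomicInterval("chr1", 0, 4)
        for eps in (0.0, 1.0, 5.0):
            assert fold_enrichment(t, t, region, "max", eps) == pytest.approx(1.0)
            assert fold_enrichment(t, t, region, "mean", eps) == pytest.approx(1.0)

    def test_zero_input_stabilised_by_pseudocount(self):
        sample = make_track({"chr1": [5, 5, 5, 5]}, 1_000_000)
        inp = make_track({"chr1": [0, 0, 0, 0]}, 1_000_000)
        region = GenomicInterval("chr1", 0, 4)
        assert fold_enrichment(sample, inp, region, "mean", 1.0) == pytest.approx(6.0)

    def test_invariant_to_duplicating_both_libraries(self, default_dataset):
        nuc = default_dataset["libs"]["nucRNA"]
        inp = default_dataset["libs"]["input"]

        def doubled(tags):
            per = {}
            for c in tags.chrom_sizes:
                s, e, st = tags.chrom_arrays(c)
                per[c] = (np.tile(s, 2), np.tile(e, 2), np.tile(st, 2))
            return TagCollection.from_arrays(tags.chrom_sizes, per)

        nuc2, inp2 = doubled(nuc).coverage(), doubled(inp).coverage()
        nuc1, inp1 = nuc.coverage(), inp.coverage()
        region = GenomicInterval("chr1", 0, 10_000)
        for stat in ("max", "mean"):
            assert fold_enrichment(nuc2, inp2, region, stat) == pytest.approx(
                fold_enrichment(nuc1, inp1, region, stat)
            )


class TestRpkm:
    def _gene(self, start=0, end=2000, strand="+"):
        return GeneModel(
            "g", GenomicInterval("chr1", start, end, strand),
            (GenomicInterval("chr1", start, start + 100),
             GenomicInterval("chr1", end - 100, end)),
        )

    def test_arithmetic(self):
        rows = [("chr1", i, i + 36, "+") for i in range(0, 1000)]
        # pad library to 10M mapped reads via a fake library_size
        tags = make_tags(rows, {"chr1": 5000})
        tags_size = tags.library_size
        assert tags_size == 1000
        gene = self._gene(0, 2000)
        # 1000 overlapping tags, 2 kb feature, library of 1000 tags:
        # rpkm = 1000 / 2 / 0.001 = 500000; rescale to the canonical example
        val = rpkm(gene, tags)
        assert val == pytest.approx(1000 / 2.0 / (1000 / 1e6))

    def test_no_tags_is_zero(self):
        tags = make_tags([("chr1", 4000, 4036, "+")], {"chr1": 5000})
        assert rpkm(self._gene(0, 2000), tags) == 0.0

    def test_exon1_is_strand_aware(self):
        rows = [("chr1", 1900, 1936, "+")] * 5 + [("chr1", 0, 36, "+")]
        tags = make_tags(rows, {"chr1": 5000})
        plus = rpkm(self._gene(strand="+"), tags, "exon1")
        minus = rpkm(self._gene(strand="-"), tags, "exon1")
        assert minus == pytest.approx(5 * plus)

    def test_zero_library_rejected(self):
        tags = make_tags([], {"chr1": 5000})
        with pytest.raises(ValueError):
            rpkm(self._gene(), tags)

    def test_replicate_rpkm_rank_correlation(self):
        """Two independent sequencing replicates of the same truth should
        rank genes almost identically."""
        from nucstate.stats import spearman_ci
        from nucstate.synthetic_data import SimConfig, build_genome, simulate_library_arrays

        ds = build_genome(SimConfig(seed=31))
        rep1 = simulate_library_arrays(ds, "nucRNA")
        ds2 = build_genome(SimConfig(seed=31))
        ds2.config.seed = 32  # same truth, fresh sampling noise
        rep2 = simulate_library_arrays(ds2, "nucRNA", ds2.config)
        x = [rpkm(g, rep1) for g in ds.genes]
        y = [rpkm(g, rep2) for g in ds.genes]
        assert spearman_ci(x, y).rho > 0.9


class TestWindowScores:
    def test_tiling_keeps_partial_window(self):
        zero = make_track({"chr1": np.zeros(25_000, dtype=np.int64)}, 1000)
        scores = window_scores(zero, zero, zero, 10_000)
        coords = [(s.region.start, s.region.end, s.partial) for s in scores]
        assert coords == [(0, 10_000, False), (10_000, 20_000, False), (20_000, 25_000, True)]

    def test_all_zero_tracks_score_one(self):
        zero = make_track({"chr1": np.zeros(25_000, dtype=np.int64)}, 1000)
        for s in window_scores(zero, zero, zero, 10_000):
            assert s.nucRNA_score == pytest.approx(1.0)
            assert s.RNAPII_score == pytest.approx(1.0)

    def test_invalid_window(self):
        zero = make_track({"chr1": np.zeros(100, dtype=np.int64)}, 1)
        with pytest.raises(ValueError):
            window_scores(zero, zero, zero, 0)

    def test_planted_bt_window_beats_genome_median(self, default_dataset):
        ds = default_dataset["dataset"]
        scores = window_scores(
            default_dataset["tracks"]["nucRNA"],
            default_dataset["tracks"]["RNAPII"],
            default_dataset["tracks"]["input"],
            genes=ds.genes,
        )
        med_nuc = np.median([s.nucRNA_score for s in scores])
        med_pol = np.median([s.RNAPII_score for s in scores])
        bt = [t for t in ds.truth if t.planted_class == "BT" and t.feature_kind == "gene"]
        for t in bt:
            hits = [
                s for s in scores
                if s.region.chrom == t.interval.chrom and s.region.overlaps(t.interval)
            ]
            assert max(s.nucRNA_score for s in hits) > med_nuc
            assert max(s.RNAPII_score for s in hits) > med_pol


class TestExonIntron:
    def _gene(self):
        return GeneModel(
            "g", GenomicInterval("chr1", 0, 300, "+"),
            (GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)),
        )

    def test_uniform_depth_means_equal(self):
        track = make_track({"chr1": np.full(300, 4, dtype=np.int64)}, 100)
        r = exon_intron_summary(self._gene(), track)
        assert r["exonic_mean"] == pytest.approx(4.0)
        assert r["intronic_mean"] == pytest.approx(4.0)
        for third in r["thirds"]:
            for key in ("exonic_mean", "intronic_mean"):
                if not np.isnan(third[key]):
                    assert third[key] == pytest.approx(4.0)

    def test_fully_spliced_introns_zero(self):
        depth = np.zeros(300, dtype=np.int64)
        depth[:100] = 3
        depth[200:] = 3
        track = make_track({"chr1": depth}, 100)
        r = exon_intron_summary(self._gene(), track)
        assert r["intronic_mean"] == 0.0
        assert r["exonic_mean"] == pytest.approx(3.0)

    def test_third_without_introns_is_nan_not_zero(self):
        gene = GeneModel(
            "g", GenomicInterval("chr1", 0, 300, "+"),
            (GenomicInterval("chr1", 0, 150), GenomicInterval("chr1", 200, 300)),
        )
        track = make_track({"chr1": np.ones(300, dtype=np.int64)}, 100)
        r = exon_intron_summary(gene, track)
        assert np.isnan(r["thirds"][0]["intronic_mean"])

    def test_minus_strand_five_prime_third_is_span_end(self):
        depth = np.zeros(300, dtype=np.int64)
        depth[200:] = 9  # high coverage at span end
        gene = GeneModel(
            "g", GenomicInterval("chr1", 0, 300, "-"),
            (GenomicInterval("chr1", 0, 300),),
        )
        r = exon_intron_summary(gene, make_track({"chr1": depth}, 100))
        assert r["thirds"][0]["third"] == "five_prime"
        assert r["thirds"][0]["exonic_mean"] == pytest.approx(9.0)

    def test_exonic_fraction_monotone_in_splicing(self):
        from nucstate.synthetic_data import SimConfig, build_genome, simulate_library_arrays

        fracs = []
        for s in (0.0, 0.5, 0.9):
            cfg = SimConfig(seed=12, splicing_fraction=s, n_lncrna=0,
                            n_lncrna_decoys=0, input_artifact=False)
            ds = build_genome(cfg)
            cov = simulate_library_arrays(ds, "nucRNA").coverage()
            fracs.append(exonic_fraction(cov, ds.genes))
        assert fracs[0] < fracs[1] < fracs[2]
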