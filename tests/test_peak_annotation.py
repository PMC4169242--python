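"""Peak-gene association, feature classification, and the random-placement null."""

import numpy as np
import pytest

from regloop.genomics_core import GeneModel, GenomeLayout, GenomicInterval, PeakSet
from regloop.peak_annotation import (
    CATEGORIES,
    associate_peaks_to_genes,
    classify_peak_features,
    feature_enrichment,
    random_peak_set,
)


class TestAssociation:
    def test_gap_boundary(self, three_genes):
        near = PeakSet([GenomicInterval("chr1", 3_999, 4_100)])  # gap 900 to gA
        fwd, inv = associate_peaks_to_genes(near, three_genes, flank=1000)
        assert fwd["peak_1"] == {"gA"}
        far = PeakSet([GenomicInterval("chr1", 2_000, 3_999)])  # gap 1001
        fwd, _ = associate_peaks_to_genes(far, three_genes, flank=1000)
        assert fwd["peak_1"] == set()

    def test_overlapping_peak_gap_zero(self, three_genes):
        inside = PeakSet([GenomicInterval("chr1", 5_200, 5_300)])
        fwd, _ = associate_peaks_to_genes(inside, three_genes)
        assert fwd["peak_1"] == {"gA"}

    def test_forward_and_inverse_maps_consistent(self, small_genome):
        rng = np.random.default_rng(0)
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", s, s + 500), "+")
            for i, s in enumerate(range(1_000, 90_000, 4_000))
        ]
        starts = np.sort(rng.choice(np.arange(0, 95_000, 120), 60, replace=False))
        peaks = PeakSet([GenomicInterval("chr1", int(s), int(s) + 100) for s in starts])
        fwd, inv = associate_peaks_to_genes(peaks, genes)
        pairs_fwd = {(p, g) for p, gs in fwd.items() for g in gs}
        pairs_inv = {(p, g) for g, ps in inv.items() for p in ps}
        assert pairs_fwd == pairs_inv
        # independent gap check on every pair
        by_pid = {f"peak_{i + 1}": iv for i, iv in enumerate(peaks)}
        by_gid = {g.gene_id: g.span for g in genes}
        for pid, iv in by_pid.items():
            for g in genes:
                gap = max(g.span.start - iv.end, iv.start - g.span.end, 0)
                assert ((pid, g.gene_id) in pairs_fwd) == (gap <= 1000)


class TestClassification:
    def test_peak_in_gene_and_upstream_of_next(self, small_genome):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 5_000, 6_000), "+"),
            GeneModel("g2", GenomicInterval("chr1", 6_500, 7_500), "+"),
        ]
        # covers g1 body tail and g2's 1 kb upstream flank [5500,6500)
        peaks = PeakSet([GenomicInterval("chr1", 5_900, 6_200)])
        counts = classify_peak_features(peaks, genes, small_genome)
        assert counts["genes"] == 1
        assert counts["upstream"] == 1
        assert counts["intergenic"] == 0

    def test_far_peak_is_intergenic_only(self, small_genome, three_genes):
        peaks = PeakSet([GenomicInterval("chr1", 50_000, 50_500)])
        counts = classify_peak_features(peaks, three_genes, small_genome)
        assert counts == {"upstream": 0, "downstream": 0, "genes": 0, "intergenic": 1}

    def test_strand_aware_flanks(self, small_genome):
        minus = [GeneModel("gm", GenomicInterval("chr1", 10_000, 12_000), "-")]
        right = PeakSet([GenomicInterval("chr1", 12_100, 12_200)])  # 3' side in + orientation
        counts = classify_peak_features(right, minus, small_genome)
        assert counts["upstream"] == 1 and counts["downstream"] == 0
        left = PeakSet([GenomicInterval("chr1", 9_100, 9_200)])
        counts = classify_peak_features(left, minus, small_genome)
        assert counts["downstream"] == 1 and counts["upstream"] == 0

    def test_whole_chromosome_gene(self):
        genome = GenomeLayout([("chr1", 10_000)])
        genes = [GeneModel("g", GenomicInterval("chr1", 0, 10_000), "+")]
        peaks = PeakSet([GenomicInterval("chr1", 2_000, 2_500)])
        counts = classify_peak_features(peaks, genes, genome)
        assert counts["genes"] == 1 and counts["intergenic"] == 0


class TestRandomPeakSet:
    def test_preserves_size_length_and_chromosome(self, small_genome):
        rng = np.random.default_rng(1)
        peaks = PeakSet(
            [GenomicInterval("chr1", 100, 1_100), GenomicInterval("chr1", 5_000, 5_300),
             GenomicInterval("chr2", 0, 2_000)]
        )
        rand = random_peak_set(peaks, small_genome, rng)
        assert len(rand) == len(peaks)
        for chrom in ("chr1", "chr2"):
            orig = sorted(iv.length for iv in peaks if iv.chrom == chrom)
            new = sorted(iv.length for iv in rand if iv.chrom == chrom)
            assert orig == new
        for iv in rand:
            assert 0 <= iv.start and iv.end <= small_genome.length_of(iv.chrom)

    def test_same_rng_state_identical(self, small_genome):
        peaks = PeakSet([GenomicInterval("chr1", 100, 1_100)])
        a = random_peak_set(peaks, small_genome, np.random.default_rng(7))
        b = random_peak_set(peaks, small_genome, np.random.default_rng(7))
        assert a == b

    def test_uniform_start_mean(self):
        genome = GenomeLayout([("chr1", 1_000_000)])
        peaks = PeakSet([GenomicInterval("chr1", 0, 1_000)])
        rng = np.random.default_rng(2)
        starts = [random_peak_set(peaks, genome, rng).intervals[0].start for _ in range(1000)]
        expected_mean = (1_000_000 - 1_000) / 2
        se = (1_000_000 - 1_000) / np.sqrt(12 * 1000)
        assert abs(np.mean(starts) - expected_mean) < 3 * se

    def test_disjoint_mode(self, small_genome):
        peaks = PeakSet([GenomicInterval("chr1", i * 3_000, i * 3_000 + 2_000) for i in range(10)])
        rng = np.random.default_rng(3)
        rand = random_peak_set(peaks, small_genome, rng, disjoint=True)
        arr = sorted((iv.start, iv.end) for iv in rand)
        for (s1, e1), (s2, e2) in zip(arr, arr[1:]):
            assert e1 <= s2


class TestFeatureEnrichment:
    def _upstream_only_setup(self):
        genome = GenomeLayout([("chr1", 1_000_000)])
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", s, s + 2_000), "+")
            for i, s in enumerate(range(10_000, 990_000, 10_000))
        ]
        peaks = []
        for g in genes[:90]:
            start = g.span.start - 800
            peaks.append(GenomicInterval("chr1", start, start + 400))
        peaks.sort(key=lambda iv: iv.start)
        return genome, genes, PeakSet(peaks)

    def test_planted_upstream_peaks_give_large_upstream_z(self):
        genome, genes, peaks = self._upstream_only_setup()
        res = feature_enrichment(peaks, genes, genome, n_sim=200, seed=1)
        assert res.table.loc["upstream", "z_score"] > 3
        assert res.table.loc["upstream", "empirical_p"] == pytest.approx(1 / 201)

    def test_empirical_p_floor(self):
        genome, genes, peaks = self._upstream_only_setup()
        res = feature_enrichment(peaks, genes, genome, n_sim=200, seed=2)
        assert (res.table["empirical_p"] >= 1 / 201).all()
        assert (res.table["observed_frequency"] <= 1).all()
        assert (res.table["observed_frequency"] >= 0).all()

    def test_degenerate_when_features_cover_genome(self):
        genome = GenomeLayout([("chr1", 10_000)])
        genes = [GeneModel("g", GenomicInterval("chr1", 0, 10_000), "+")]
        peaks = PeakSet([GenomicInterval("chr1", 100, 200)])
        res = feature_enrichment(peaks, genes, genome, n_sim=50, seed=0)
        row = res.table.loc["genes"]
        assert row["observed_frequency"] == 1.0
        assert row["degenerate"] and row["z_score"] == 0.0

    def test_null_peaks_are_calibrated(self, small_genome, three_genes):
        """Peaks drawn from the null itself rarely produce |z| > 3."""
        rng = np.random.default_rng(5)
        base = PeakSet(
            [GenomicInterval("chr1", i * 4_000, i * 4_000 + 700) for i in range(20)]
        )
        bad = 0
        trials = 30
        for t in range(trials):
            rand = random_peak_set(base, small_genome, rng)
            res = feature_enrichment(rand, three_genes, small_genome, n_sim=100, seed=100 + t)
            if (res.table["z_score"].abs() > 3).any():
                bad += 1
        assert bad <= max(2, 0.05 * trials)
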