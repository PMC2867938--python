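"""Extragenic curation: summits, filtering rules, regulation classes,
clustering, and the fallback Poisson peak caller."""

import numpy as np
import pytest
from scipy.special import comb

from enhancerscan.genome_io import GeneModel, GenomicInterval, TagTrack
from enhancerscan.peaks import (
    PolIIPeak,
    annotate_peaks,
    call_peaks,
    classify_regulation,
    cluster_and_filter,
    filter_extragenic,
    find_summit,
)

from conftest import random_intervals


def _gene(gid, chrom, start, end, strand="+", coding=True):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), coding)


class TestFindSummit:
    def test_point_pile(self):
        track = TagTrack({"chr1": np.full(20, 1500)})
        assert find_summit(track, GenomicInterval("chr1", 1000, 2000)) == 1500

    def test_empty_signal_returns_midpoint(self):
        assert (
            find_summit(TagTrack(), GenomicInterval("chr1", 1000, 2000)) == 1500
        )

    def test_matches_per_base_scan_oracle(self, rng):
        for _ in range(20):
            pos = np.sort(rng.integers(900, 2100, size=200))
            track = TagTrack({"chr1": pos})
            iv = GenomicInterval("chr1", 1000, 2000)
            smooth = int(rng.integers(1, 120))
            counts = []
            for p in range(iv.start, iv.end):
                lo = p - smooth // 2
                counts.append(int(np.sum((pos >= lo) & (pos < lo + smooth))))
            best = max(counts)
            i = counts.index(best)
            j = i
            while j + 1 < len(counts) and counts[j + 1] == best:
                j += 1
            expected = (iv.start + i + iv.start + j) // 2
            assert find_summit(track, iv, smooth) == expected


class TestFilterExtragenic:
    GENES = [_gene("gA", "chr1", 50_000, 70_000, "+")]

    def test_gene_body_overlap_removed(self):
        peak = GenomicInterval("chr1", 60_000, 61_000)
        kept, rejected = filter_extragenic([peak], self.GENES)
        assert kept == [] and rejected[0][1] == "gene_body_overlap"

    def test_3prime_flank_removed(self):
        # 5 kb downstream of the + strand 3' end (70_000)
        peak = GenomicInterval("chr1", 75_000, 75_500)
        kept, rejected = filter_extragenic([peak], self.GENES)
        assert kept == [] and rejected[0][1] == "3prime_flank"

    def test_minus_strand_flank_is_upstream_in_coordinates(self):
        genes = [_gene("gB", "chr1", 50_000, 70_000, "-")]
        peak = GenomicInterval("chr1", 45_000, 45_400)  # 3' end is start=50_000
        kept, rejected = filter_extragenic([peak], genes)
        assert kept == [] and rejected[0][1] == "3prime_flank"

    def test_far_peak_without_coverage_retained(self):
        peak = GenomicInterval("chr1", 85_000, 86_000)  # 15 kb downstream
        kept, _ = filter_extragenic([peak], self.GENES, TagTrack())
        assert kept == [peak]

    def test_readthrough_continuity_removed(self):
        peak = GenomicInterval("chr1", 85_000, 86_000)
        # continuous coverage every 300 bp from gene 3' end to the peak
        fill = np.arange(60_000, 85_000, 300)
        track = TagTrack({"chr1": fill})
        kept, rejected = filter_extragenic(
            [peak], self.GENES, track, continuity_gap_bp=500
        )
        assert kept == [] and rejected[0][1] == "upstream_continuity"
        # a 2 kb hole in coverage breaks continuity
        holed = fill[(fill < 75_000) | (fill > 77_000)]
        kept, _ = filter_extragenic(
            [peak], self.GENES, TagTrack({"chr1": holed}), continuity_gap_bp=500
        )
        assert kept == [peak]

    def test_no_residual_overlap_with_bodies_or_flanks(self, rng):
        genes = [
            _gene(f"g{i}", "chr1", s, s + 5_000, "+" if i % 2 else "-")
            for i, s in enumerate(range(0, 500_000, 40_000))
        ]
        peaks = random_intervals(rng, 200, max_start=500_000, max_len=2_000)
        kept, _ = filter_extragenic(peaks, genes)
        flanks = []
        for g in genes:
            iv = g.interval
            if iv.strand == "+":
                flanks.append(GenomicInterval("chr1", iv.end - 1, iv.end + 10_000))
            else:
                flanks.append(GenomicInterval("chr1", max(0, iv.start - 10_000), iv.start + 1))
        for p in kept:
            assert not any(p.overlaps(g.interval) for g in genes)
            assert not any(p.overlaps(f) for f in flanks)


def _binom_two_sided_oracle(k, n, q):
    """Exact two-sided binomial p by direct summation over outcomes."""
    pmf = [comb(n, i, exact=True) * (q**i) * ((1 - q) ** (n - i)) for i in range(n + 1)]
    pk = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= pk * (1 + 1e-12)))


class TestClassifyRegulation:
    def test_symmetric_counts_constitutive(self):
        label, p = classify_regulation(50, 50, 1_000_000, 1_000_000)
        assert label == "constitutive" and p > 0.9

    def test_inducible_and_p_matches_exact_summation(self):
        label, p = classify_regulation(2, 40, 1_000_000, 1_000_000)
        assert label == "inducible"
        assert p == pytest.approx(_binom_two_sided_oracle(40, 42, 0.5), rel=1e-9)

    def test_repressed_mirror(self):
        label, _ = classify_regulation(40, 2, 1_000_000, 1_000_000)
        assert label == "repressed"

    def test_antisymmetric_under_condition_swap(self, rng):
        lib_ut, lib_lps = 800_000, 1_200_000
        flips = {"inducible": "repressed", "repressed": "inducible",
                 "constitutive": "constitutive"}
        for _ in range(50):
            a, b = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            fwd, _ = classify_regulation(a, b, lib_ut, lib_lps)
            rev, _ = classify_regulation(b, a, lib_lps, lib_ut)
            assert rev == flips[fwd]

    def test_p_matches_oracle_on_small_counts(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(0, n + 1))
            lib_ut = int(rng.integers(10_000, 100_000))
            lib_lps = int(rng.integers(10_000, 100_000))
            q = lib_lps / (lib_ut + lib_lps)
            _, p = classify_regulation(n - k, k, lib_ut, lib_lps)
            assert p == pytest.approx(_binom_two_sided_oracle(k, n, q), abs=1e-12)

    def test_planted_fold_recovery(self, rng):
        """>= 90 % correct labels at planted fold 4, mean 60 tags."""
        lib = 1_000_000
        correct = 0
        n_trials = 300
        for i in range(n_trials):
            if i % 2 == 0:
                ut, lps = rng.poisson(15), rng.poisson(60)
                want = "inducible"
            else:
                ut, lps = rng.poisson(60), rng.poisson(60)
                want = "constitutive"
            got, _ = classify_regulation(int(ut), int(lps), lib, lib)
            correct += got == want
        assert correct / n_trials >= 0.90


class TestClusterAndFilter:
    def _peak(self, start, end, reg="constitutive", sig="enhancer"):
        iv = GenomicInterval("chr1", start, end)
        return PolIIPeak(iv, (start + end) // 2, 10, 10, reg, 0.5, sig)

    def test_two_peaks_merge_within_gap(self):
        peaks = [self._peak(1_000, 2_000), self._peak(3_000, 3_500)]
        clusters = cluster_and_filter(peaks, [], cluster_gap_bp=2_000)
        assert len(clusters) == 1 and len(clusters[0].member_peaks) == 2
        assert (clusters[0].interval.start, clusters[0].interval.end) == (1_000, 3_500)

    def test_protein_coding_overlap_discarded(self):
        peaks = [self._peak(1_000, 2_000)]
        coding = [_gene("gC", "chr1", 1_500, 9_000)]
        assert cluster_and_filter(peaks, coding) == []
        noncoding = [_gene("gN", "chr1", 1_500, 9_000, coding=False)]
        assert len(cluster_and_filter(peaks, noncoding)) == 1

    def test_majority_and_tie_rules(self):
        peaks = [
            self._peak(1_000, 2_000, "inducible", "enhancer"),
            self._peak(2_100, 3_000, "inducible", "promoter"),
            self._peak(3_100, 4_000, "repressed", "enhancer"),
        ]
        (cluster,) = cluster_and_filter(peaks, [], cluster_gap_bp=500)
        assert cluster.regulation == "inducible"
        assert cluster.signature_class == "enhancer"
        # 1-1 tie in regulation -> constitutive; class tie -> unpredictable
        peaks2 = [
            self._peak(1_000, 2_000, "inducible", "enhancer"),
            self._peak(2_100, 3_000, "repressed", "promoter"),
        ]
        (cluster2,) = cluster_and_filter(peaks2, [], cluster_gap_bp=500)
        assert cluster2.regulation == "constitutive"
        assert cluster2.signature_class == "unpredictable"

    def test_partition_matches_merge_oracle(self, rng):
        ivs = random_intervals(rng, 80, max_start=50_000, max_len=800)
        peaks = [
            PolIIPeak(iv, iv.midpoint, 1, 1, "constitutive", 1.0) for iv in ivs
        ]
        clusters = cluster_and_filter(peaks, [], cluster_gap_bp=300)
        from enhancerscan.genome_io import merge_intervals

        merged = merge_intervals(ivs, 300)
        got = sorted((c.interval.chrom, c.interval.start, c.interval.end) for c in clusters)
        want = sorted((m.chrom, m.start, m.end) for m in merged)
        assert got == want
        assert sum(len(c.member_peaks) for c in clusters) == len(peaks)


class TestCallPeaks:
    def test_recovers_planted_pile(self, rng):
        background = rng.integers(0, 1_000_000, size=500)
        pile = rng.normal(400_000, 200, size=300).astype(np.int64)
        track = TagTrack({"chr1": np.sort(np.concatenate([background, pile]))})
        peaks = call_peaks(track, {"chr1": 1_000_000})
        assert any(p.start <= 400_000 < p.end for p in peaks)
        assert len(peaks) <= 3

    def test_uniform_noise_yields_few_calls(self, rng):
        track = TagTrack({"chr1": np.sort(rng.integers(0, 1_000_000, size=1_000))})
        assert len(call_peaks(track, {"chr1": 1_000_000})) <= 1


class TestAnnotatePeaks:
    def test_counts_and_labels(self):
        filler = np.arange(100_000, 100_000 + 960)  # equalize library depth
        ut = TagTrack({"chr1": np.sort(np.r_[np.full(5, 1_500), filler[:995]])})
        lps = TagTrack({"chr1": np.sort(np.r_[np.full(40, 1_500), filler[:960]])})
        (peak,) = annotate_peaks([GenomicInterval("chr1", 1_000, 2_000)], ut, lps)
        assert (peak.tags_ut, peak.tags_lps) == (5, 40)
        assert peak.summit == 1_500
        assert peak.regulation == "inducible"
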