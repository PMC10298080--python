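"""Incidence track, top-percentile threshold, island merging and gene overlap."""

import math

import numpy as np
import pytest

from rohscan.caller import ROHSegment
from rohscan.islands import (
    GeneFeature,
    IncidenceTrack,
    annotate_islands,
    build_islands,
    incidence_track,
    read_genes_bed,
    read_genes_gff3,
    top_percentile_threshold,
)


def seg(sample, start, end, chrom="1"):
    return ROHSegment(sample, chrom, start, end, 25)


def track_from(values, positions=None, chrom="1", n=100):
    values = np.asarray(values, dtype=float)
    pos = np.asarray(positions if positions is not None else (np.arange(len(values)) + 1) * 1000)
    return IncidenceTrack(
        n_individuals=n,
        positions={chrom: pos.astype(np.int64)},
        n_covered={chrom: np.round(values * n).astype(np.int32)},
    )


class TestIncidenceTrack:
    def test_snp_covered_in_every_sample(self):
        samples = [f"s{i}" for i in range(22)]
        segs = [seg(s, 1, 2000) for s in samples]
        t = incidence_track(segs, {"1": np.array([1500])}, samples)
        assert t.incidence["1"].tolist() == [1.0]

    def test_snp_covered_in_half_the_samples(self):
        samples = [f"s{i}" for i in range(22)]
        segs = [seg(s, 1, 2000) for s in samples[:11]]
        t = incidence_track(segs, {"1": np.array([1500])}, samples)
        assert t.incidence["1"].tolist() == [0.5]

    def test_individual_counts_once_despite_multiple_segments(self):
        # disjoint segments of one sample cannot both cover one SNP, but a
        # point covered by any of them still counts that sample exactly once
        samples = ["a", "b"]
        segs = [seg("a", 1, 2000), seg("a", 5000, 9000)]
        t = incidence_track(segs, {"1": np.array([1500, 6000])}, samples)
        assert t.incidence["1"].tolist() == [0.5, 0.5]

    def test_empty_population_is_error(self):
        with pytest.raises(ValueError, match="empty population"):
            incidence_track([], {"1": np.array([100])}, [])

    def test_matches_brute_force_membership_scan(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(8)]
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=200, replace=False))
        segs = []
        for s in samples:
            cursor = 1
            for _ in range(rng.integers(0, 5)):
                start = cursor + int(rng.integers(0, 20_000))
                end = start + int(rng.integers(500, 15_000))
                segs.append(seg(s, start, end))
                cursor = end + 2
        t = incidence_track(segs, {"1": pos}, samples)
        for j, p in enumerate(pos):
            n_cov = sum(
                1
                for s in samples
                if any(x.sample_id == s and x.start_bp <= p <= x.end_bp for x in segs)
            )
            assert t.n_covered["1"][j] == n_cov


class TestTopPercentileThreshold:
    def test_distinct_values_flag_exactly_top_fraction(self):
        vals = np.arange(1, 1001) / 1000.0
        t = track_from(np.random.default_rng(0).permutation(vals), n=1000)
        cutoff = top_percentile_threshold(t, 0.01)
        flagged = t.all_incidences() >= cutoff
        assert flagged.sum() == 10
        assert cutoff == pytest.approx(0.991)  # 10th-largest value

    def test_all_equal_values_flag_everything(self):
        t = track_from([0.4] * 50, n=10)
        cutoff = top_percentile_threshold(t, 0.01)
        assert (t.all_incidences() >= cutoff).sum() == 50

    def test_matches_sort_and_slice_with_tie_expansion(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            vals = rng.integers(0, 12, size=rng.integers(5, 300)) / 12.0
            t = track_from(vals, n=12)
            cutoff = top_percentile_threshold(t, 0.01)
            srt = np.sort(vals)[::-1]
            k = max(1, math.ceil(0.01 * len(vals)))
            brute_cutoff = srt[k - 1]
            assert cutoff == pytest.approx(brute_cutoff)
            assert set(np.flatnonzero(vals >= cutoff)) == set(
                np.flatnonzero(vals >= brute_cutoff)
            )

    def test_flagged_count_never_below_top_fraction(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            vals = rng.integers(0, 8, size=rng.integers(3, 500)) / 8.0
            t = track_from(vals, n=8)
            cutoff = top_percentile_threshold(t, 0.01)
            assert (vals >= cutoff).sum() >= math.ceil(0.01 * len(vals))


class TestBuildIslands:
    def test_gap_splits_islands(self):
        t = track_from([1.0, 1.0, 1.0, 1.0], positions=[1_000_000, 1_100_000, 1_200_000, 5_000_000])
        islands = build_islands(t, cutoff=0.5, merge_gap_bp=1_000_000)
        assert [(i.start_bp, i.end_bp, i.n_snps) for i in islands] == [
            (1_000_000, 1_200_000, 3),
            (5_000_000, 5_000_000, 1),
        ]

    def test_single_flagged_snp_is_an_island(self):
        t = track_from([0.1, 0.9, 0.1])
        islands = build_islands(t, cutoff=0.5)
        assert len(islands) == 1 and islands[0].n_snps == 1

    def test_matches_linear_scan_oracle_and_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 400))
            pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=n, replace=False))
            vals = rng.integers(0, 10, size=n) / 10.0
            t = track_from(vals, positions=pos, n=10)
            cutoff = 0.7
            gap = 500_000
            islands = build_islands(t, cutoff, gap)
            # brute force: walk flagged indices
            flagged = [j for j in range(n) if vals[j] >= cutoff]
            runs = []
            for j in flagged:
                if runs and pos[j] - runs[-1][-1][1] <= gap:
                    runs[-1].append((j, pos[j]))
                else:
                    runs.append([(j, pos[j])])
            assert len(islands) == len(runs)
            total_snps = 0
            prev_end = -1
            for isl, run in zip(islands, runs):
                assert isl.start_bp == run[0][1] and isl.end_bp == run[-1][1]
                assert isl.n_snps == len(run)
                assert isl.start_bp > prev_end  # disjoint, sorted
                prev_end = isl.end_bp
                total_snps += isl.n_snps
            assert total_snps == len(flagged)  # union of islands = flagged set


class TestAnnotateIslands:
    ISLAND = build_islands(track_from([1.0, 1.0], positions=[1_000_000, 2_000_000]), 0.5)

    def annotate(self, genes, **kw):
        return annotate_islands(self.ISLAND, genes, **kw)[0].gene_ids

    def test_gene_inside_island_reported(self):
        assert self.annotate([GeneFeature("g", "1", 1_200_000, 1_500_000)]) == ["g"]

    def test_gene_ending_just_before_island_not_reported(self):
        assert self.annotate([GeneFeature("g", "1", 900_000, 999_999)]) == []

    def test_gene_straddling_boundary_reported(self):
        assert self.annotate([GeneFeature("g", "1", 900_000, 1_000_000)]) == ["g"]

    def test_containment_mode_excludes_straddlers(self):
        genes = [
            GeneFeature("in", "1", 1_100_000, 1_300_000),
            GeneFeature("straddle", "1", 900_000, 1_200_000),
        ]
        assert self.annotate(genes) == ["in", "straddle"]
        assert self.annotate(genes, require_containment=True) == ["in"]

    def test_wrong_chromosome_not_reported(self):
        assert self.annotate([GeneFeature("g", "2", 1_000_000, 2_000_000)]) == []


class TestGeneReaders:
    def test_gff3_gene_features(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t500\t.\t+\t.\tID=geneA;Name=A\n"
            "1\tsrc\texon\t100\t200\t.\t+\t.\tID=exon1\n"
            "2\tsrc\tgene\t300\t900\t.\t-\t.\tID=geneB\n"
        )
        genes = read_genes_gff3(p)
        assert [(g.gene_id, g.chrom, g.start_bp, g.end_bp) for g in genes] == [
            ("geneA", "1", 100, 500),
            ("geneB", "2", 300, 900),
        ]

    def test_malformed_gff3_record_lists_offender(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("1\tsrc\tgene\t500\t100\t.\t+\t.\tID=geneA\n")
        with pytest.raises(ValueError, match="line 1"):
            read_genes_gff3(p)

    def test_bed_coordinates_convert_to_one_based(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("1\t999\t2000\tgeneA\t0\t+\n")
        (g,) = read_genes_bed(p)
        assert (g.start_bp, g.end_bp, g.strand) == (1000, 2000, "+")
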