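"""Coverage-feature extraction and pooled site merging."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from apadiff.discovery import (
    CoverageFeature,
    extract_coverage_features,
    pool_and_merge,
)
from apadiff.intervals import GenomicInterval
from tests.conftest import write_bam


def feature(start, end, strand="+", sample="s1", peak=1, chrom="c1"):
    return CoverageFeature(GenomicInterval(chrom, start, end, strand), sample, peak)


class TestExtractCoverageFeatures:
    def test_stacked_reads_form_one_feature_with_peak_depth(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", {"c1": 1000},
                        [("c1", 100, 10, "+")] * 3)
        with pysam.AlignmentFile(bam) as fh:
            feats = extract_coverage_features(fh, "s1", min_depth=1)
        assert len(feats) == 1
        f = feats[0]
        assert (f.interval.start, f.interval.end, f.interval.strand) == (100, 110, "+")
        assert f.peak_depth == 3

    def test_min_depth_threshold_excludes_shallow_bases(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", {"c1": 1000},
                        [("c1", 100, 10, "+")] * 3)
        with pysam.AlignmentFile(bam) as fh:
            assert extract_coverage_features(fh, "s1", min_depth=4) == []

    def test_disjoint_loci_give_separate_features(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", {"c1": 1000},
                        [("c1", 100, 10, "+"), ("c1", 500, 10, "+")])
        with pysam.AlignmentFile(bam) as fh:
            feats = extract_coverage_features(fh, "s1")
        assert len(feats) == 2

    def test_strands_are_separated_and_strandness_flips(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", {"c1": 1000},
                        [("c1", 100, 10, "+"), ("c1", 105, 10, "-")])
        with pysam.AlignmentFile(bam) as fh:
            feats = extract_coverage_features(fh, "s1")
            strands = sorted(f.interval.strand for f in feats)
            assert strands == ["+", "-"]
            flipped = extract_coverage_features(fh, "s1", strandness="reverse")
        by_start = {f.interval.start: f.interval.strand for f in flipped}
        assert by_start[100] == "-" and by_start[105] == "+"

    def test_matches_per_base_pileup_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        reads = [("c1", int(s), 10, "+") for s in rng.integers(0, 200, size=40)]
        bam = write_bam(tmp_path / "a.bam", {"c1": 1000}, reads)
        depth = np.zeros(1000, int)
        for _, s, ln, _ in reads:
            depth[s:s + ln] += 1
        with pysam.AlignmentFile(bam) as fh:
            feats = extract_coverage_features(fh, "s1", min_depth=2)
        rebuilt = np.zeros(1000, bool)
        for f in feats:
            assert depth[f.interval.start:f.interval.end].min() >= 2
            assert depth[f.interval.start:f.interval.end].max() == f.peak_depth
            rebuilt[f.interval.start:f.interval.end] = True
        assert np.array_equal(rebuilt, depth >= 2)


class TestPoolAndMerge:
    def test_gap_within_md_merges_to_union(self):
        lib = pool_and_merge([feature(100, 110), feature(115, 125)], md=10)
        assert len(lib) == 1
        iv = lib.sites[0].interval
        assert (iv.start, iv.end) == (100, 125)

    def test_gap_beyond_md_stays_separate(self):
        lib = pool_and_merge([feature(100, 110), feature(115, 125)], md=4)
        assert len(lib) == 2

    def test_single_feature_is_identity(self):
        lib = pool_and_merge([feature(100, 110)], md=50)
        assert len(lib) == 1
        assert (lib.sites[0].interval.start, lib.sites[0].interval.end) == (100, 110)

    def test_different_strands_never_merge(self):
        lib = pool_and_merge([feature(100, 110, "+"), feature(105, 120, "-")], md=25)
        assert len(lib) == 2

    def test_transitive_chains_collapse(self):
        feats = [feature(0, 10), feature(15, 25), feature(30, 40)]
        lib = pool_and_merge(feats, md=5)
        assert len(lib) == 1
        assert (lib.sites[0].interval.start, lib.sites[0].interval.end) == (0, 40)

    def test_merge_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        feats = [feature(int(s), int(s) + int(w), sample=f"s{i % 3}")
                 for i, (s, w) in enumerate(zip(rng.integers(0, 500, 60),
                                                rng.integers(1, 30, 60)))]
        lib = pool_and_merge(feats, md=7)
        spans = [(s.interval.start, s.interval.end) for s in lib]
        again = pool_and_merge(
            [feature(a, b) for a, b in spans], md=7)
        assert [(s.interval.start, s.interval.end) for s in again] == spans
        shuffled = list(feats)
        rng.shuffle(shuffled)
        lib2 = pool_and_merge(shuffled, md=7)
        assert [(s.interval.start, s.interval.end) for s in lib2] == spans

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 40)),
            min_size=1, max_size=60),
        md=st.integers(0, 30),
    )
    def test_matches_union_find_oracle(self, intervals, md):
        feats = [feature(s, s + w) for s, w in intervals]
        lib = pool_and_merge(feats, md=md)
        # union-find oracle over all pairs
        parent = list(range(len(feats)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                a, b = feats[i].interval, feats[j].interval
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap <= md:
                    parent[find(i)] = find(j)
        groups = {}
        for i, f in enumerate(feats):
            groups.setdefault(find(i), []).append(f.interval)
        expected = sorted(
            (min(iv.start for iv in g), max(iv.end for iv in g))
            for g in groups.values()
        )
        got = sorted((s.interval.start, s.interval.end) for s in lib)
        assert got == expected

    def test_negative_md_rejected(self):
        with pytest.raises(ValueError):
            pool_and_merge([feature(0, 5)], md=-1)
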