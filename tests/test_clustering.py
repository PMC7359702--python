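"""Window clustering: distance primitive, single linkage, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import transitive_closure_clusters
from pseudomap.clustering import (
    WindowConfig,
    assign_labels,
    cluster_qtl,
    qtl_distance,
    summarize_clusters,
)
from pseudomap.model import GenomicInterval, QtlRecord


def iv(chrom, start, end=None):
    return GenomicInterval(chrom, start, end if end is not None else start)


def recs(loci):
    return [
        QtlRecord(i + 1, "YLD", f"Q{i + 1}", loci=[loc])
        for i, loc in enumerate(loci)
    ]


class TestDistance:
    def test_different_chromosomes_are_infinitely_far(self):
        assert qtl_distance(iv("chr1", 100, 200), iv("chr2", 100, 200)) == math.inf

    def test_overlap_is_zero(self):
        assert qtl_distance(iv("chr1", 100, 200), iv("chr1", 150, 300)) == 0
        assert qtl_distance(iv("chr1", 100, 200), iv("chr1", 200, 300)) == 0

    def test_gap_counts_bases_strictly_between(self):
        assert qtl_distance(iv("chr1", 100, 200), iv("chr1", 300, 400)) == 99
        assert qtl_distance(iv("chr1", 300, 400), iv("chr1", 100, 200)) == 99
        assert qtl_distance(iv("chr1", 100, 200), iv("chr1", 201, 300)) == 0


class TestClusterQtl:
    def test_single_record_single_cluster(self):
        (c,) = cluster_qtl(recs([iv("chr1", 500, 900)]))
        assert c.label == 1 and c.members == (1,)
        assert c.span == iv("chr1", 500, 900)

    def test_three_points_two_clusters(self):
        # gaps 89,999 (links) and 119,999 (does not) at 100 kb flank
        clusters = cluster_qtl(recs([iv("c", 100_000), iv("c", 190_000),
                                     iv("c", 310_000)]))
        assert [c.members for c in clusters] == [(1, 2), (3,)]

    def test_points_exactly_window_apart_link(self):
        # gap of point loci 100 kb apart is 99,999 <= flank
        clusters = cluster_qtl(recs([iv("c", 100_000), iv("c", 200_000)]))
        assert len(clusters) == 1

    def test_chain_of_five_links_into_one_cluster(self):
        pts = [iv("c", 100_000 + 90_000 * i) for i in range(5)]
        (c,) = cluster_qtl(recs(pts))
        assert c.members == (1, 2, 3, 4, 5)
        assert len(c.span) == 360_001  # far wider than one window

    def test_multi_mapped_records_excluded_by_default(self):
        records = recs([iv("c", 100_000)])
        records.append(
            QtlRecord(99, "PLH", "dual",
                      loci=[iv("c", 120_000), iv("d", 500_000)])
        )
        clusters = cluster_qtl(records)
        assert [c.members for c in clusters] == [(1,)]
        with_multi = cluster_qtl(records, include_multi=True)
        assert [c.members for c in with_multi] == [(1, 99), (99,)]

    def test_unmapped_records_ignored(self):
        records = [
            QtlRecord(7, "FW", "afB13"),
            QtlRecord(8, "YLD", "Q8", loci=[iv("c", 5_000)]),
        ]
        (c,) = cluster_qtl(records)
        assert c.members == (8,)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["c1", "c2"]),
                st.integers(min_value=1, max_value=1_500_000),
                st.integers(min_value=0, max_value=250_000),
            ),
            min_size=1,
            max_size=60,
        ),
        st.sampled_from([0, 1_000, 100_000]),
    )
    def test_equals_brute_force_transitive_closure(self, raw, flank):
        records = recs([iv(c, s, s + l) for c, s, l in raw])
        clusters = cluster_qtl(records, WindowConfig(flank))
        got = sorted(
            (frozenset(c.members) for c in clusters), key=lambda g: sorted(g)
        )
        loci = [
            (r.loci[0].chrom, r.loci[0].start, r.loci[0].end, r.qtl_no)
            for r in records
        ]
        assert got == transitive_closure_clusters(loci, flank)

    def test_200_random_qtl_match_oracle(self):
        rng = np.random.default_rng(42)
        loci = []
        for i in range(200):
            chrom = f"c{rng.integers(1, 4)}"
            start = int(rng.integers(1, 3_000_000))
            loci.append(iv(chrom, start, start + int(rng.integers(0, 400_000))))
        records = recs(loci)
        got = sorted(
            (frozenset(c.members) for c in cluster_qtl(records)),
            key=lambda g: sorted(g),
        )
        oracle = transitive_closure_clusters(
            [(l.chrom, l.start, l.end, i + 1) for i, l in enumerate(loci)], 100_000
        )
        assert got == oracle

    def test_permutation_changes_labels_only_by_relabeling(self):
        rng = np.random.default_rng(8)
        loci = [iv("c", int(p)) for p in rng.integers(1, 2_000_000, size=40)]
        records = recs(loci)
        base = {frozenset(c.members) for c in cluster_qtl(records)}
        shuffled = list(records)
        rng.shuffle(shuffled)
        perm = {frozenset(c.members) for c in cluster_qtl(shuffled)}
        assert base == perm

    def test_cluster_count_monotone_in_window(self):
        rng = np.random.default_rng(9)
        records = recs([iv("c", int(p)) for p in rng.integers(1, 5_000_000, size=80)])
        counts = [
            len(cluster_qtl(records, WindowConfig(f)))
            for f in (0, 10_000, 50_000, 100_000, 500_000, 10_000_000)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1

    def test_zero_flank_reduces_to_overlap_merging(self):
        records = recs([iv("c", 100, 200), iv("c", 200, 250), iv("c", 251, 300)])
        clusters = cluster_qtl(records, WindowConfig(0))
        # [100,200] and [200,250] overlap; [251,300] is adjacent (gap 0) and
        # under the gap convention distance 0 also links it
        assert [c.members for c in clusters] == [(1, 2, 3)]
        apart = recs([iv("c", 100, 200), iv("c", 202, 300)])
        assert len(cluster_qtl(apart, WindowConfig(0))) == 2

    def test_labels_ordered_by_chromosome_then_position(self):
        records = recs([iv("b", 900_000), iv("b", 100), iv("a", 5)])
        # chromosome order follows first appearance in the input ("b" first)
        clusters = cluster_qtl(records)
        assert [(c.label, c.chrom, c.members) for c in clusters] == [
            (1, "b", (2,)), (2, "b", (1,)), (3, "a", (3,)),
        ]


class TestSummarize:
    def test_assign_labels_writes_back(self):
        records = recs([iv("c", 100), iv("c", 50_000), iv("c", 900_000)])
        records, clusters = assign_labels(records)
        assert [r.cluster_label for r in records] == [1, 1, 2]
        assert len(clusters) == 2

    def test_summary_counts(self):
        records = recs([iv("c", 100), iv("c", 50_000), iv("c", 900_000)])
        records[2].trait = "PLH"
        records.append(QtlRecord(10, "FW", "un"))  # unmapped
        records.append(
            QtlRecord(11, "TL", "dual", loci=[iv("c", 1), iv("d", 2)])
        )
        records, _ = assign_labels(records)
        s = summarize_clusters(records)
        assert s.n_records == 5
        assert s.n_mapped_unique == 3
        assert s.n_unmapped == 1 and s.n_multi == 1
        assert s.n_clusters == 2
        assert s.n_traits == 2  # YLD, PLH; FW/TL not uniquely mapped
        assert s.sizes == {1: 2, 2: 1}
        assert s.n_clusters_min_size(2) == 1
        assert s.n_clusters_min_size(1) == 2
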