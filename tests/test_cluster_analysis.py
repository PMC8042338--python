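"""Cluster construction, compaction arithmetic and offset patterns."""

import numpy as np
import pytest

from mirsite.cluster_analysis import (
    build_clusters,
    compaction_stats,
    offset_patterns,
    summarize_by_region,
)
from mirsite.datasets import (
    CCNY_5UTR_ROWS,
    CCNY_CLUSTER1_INTERVAL,
    GSK3B_5UTR_ROWS,
    RBBP5_3UTR_ROWS,
    rows_to_sites,
    sites_within,
)
from mirsite.errors import ContractError
from mirsite.site_scanner import BindingSite


def site(start, length=22, mirna="m", transcript="t", gene="G", region="5UTR"):
    return BindingSite(mirna, transcript, gene, start, length, -100.0, 90.0, region=region)


class TestBuildClusters:
    def test_overlapping_merge(self):
        (c,) = build_clusters([site(3, 23), site(12, 24)])
        assert (c.span_start, c.span_end) == (3, 35)

    def test_disjoint_split(self):
        clusters = build_clusters([site(1), site(30)])
        assert len(clusters) == 2

    def test_adjacent_non_overlapping_split(self):
        # [1,22] and [23,44] share no position: two clusters
        assert len(build_clusters([site(1), site(23)])) == 2

    def test_transitive_chain(self):
        # a-b overlap, b-c overlap, a-c do not: still one component
        (c,) = build_clusters([site(1, 10), site(8, 10), site(16, 10)])
        assert c.size == 3

    def test_multiple_transcripts_rejected(self):
        with pytest.raises(ContractError):
            build_clusters([site(1), site(2, transcript="other")])

    def test_gsk3b_printed_rows_form_one_cluster(self):
        sites = rows_to_sites(GSK3B_5UTR_ROWS, "5UTR")
        (c,) = build_clusters(sites)
        # 28 starts over 22 table rows; one miRNA is listed twice -> 21 ids
        assert c.size == 28 and c.distinct_mirna_count == 21
        assert c.span_start == 3

    def test_matches_quadratic_closure_oracle(self, rng):
        """Sweep merging equals brute-force transitive closure of overlap."""
        for _ in range(30):
            n = int(rng.integers(2, 25))
            sites = [
                site(int(s), int(l))
                for s, l in zip(rng.integers(1, 300, n), rng.integers(18, 27, n))
            ]
            got = {
                tuple(sorted((m.start, m.end) for m in c.members))
                for c in build_clusters(sites)
            }
            # oracle: union-find over all O(n^2) overlap pairs
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = sites[i], sites[j]
                    if a.start <= b.end and b.start <= a.end:
                        parent[find(i)] = find(j)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(sites[i])
            expected = {
                tuple(sorted((m.start, m.end) for m in members))
                for members in groups.values()
            }
            assert got == expected

    def test_span_union_and_length_conservation(self, rng):
        n = 40
        sites = [
            site(int(s), int(l))
            for s, l in zip(rng.integers(1, 500, n), rng.integers(18, 27, n))
        ]
        clusters = build_clusters(sites)
        assert sum(c.total_site_length for c in clusters) == sum(s.length for s in sites)
        spans = sorted((c.span_start, c.span_end) for c in clusters)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2  # pairwise disjoint spans


class TestCompaction:
    def test_singleton(self):
        (c,) = build_clusters([site(10)])
        stats = compaction_stats(c)
        assert stats == {"total_site_length": 22, "span_length": 22, "compaction": 1.0}

    def test_tiling_compaction_exactly_one(self):
        (c,) = build_clusters([site(1, 22), site(22, 22)])  # overlap of one position
        assert c.compaction > 1.0
        clusters = build_clusters([site(1, 22), site(23, 22)])
        assert all(c.compaction == 1.0 for c in clusters)

    def test_ccny_cluster1_published_numbers(self):
        sites = sites_within(rows_to_sites(CCNY_5UTR_ROWS, "5UTR"), CCNY_CLUSTER1_INTERVAL)
        assert len(sites) == 9
        (c,) = build_clusters(sites)
        stats = compaction_stats(c)
        assert stats["total_site_length"] == 206
        assert stats["compaction"] == 6.9

    def test_span_override(self):
        (c,) = build_clusters([site(10)])
        assert compaction_stats(c, span=(1, 44))["compaction"] == 0.5


class TestOffsetPatterns:
    def test_rbbp5_74nt(self):
        sites = rows_to_sites(RBBP5_3UTR_ROWS, "3UTR")
        (p,) = offset_patterns(sites, [("miR-619-5p", "miR-5096")])
        assert p.per_gene == {"RBBP5": 74}

    def test_identical_starts_zero(self):
        sites = [site(100, mirna="a"), site(100, mirna="b")]
        (p,) = offset_patterns(sites, [("a", "b")])
        assert p.per_gene == {"G": 0} and p.constant and p.offset == 0

    def test_missing_gene_warns(self):
        sites = [site(1, mirna="a", gene="G1"), site(5, mirna="b", gene="G1"),
                 site(9, mirna="a", gene="G2")]
        (p,) = offset_patterns(sites, [("a", "b")])
        assert p.per_gene == {"G1": 4}
        assert any("G2" in w for w in p.warnings)

    def test_nearest_pair_matching(self):
        sites = [site(100, mirna="a"), site(1000, mirna="a"),
                 site(1074, mirna="b"), site(5000, mirna="b")]
        (p,) = offset_patterns(sites, [("a", "b")])
        assert p.per_gene == {"G": 74}


class TestSummary:
    def test_region_counts(self):
        sites = (
            [site(s, region="5UTR") for s in (1, 5, 9, 60, 64, 100, 130, 160, 190, 220)]
        )
        clusters = build_clusters(sites)
        report = summarize_by_region(clusters, sites)
        info = report["regions"]["5UTR"]
        assert info["n_sites"] == 10
        assert info["n_clusters"] == 7
        assert info["n_clusters_multi_member"] == 2
        assert info["clustered_site_fraction"] == pytest.approx(0.5)

    def test_empty_region_absent(self):
        sites = [site(1, region="5UTR")]
        report = summarize_by_region(build_clusters(sites), sites)
        assert "3UTR" not in report["regions"]

    def test_gene_targeting_split(self):
        sites = [site(1, mirna="a", gene="G1"), site(40, mirna="b", gene="G1"),
                 site(1, mirna="a", gene="G2", transcript="t2")]
        report = summarize_by_region([], sites)
        assert report["genes"]["multi_mirna_targets"] == ["G1"]
        assert report["genes"]["single_mirna_targets"] == ["G2"]
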