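"""Binding-site clusters, compaction statistics and recurrent start offsets.

A cluster is a connected component of the interval-overlap graph over site
intervals (closed, 1-based; overlap of a single shared position suffices).
Compaction is the total site length — every start counts a full miRNA
length, so multiple starts of one miRNA all contribute — divided by the
span the cluster occupies: values above 1 mean the sites could not be laid
end to end in the available region and must overlap, which in turn implies
competition, since only one miRNA can physically occupy the span at a time.

Offset patterns capture the recurring constant distances between the starts
of two miRNAs' sites across genes (e.g. a 6-nt or 74-nt spacing repeated in
several 3'UTRs), which flags coordinated site pairs rather than chance
co-occurrence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .errors import ContractError
from .io_formats import Transcript
from .site_scanner import BindingSite


@dataclass(frozen=True)
class SiteCluster:
    """A maximal set of pairwise-connected overlapping sites."""

    transcript_id: str
    members: tuple[BindingSite, ...]
    span_start: int
    span_end: int

    @property
    def region(self) -> str:
        regions = {m.region for m in self.members}
        return regions.pop() if len(regions) == 1 else "mixed"

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1

    @property
    def total_site_length(self) -> int:
        """Σ member lengths; each start counted separately (multiplicity)."""
        return sum(m.length for m in self.members)

    @property
    def compaction(self) -> float:
        return self.total_site_length / self.span_length

    @property
    def distinct_mirna_count(self) -> int:
        return len({m.mirna_id for m in self.members})

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OffsetPattern:
    """Start differences of one miRNA pair across genes."""

    mirna_a: str
    mirna_b: str
    per_gene: dict[str, int]  # gene -> start_b - start_a (nearest pair)
    warnings: tuple[str, ...] = ()

    @property
    def constant(self) -> bool:
        return len(set(self.per_gene.values())) == 1 and bool(self.per_gene)

    @property
    def offset(self) -> int | None:
        return next(iter(self.per_gene.values())) if self.constant else None


def build_clusters(sites: list[BindingSite]) -> list[SiteCluster]:
    """Connected components of interval overlap on one transcript's sites.

    Sorted-sweep merging: with sites ordered by start, a site joins the open
    cluster iff its start does not pass the running maximum end, which is
    exactly the transitive closure of pairwise overlap of closed intervals.
    """
    if not sites:
        return []
    transcript_ids = {s.transcript_id for s in sites}
    if len(transcript_ids) > 1:
        raise ContractError(f"sites from multiple transcripts: {sorted(transcript_ids)}")
    ordered = sorted(sites, key=lambda s: (s.start, s.end, s.mirna_id))
    clusters: list[SiteCluster] = []
    current: list[BindingSite] = [ordered[0]]
    current_end = ordered[0].end
    for site in ordered[1:]:
        if site.start <= current_end:  # closed intervals: sharing one position overlaps
            current.append(site)
            current_end = max(current_end, site.end)
        else:
            clusters.append(_finalize(current))
            current = [site]
            current_end = site.end
    clusters.append(_finalize(current))
    return clusters


def _finalize(members: list[BindingSite]) -> SiteCluster:
    return SiteCluster(
        transcript_id=members[0].transcript_id,
        members=tuple(members),
        span_start=min(m.start for m in members),
        span_end=max(m.end for m in members),
    )


def compaction_stats(
    cluster: SiteCluster, span: tuple[int, int] | None = None
) -> dict[str, float]:
    """Total site length, span length and compaction (one decimal).

    ``span`` optionally overrides the realized union span with an externally
    stated cluster interval, for comparisons against narrative bounds.
    """
    if span is None:
        span_length = cluster.span_length
    else:
        span_length = span[1] - span[0] + 1
        if span_length <= 0:
            raise ContractError(f"empty span {span}")
    total = cluster.total_site_length
    return {
        "total_site_length": total,
        "span_length": span_length,
        "compaction": round(total / span_length, 1),
    }


def offset_patterns(
    sites: list[BindingSite], pairs: list[tuple[str, str]]
) -> list[OffsetPattern]:
    """Per-gene start offsets of designated miRNA pairs, nearest-pair matched.

    For each gene where both miRNAs have sites, the reported difference is
    ``start_b − start_a`` of the pair minimizing the absolute distance
    (ties broken toward the smaller ``start_a``).  Genes missing either
    miRNA are omitted with a warning record on the pattern.
    """
    by_gene_mirna: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for s in sites:
        by_gene_mirna[s.gene][s.mirna_id].append(s.start)
    patterns = []
    for mirna_a, mirna_b in pairs:
        per_gene: dict[str, int] = {}
        warnings: list[str] = []
        for gene in sorted(by_gene_mirna):
            starts_a = sorted(by_gene_mirna[gene].get(mirna_a, []))
            starts_b = sorted(by_gene_mirna[gene].get(mirna_b, []))
            if not starts_a or not starts_b:
                warnings.append(
                    f"{gene}: pair ({mirna_a}, {mirna_b}) incomplete; gene omitted"
                )
                continue
            best = min(
                ((b - a, a) for a in starts_a for b in starts_b),
                key=lambda diff_a: (abs(diff_a[0]), diff_a[1]),
            )
            per_gene[gene] = best[0]
        patterns.append(
            OffsetPattern(
                mirna_a=mirna_a,
                mirna_b=mirna_b,
                per_gene=per_gene,
                warnings=tuple(warnings),
            )
        )
    return patterns


def summarize_by_region(
    clusters: list[SiteCluster],
    sites: list[BindingSite],
    transcripts: list[Transcript] | None = None,
) -> dict:
    """Per-region site/cluster counts, compaction values and per-gene targeting."""
    report: dict = {"regions": {}, "genes": {}}
    regions = sorted({s.region for s in sites} | {c.region for c in clusters})
    for region in regions:
        region_sites = [s for s in sites if s.region == region]
        region_clusters = [c for c in clusters if c.region == region]
        multi = [c for c in region_clusters if c.size >= 2]
        clustered_sites = sum(c.size for c in multi)
        report["regions"][region] = {
            "n_sites": len(region_sites),
            "n_clusters": len(region_clusters),
            "n_clusters_multi_member": len(multi),
            "clustered_site_fraction": (
                clustered_sites / len(region_sites) if region_sites else 0.0
            ),
            "compaction_values": sorted(round(c.compaction, 1) for c in multi),
        }
    per_gene_mirnas: dict[str, set] = defaultdict(set)
    for s in sites:
        per_gene_mirnas[s.gene].add(s.mirna_id)
    report["genes"] = {
        "single_mirna_targets": sorted(g for g, m in per_gene_mirnas.items() if len(m) == 1),
        "multi_mirna_targets": sorted(g for g, m in per_gene_mirnas.items() if len(m) > 1),
    }
    return report
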