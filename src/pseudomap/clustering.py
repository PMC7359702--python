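"""Group QTL into co-location clusters with a flanking-window rule, and
summarize cluster structure.

Two QTL link when the gap between their intervals is at most ``flank_bp``
(default 100 kb on each side, i.e. a 200 kb window around a point locus);
clusters are the connected components of that relation (single linkage), so
a chain of pairwise-close QTL can span far more than one window.  Intervals
are used as published, not reduced to midpoints.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .model import Cluster, GenomicInterval, QtlRecord, WindowConfig


def qtl_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Base pairs between two loci: inf across chromosomes, 0 on overlap,
    otherwise the gap between nearest ends (bases strictly between them)."""
    if a.chrom != b.chrom:
        return math.inf
    if a.overlaps(b):
        return 0
    if b.start > a.end:
        return b.start - a.end - 1
    return a.start - b.end - 1


def cluster_qtl(
    records: Iterable[QtlRecord],
    window: WindowConfig = WindowConfig(),
    include_multi: bool = False,
) -> List[Cluster]:
    """Single-linkage clustering of mapped QTL loci.

    Uniquely mapped records contribute their locus; multi-mapped records are
    skipped unless ``include_multi``, in which case each of their loci joins
    clustering independently.  Labels are assigned 1..N ordered by (first
    appearance of the chromosome in the input, leftmost member start).
    """
    records = list(records)
    chrom_order: Dict[str, int] = {}
    entries = []  # (chrom, start, end, qtl_no)
    for r in records:
        if r.is_unmapped or (r.is_multi and not include_multi):
            continue
        for loc in r.loci:
            chrom_order.setdefault(loc.chrom, len(chrom_order))
            entries.append((loc.chrom, loc.start, loc.end, r.qtl_no))
    entries.sort(key=lambda e: (chrom_order[e[0]], e[1], e[2], e[3]))

    clusters: List[Cluster] = []
    cur: Optional[dict] = None

    def close(c):
        clusters.append(
            Cluster(
                label=len(clusters) + 1,
                chrom=c["chrom"],
                span=GenomicInterval(c["chrom"], c["start"], c["end"]),
                members=tuple(c["members"]),
            )
        )

    for chrom, start, end, qno in entries:
        gap = (
            math.inf
            if cur is None or cur["chrom"] != chrom
            else max(start - cur["end"] - 1, 0)
        )
        if cur is not None and gap <= window.flank_bp:
            cur["end"] = max(cur["end"], end)
            cur["members"].append(qno)
        else:
            if cur is not None:
                close(cur)
            cur = {"chrom": chrom, "start": start, "end": end, "members": [qno]}
    if cur is not None:
        close(cur)
    return clusters


def assign_labels(records: Iterable[QtlRecord], window: WindowConfig = WindowConfig()):
    """Run :func:`cluster_qtl` and write the labels back onto the records
    (multi-mapped and unmapped records keep ``cluster_label`` None).
    Returns (records, clusters)."""
    records = list(records)
    clusters = cluster_qtl(records, window)
    label_of = {}
    for c in clusters:
        for qno in c.members:
            label_of[qno] = c.label
    for r in records:
        r.cluster_label = label_of.get(r.qtl_no) if r.is_unique else None
    return records, clusters


@dataclass
class ClusterSummary:
    """Headline counts of a labelled QTL table."""

    n_records: int
    n_unmapped: int
    n_multi: int
    n_mapped_unique: int
    n_clusters: int
    n_traits: int
    sizes: Dict[int, int] = field(default_factory=dict)

    def n_clusters_min_size(self, k: int) -> int:
        return sum(1 for n in self.sizes.values() if n >= k)


def summarize_clusters(records: Iterable[QtlRecord], min_size: int = 3) -> ClusterSummary:
    """Summarize records that carry cluster labels (curated or computed).

    ``n_mapped_unique`` counts records with exactly one locus; cluster sizes
    count label occurrences among those records; ``n_traits`` counts
    distinct trait codes among uniquely mapped records.
    """
    records = list(records)
    unique = [r for r in records if r.is_unique]
    sizes = Counter(
        r.cluster_label for r in unique if r.cluster_label is not None
    )
    return ClusterSummary(
        n_records=len(records),
        n_unmapped=sum(r.is_unmapped for r in records),
        n_multi=sum(r.is_multi for r in records),
        n_mapped_unique=len(unique),
        n_clusters=len(sizes),
        n_traits=len({r.trait for r in unique if r.trait}),
        sizes=dict(sizes),
    )
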