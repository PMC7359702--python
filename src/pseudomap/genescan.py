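"""Scan annotated genes (optionally RGAs only) within the flanking window of
each QTL locus.

A gene is a candidate for a QTL when its locus intersects the window
``[qtl.start - flank_bp, qtl.end + flank_bp]`` (inclusive boundaries) on the
same chromosome.  The window is applied around the QTL interval as
published, not around an inferred peak; point genes are 1-bp intervals.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .clustering import qtl_distance
from .model import GeneRecord, GenomicInterval, QtlRecord, WindowConfig


class GeneIndex:
    """Per-chromosome interval tree over gene loci."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.locus.chrom, IntervalTree()).addi(
                g.locus.start, g.locus.end + 1, g
            )

    def query(self, chrom: str, start: int, end: int) -> List[GeneRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        found = [iv.data for iv in tree[start : end + 1]]
        found.sort(key=lambda g: (g.locus.start, g.locus.end, g.gene_id))
        return found


def _as_index(genes) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def genes_in_window(
    locus: GenomicInterval,
    genes,
    window: WindowConfig = WindowConfig(),
    rga_only: bool = False,
) -> List[GeneRecord]:
    """Genes intersecting the flanking window of one locus, sorted by start."""
    index = _as_index(genes)
    start = max(1, locus.start - window.flank_bp)
    end = locus.end + window.flank_bp
    found = index.query(locus.chrom, start, end)
    if rga_only:
        found = [g for g in found if g.is_rga]
    return found


def scan_all(
    qtl_records: Iterable[QtlRecord],
    genes,
    window: WindowConfig = WindowConfig(),
    rga_only: bool = False,
) -> Tuple[pd.DataFrame, Set[str]]:
    """Candidate-gene table over all mapped QTL loci.

    Returns (pairs, unique_gene_ids): one row per (QTL locus, gene) with the
    gap in bp (0 on overlap) and the gene's annotation/RGA class, plus the
    deduplicated set of candidate gene IDs across all QTL.
    """
    index = _as_index(genes)
    rows = []
    unique: Set[str] = set()
    for r in qtl_records:
        for loc in r.loci:
            for g in genes_in_window(loc, index, window, rga_only):
                d = qtl_distance(loc, g.locus)
                rows.append(
                    {
                        "qtl_no": r.qtl_no,
                        "qtl_id": r.qtl_id,
                        "chrom": loc.chrom,
                        "gene_id": g.gene_id,
                        "gene_start": g.locus.start,
                        "gene_end": g.locus.end,
                        "distance_bp": int(d),
                        "rga_class": g.rga_class or "",
                        "annotation": g.annotation,
                    }
                )
                unique.add(g.gene_id)
    pairs = pd.DataFrame(
        rows,
        columns=[
            "qtl_no", "qtl_id", "chrom", "gene_id", "gene_start", "gene_end",
            "distance_bp", "rga_class", "annotation",
        ],
    )
    return pairs, unique
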