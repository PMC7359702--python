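"""Deterministic scaffold <-> pseudomolecule coordinate conversion.

A placement table (one row per scaffold: span on the chromosome plus
orientation) is the single source of truth; no sequence comparison is done.
Forward placements shift coordinates, reverse placements mirror them, and
interval lifts preserve length exactly.
"""

from __future__ import annotations

import difflib
from typing import Dict, Iterable, List, Optional, Tuple

from intervaltree import IntervalTree

from .model import GenomicInterval, ScaffoldPlacement, parse_scaffold_marker


class PlacementTable:
    """Indexed view over a list of placements for both lookup directions."""

    def __init__(self, placements: Iterable[ScaffoldPlacement]):
        self.placements: List[ScaffoldPlacement] = list(placements)
        self.by_scaffold: Dict[str, ScaffoldPlacement] = {}
        for p in self.placements:
            if p.scaffold_id in self.by_scaffold:
                raise ValueError(f"scaffold {p.scaffold_id} placed more than once")
            self.by_scaffold[p.scaffold_id] = p
        self._trees: Dict[str, IntervalTree] = {}
        for p in self.placements:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(
                p.chr_start, p.chr_end + 1, p
            )

    def __len__(self):
        return len(self.placements)

    def get(self, scaffold_id: str) -> ScaffoldPlacement:
        try:
            return self.by_scaffold[scaffold_id]
        except KeyError:
            near = difflib.get_close_matches(
                scaffold_id, self.by_scaffold.keys(), n=3
            )
            hint = f"; nearest IDs: {', '.join(near)}" if near else ""
            raise KeyError(f"unknown scaffold {scaffold_id!r}{hint}") from None

    def at(self, chrom: str, chr_pos: int) -> Optional[ScaffoldPlacement]:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        found = tree[chr_pos]
        return next(iter(found)).data if found else None


def _as_table(placements) -> PlacementTable:
    return placements if isinstance(placements, PlacementTable) else PlacementTable(placements)


def scaffold_to_chrom(scaffold_id: str, pos: int, placements) -> Tuple[str, int]:
    """Convert a 1-based scaffold position to its chromosome position."""
    table = _as_table(placements)
    p = table.get(scaffold_id)
    if not 1 <= pos <= p.scaffold_len:
        raise ValueError(
            f"{scaffold_id}: position {pos} outside scaffold of length "
            f"{p.scaffold_len}"
        )
    if p.orientation == "+":
        return p.chrom, p.chr_start + pos - 1
    return p.chrom, p.chr_end - pos + 1


def chrom_to_scaffold(chrom: str, chr_pos: int, placements) -> Optional[Tuple[str, int]]:
    """Exact inverse of :func:`scaffold_to_chrom`.

    Returns None for positions in inter-scaffold gaps ("unplaced"), rather
    than raising.
    """
    table = _as_table(placements)
    p = table.at(chrom, chr_pos)
    if p is None:
        return None
    if p.orientation == "+":
        return p.scaffold_id, chr_pos - p.chr_start + 1
    return p.scaffold_id, p.chr_end - chr_pos + 1


def lift_interval(scaffold_id: str, start: int, end: int, placements) -> GenomicInterval:
    """Lift a scaffold interval onto the chromosome, preserving its length.

    Endpoints are lifted independently and re-ordered, since a reverse
    placement flips them.
    """
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    chrom, a = scaffold_to_chrom(scaffold_id, start, placements)
    _, b = scaffold_to_chrom(scaffold_id, end, placements)
    return GenomicInterval(chrom, min(a, b), max(a, b))


def lift_marker(marker_id: str, placements) -> Optional[Tuple[str, int]]:
    """Lift a scaffold-encoded SNP name (``scaffoldNNN_POS``/``-POS``) to its
    chromosome position; None if the name does not follow the convention."""
    parsed = parse_scaffold_marker(marker_id)
    if parsed is None:
        return None
    scaffold_id, pos = parsed
    return scaffold_to_chrom(scaffold_id, pos, placements)


def verify_placements(
    placements, chrom_seqs: Dict[str, str], scaffold_seqs: Dict[str, str]
) -> List[str]:
    """Optional consistency check: each scaffold sequence must equal the
    (oriented) chromosome slice its placement claims.  Returns the IDs of
    scaffolds that fail."""
    from .model import revcomp

    table = _as_table(placements)
    bad = []
    for p in table.placements:
        if p.scaffold_id not in scaffold_seqs or p.chrom not in chrom_seqs:
            bad.append(p.scaffold_id)
            continue
        piece = chrom_seqs[p.chrom][p.chr_start - 1 : p.chr_end]
        if p.orientation == "-":
            piece = revcomp(piece)
        if piece != scaffold_seqs[p.scaffold_id].upper():
            bad.append(p.scaffold_id)
    return bad
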