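"""Map SNP flanking sequences onto the genome and convert the variant base's
offset to a chromosome position.

The aligner is deliberately minimal: exact k-mer seeds from the shared word
index, ungapped X-drop extension with a +1/-2 match/mismatch score, and a
Karlin-Altschul expectation-value filter (default 1e-30).  Published flank
placements are near-exact, so gapped alignment is out of scope; an external
gapped aligner can be slotted in by producing the same hit schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .epcr import PrimerIndex
from .model import FlankSequence, GenomicInterval, revcomp

#: Karlin-Altschul parameters for ungapped +1/-2 scoring (declared, not tuned).
LAMBDA = 1.374
KAPPA = 0.711

DEFAULT_EVALUE = 1e-30
XDROP = 10
MATCH = 1
MISMATCH = -2

#: Hits within this relative score of the best are all reported as top hits.
TOP_HIT_REL_TOL = 1e-3


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped local alignment of a flank against the genome.

    ``query_start``/``query_end`` are 1-based positions in the flank as
    given (not reverse-complemented); on the minus strand the subject runs
    antiparallel to the query.
    """

    marker_id: str
    subject: GenomicInterval
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    score: int
    evalue: float

    def __post_init__(self):
        if len(self.subject) != self.query_end - self.query_start + 1:
            raise ValueError("ungapped hit: subject and query spans differ")
        if self.evalue < 0:
            raise ValueError("negative E-value")


def evalue(score: float, query_len: int, genome_len: int) -> float:
    """Expected number of chance alignments at this score: E = K*m*n*e^(-lambda*S),
    with the search space n counted over both strands."""
    return KAPPA * query_len * (2 * genome_len) * math.exp(-LAMBDA * score)


def _xdrop_extend(query: str, subject: str, qpos: int, spos: int, k: int):
    """Extend an exact k-word seed at (qpos, spos) (0-based) in both
    directions; returns (q0, q1, s0, s1, score) with inclusive 0-based ends."""

    def step(qi, si, direction):
        best_delta, best_steps = 0, 0
        delta, steps = 0, 0
        while True:
            qi += direction
            si += direction
            if qi < 0 or si < 0 or qi >= len(query) or si >= len(subject):
                break
            delta += MATCH if query[qi] == subject[si] else MISMATCH
            steps += 1
            if delta > best_delta:
                best_delta, best_steps = delta, steps
            elif best_delta - delta > XDROP:
                break
        return best_delta, best_steps

    score = k * MATCH  # the seed itself is exact
    right_delta, right_steps = step(qpos + k - 1, spos + k - 1, +1)
    left_delta, left_steps = step(qpos, spos, -1)
    return (
        qpos - left_steps,
        qpos + k - 1 + right_steps,
        spos - left_steps,
        spos + k - 1 + right_steps,
        score + right_delta + left_delta,
    )


def map_flank(
    flank: FlankSequence,
    index: PrimerIndex,
    evalue_max: float = DEFAULT_EVALUE,
) -> List[AlignmentHit]:
    """Align one flanking sequence against both strands of the indexed genome.

    Returns hits with E-value <= ``evalue_max``, best first (E-value
    ascending, then score descending, then position).  An empty list means
    nothing passed the filter.
    """
    k = index.word_size
    if len(flank.seq) < k:
        raise ValueError(
            f"{flank.marker_id}: flank shorter than word_size ({k})"
        )
    genome_len = sum(len(s) for s in index.genome.values())
    L = len(flank.seq)
    hits: Dict[Tuple, AlignmentHit] = {}
    for strand, query in (("+", flank.seq), ("-", revcomp(flank.seq))):
        diagonals = {}  # (chrom, subject_start - query_start) -> first seed
        for i in range(L - k + 1):
            for chrom, pos in index.lookup(query[i : i + k]):
                diag = (chrom, pos - 1 - i)
                if diag not in diagonals:
                    diagonals[diag] = (i, pos - 1)
        for (chrom, _), (qpos, spos) in diagonals.items():
            subject = index.genome[chrom]
            q0, q1, s0, s1, score = _xdrop_extend(query, subject, qpos, spos, k)
            ev = evalue(score, L, genome_len)
            if ev > evalue_max:
                continue
            if strand == "+":
                query_start, query_end = q0 + 1, q1 + 1
            else:  # map back to original flank orientation
                query_start, query_end = L - q1, L - q0
            hit = AlignmentHit(
                marker_id=flank.marker_id,
                subject=GenomicInterval(chrom, s0 + 1, s1 + 1),
                query_start=query_start,
                query_end=query_end,
                strand=strand,
                score=score,
                evalue=ev,
            )
            key = (chrom, s0, s1, strand)
            if key not in hits or hit.score > hits[key].score:
                hits[key] = hit
    out = list(hits.values())
    out.sort(
        key=lambda h: (h.evalue, -h.score, h.subject.chrom, h.subject.start)
    )
    return out


def top_hits(hits: List[AlignmentHit]) -> List[AlignmentHit]:
    """All hits within a small relative score tolerance of the best one.

    More than one top hit across loci marks the marker multi-mapped (same
    semantics as :func:`pseudomap.epcr.classify_mapping`).
    """
    if not hits:
        return []
    best = max(h.score for h in hits)
    return [h for h in hits if h.score >= best * (1 - TOP_HIT_REL_TOL)]


def snp_position(hit: AlignmentHit, snp_offset: int) -> Tuple[str, int]:
    """Chromosome position of the variant base, given its 1-based offset in
    the flank.  Raises if the offset fell outside the aligned span."""
    if not hit.query_start <= snp_offset <= hit.query_end:
        raise ValueError(
            f"{hit.marker_id}: SNP offset {snp_offset} outside aligned query "
            f"span [{hit.query_start}, {hit.query_end}]"
        )
    if hit.strand == "+":
        pos = hit.subject.start + (snp_offset - hit.query_start)
    else:
        pos = hit.subject.end - (snp_offset - hit.query_start)
    return hit.subject.chrom, pos
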