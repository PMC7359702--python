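"""Electronic PCR: locate primer pairs on a genome in valid head-to-head
orientation with zero mismatches or gaps, and report amplicon spans.

The search is the exact-match special case of electronic PCR: each primer is
anchored by its 3'-terminal k-mer in a genome-wide word index, candidates
are verified by full-length exact comparison, and the two primers must face
each other (3' ends inward) within a bounded amplicon size.  The 3' anchor
is the PCR-relevant constraint — a mismatch there aborts extension — and it
keeps candidate lists short.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

from .model import DNA_ALPHABET, GenomicInterval, PrimerPair, revcomp

DEFAULT_WORD_SIZE = 12
DEFAULT_MAX_AMPLICON = 10_000

_INDEX_FORMAT = 1


@dataclass(frozen=True)
class PcrHit:
    """One predicted amplicon.

    ``interval`` spans from the plus-strand primer's 5' end to the image of
    the other primer's 5' end on the plus strand; ``plus_strand_primer``
    records which primer of the pair matched the plus strand.
    """

    marker_id: str
    interval: GenomicInterval
    amplicon_len: int
    plus_strand_primer: str  # 'forward' or 'reverse'

    def __post_init__(self):
        if self.amplicon_len != len(self.interval):
            raise ValueError("amplicon_len inconsistent with interval span")


class PrimerIndex:
    """Genome k-mer index: word -> sorted (chrom, 1-based start) occurrences.

    Words containing any non-ACGT base are omitted, so masked (N) regions
    never seed a hit.  The index keeps a handle on the genome sequences for
    full-length verification of candidates.
    """

    def __init__(self, genome: Mapping[str, str], word_size: int = DEFAULT_WORD_SIZE):
        if word_size < 4:
            raise ValueError(f"word_size must be >= 4, got {word_size}")
        if not genome:
            raise ValueError("empty genome")
        self.word_size = int(word_size)
        self.genome: Dict[str, str] = {c: s.upper() for c, s in genome.items()}
        self.word_map: Dict[str, List[Tuple[str, int]]] = {}
        k = self.word_size
        for chrom, seq in self.genome.items():
            if len(seq) < k:
                warnings.warn(
                    f"chromosome {chrom} shorter than word_size {k}; "
                    "it contributes no words"
                )
                continue
            wm = self.word_map
            for i in range(len(seq) - k + 1):
                word = seq[i : i + k]
                if set(word) <= DNA_ALPHABET:
                    wm.setdefault(word, []).append((chrom, i + 1))

    def lookup(self, word: str) -> List[Tuple[str, int]]:
        return self.word_map.get(word, [])

    # -- persistence --------------------------------------------------------
    def save(self, path):
        payload = {
            "format": _INDEX_FORMAT,
            "word_size": self.word_size,
            "genome": self.genome,
            "word_map": self.word_map,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load(cls, path) -> "PrimerIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != _INDEX_FORMAT:
            raise ValueError(f"{path}: unsupported index format")
        obj = cls.__new__(cls)
        obj.word_size = payload["word_size"]
        obj.genome = payload["genome"]
        obj.word_map = payload["word_map"]
        return obj


def build_index(genome: Mapping[str, str], word_size: int = DEFAULT_WORD_SIZE) -> PrimerIndex:
    """Build the k-mer search index over a genome (see :class:`PrimerIndex`)."""
    return PrimerIndex(genome, word_size)


def _plus_matches(primer: str, index: PrimerIndex) -> List[Tuple[str, int]]:
    """All exact full-length matches of ``primer`` on the plus strand,
    anchored at the primer's 3'-terminal word."""
    k = index.word_size
    offset = len(primer) - k
    out = []
    for chrom, pos in index.lookup(primer[-k:]):
        start = pos - offset  # 1-based start of the full primer match
        if start < 1:
            continue
        seq = index.genome[chrom]
        if seq[start - 1 : start - 1 + len(primer)] == primer:
            out.append((chrom, start))
    return out


def _minus_matches(primer: str, index: PrimerIndex) -> List[Tuple[str, int]]:
    """Plus-strand start positions of revcomp(primer), i.e. sites where the
    primer anneals to the plus strand and extends leftward.  Anchored at the
    first word of revcomp(primer), which is the primer's 3'-terminal word."""
    rc = revcomp(primer)
    k = index.word_size
    out = []
    for chrom, pos in index.lookup(rc[:k]):
        seq = index.genome[chrom]
        if seq[pos - 1 : pos - 1 + len(rc)] == rc:
            out.append((chrom, pos))
    return out


def epcr(
    pair: PrimerPair,
    index: PrimerIndex,
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
) -> List[PcrHit]:
    """Map one primer pair onto the indexed genome with zero mismatches.

    Both orientations are searched: forward primer on the plus strand with
    the reverse primer annealing downstream on the minus strand, and the
    mirror arrangement.  A valid hit has inward-facing 3' ends, an amplicon
    no longer than ``max_amplicon``, and non-overlapping primer footprints
    (amplicon at least as long as the two primers combined).
    """
    k = index.word_size
    if len(pair.forward) < k or len(pair.reverse) < k:
        raise ValueError(
            f"{pair.marker_id}: primers must be at least word_size ({k}) long"
        )
    min_len = len(pair.forward) + len(pair.reverse)
    seen = set()
    hits: List[PcrHit] = []
    for plus_name, plus_primer, minus_primer in (
        ("forward", pair.forward, pair.reverse),
        ("reverse", pair.reverse, pair.forward),
    ):
        plus_sites = _plus_matches(plus_primer, index)
        minus_sites = _minus_matches(minus_primer, index)
        by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in minus_sites:
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, starts in by_chrom.items():
            starts.sort()
        for chrom, fstart in plus_sites:
            for mstart in by_chrom.get(chrom, ()):
                end = mstart + len(minus_primer) - 1  # 5' end of minus primer
                amp = end - fstart + 1
                if amp < min_len or amp > max_amplicon:
                    continue
                key = (chrom, fstart, end)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    PcrHit(
                        marker_id=pair.marker_id,
                        interval=GenomicInterval(chrom, fstart, end),
                        amplicon_len=amp,
                        plus_strand_primer=plus_name,
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    return hits


def classify_mapping(hits) -> str:
    """'unmapped' (0 hits), 'unique' (1), or 'multi' (>= 2, including two
    hits on the same chromosome)."""
    n = len(hits)
    if n == 0:
        return "unmapped"
    if n == 1:
        return "unique"
    return "multi"
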