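"""Deterministic synthetic fixtures with known ground truth.

Every generator records what it planted in a :class:`PlantLog`, which is
sufficient to predict the correct output of each analysis module exactly:
planted primer pairs must be recovered by e-PCR at their logged coordinates,
planted flanks at their logged SNP positions, decomposed scaffolds must
round-trip through liftover, and constructed QTL sets must cluster into the
requested sizes.

Genomes are uniform random ACGT with no repeat or GC structure — sufficient
because every downstream algorithm is exact-match based.  Multi-mapping is
exercised by explicitly duplicating planted loci (``with_duplication``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    FlankSequence,
    GenomicInterval,
    GeneRecord,
    PrimerPair,
    QtlRecord,
    ScaffoldPlacement,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MAX_PLANT_RETRIES = 100


@dataclass
class PlantLog:
    """Ground truth of everything a fixture generator planted."""

    seed: int
    chrom_lengths: Dict[str, int] = field(default_factory=dict)
    primer_sites: List[dict] = field(default_factory=list)
    flank_sites: List[dict] = field(default_factory=list)
    placements: List[ScaffoldPlacement] = field(default_factory=list)
    gene_sites: List[dict] = field(default_factory=list)
    qtl_cluster_sizes: List[int] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def make_genome(
    seed: int,
    n_chrom: int = 3,
    lengths: Optional[Sequence[int]] = None,
) -> Tuple[Dict[str, str], PlantLog]:
    """Uniform random genome; reproducible for a fixed seed.

    ``lengths`` (default 50 kb per chromosome) must each be >= 10 kb so that
    planted features have room to be unique.
    """
    if lengths is None:
        lengths = [50_000] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(L < 10_000 for L in lengths):
        raise ValueError("chromosome lengths must be >= 10 kb")
    rng = np.random.default_rng(seed)
    genome = {}
    log = PlantLog(seed=seed)
    for i, L in enumerate(lengths, start=1):
        name = f"chr{i}"
        genome[name] = _BASES[rng.integers(0, 4, int(L))].tobytes().decode()
        log.chrom_lengths[name] = int(L)
    return genome, log


def _occurrences(genome: Dict[str, str], pattern: str) -> int:
    """Overlapping occurrence count of ``pattern`` over both strands."""
    total = 0
    for strand_seq in (pattern, revcomp(pattern)):
        for seq in genome.values():
            start = seq.find(strand_seq)
            while start != -1:
                total += 1
                start = seq.find(strand_seq, start + 1)
    return total


def _pick_interval(rng, log: PlantLog, length: int, used, min_sep: int = 0):
    """Random (chrom, start) for an interval avoiding previously used spans."""
    chroms = list(log.chrom_lengths)
    for _ in range(MAX_PLANT_RETRIES):
        chrom = chroms[rng.integers(0, len(chroms))]
        L = log.chrom_lengths[chrom]
        if L < length + 2:
            continue
        start = int(rng.integers(1, L - length + 1))
        end = start + length - 1
        if all(
            c != chrom or start > e + min_sep or end < s - min_sep
            for c, s, e in used
        ):
            return chrom, start, end
    raise RuntimeError(
        "could not place a non-overlapping feature after "
        f"{MAX_PLANT_RETRIES} tries; use a longer genome"
    )


def plant_primer_pairs(
    genome: Dict[str, str],
    log: PlantLog,
    n: int = 20,
    amplicon_range: Tuple[int, int] = (80, 300),
    primer_len_range: Tuple[int, int] = (18, 24),
    seed: int = 0,
    with_duplication: bool = False,
) -> List[PrimerPair]:
    """Plant ``n`` primer pairs whose amplicons are genome substrings.

    Primers are copied from the genome, so e-PCR must recover each site
    exactly; both primers are rejection-sampled to be unique genome-wide.
    Half the pairs are emitted with swapped roles (the "reverse" primer
    matching the plus strand) to exercise both orientations.  With
    ``with_duplication`` every planted amplicon is duplicated onto a second
    locus, making each marker multi-mapped.
    """
    rng = np.random.default_rng(seed)
    used = [(s["chrom"], s["start"], s["end"]) for s in log.primer_sites]
    pairs = []
    for i in range(n):
        for _ in range(MAX_PLANT_RETRIES):
            amp = int(rng.integers(amplicon_range[0], amplicon_range[1] + 1))
            lf = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
            lr = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
            if lf + lr > amp:
                continue
            chrom, start, end = _pick_interval(rng, log, amp, used, min_sep=1)
            template = genome[chrom][start - 1 : end]
            fwd = template[:lf]
            rev = revcomp(template[-lr:])
            if _occurrences(genome, fwd) == 1 and _occurrences(genome, rev) == 1:
                break
        else:
            raise RuntimeError(
                "could not plant a unique primer pair; use a longer genome"
            )
        used.append((chrom, start, end))
        marker = f"mk{len(log.primer_sites) + 1:03d}"
        swapped = bool(rng.integers(0, 2))
        pair = (
            PrimerPair(marker, rev, fwd) if swapped else PrimerPair(marker, fwd, rev)
        )
        pairs.append(pair)
        log.primer_sites.append(
            {
                "marker_id": marker,
                "chrom": chrom,
                "start": start,
                "end": end,
                "plus_strand_primer": "reverse" if swapped else "forward",
            }
        )
    if with_duplication:
        _duplicate_primer_sites(genome, log)
    return pairs


def _duplicate_primer_sites(genome: Dict[str, str], log: PlantLog):
    """Copy each planted amplicon to a fresh locus so markers multi-map.

    Mutates the genome dict in place by appending a duplication arm to the
    last chromosome."""
    arm = []
    chrom = list(log.chrom_lengths)[-1]
    offset = log.chrom_lengths[chrom]
    extra = []
    for site in list(log.primer_sites):
        seq = genome[site["chrom"]][site["start"] - 1 : site["end"]]
        spacer = "T" * 50
        arm.append(spacer + seq)
        start = offset + sum(len(a) for a in arm[:-1]) + len(spacer) + 1
        extra.append(
            {**site, "chrom": chrom, "start": start, "end": start + len(seq) - 1}
        )
    genome[chrom] = genome[chrom] + "".join(arm)
    log.chrom_lengths[chrom] = len(genome[chrom])
    log.primer_sites.extend(extra)


def plant_flanks(
    genome: Dict[str, str],
    log: PlantLog,
    n: int = 50,
    length_range: Tuple[int, int] = (60, 200),
    seed: int = 0,
) -> List[FlankSequence]:
    """Plant ``n`` SNP flanking sequences with random strands and offsets.

    Each flank is a unique genome substring (or its reverse complement);
    the log records the strand and the true chromosome position of the
    variant base.
    """
    rng = np.random.default_rng(seed)
    used = [(s["chrom"], s["start"], s["end"]) for s in log.flank_sites]
    flanks = []
    for i in range(n):
        for _ in range(MAX_PLANT_RETRIES):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            chrom, start, end = _pick_interval(rng, log, L, used)
            sub = genome[chrom][start - 1 : end]
            if _occurrences(genome, sub) == 1:
                break
        else:
            raise RuntimeError("could not plant a unique flank; use a longer genome")
        used.append((chrom, start, end))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = sub if strand == "+" else revcomp(sub)
        offset = int(rng.integers(1, L + 1))
        snp_pos = start + offset - 1 if strand == "+" else end - offset + 1
        marker = f"fl{len(log.flank_sites) + 1:03d}"
        flanks.append(FlankSequence(marker, seq, offset))
        log.flank_sites.append(
            {
                "marker_id": marker,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "snp_offset": offset,
                "snp_chrom_pos": snp_pos,
            }
        )
    return flanks


def decompose_scaffolds(
    genome: Dict[str, str],
    log: PlantLog,
    n_per_chrom: int = 6,
    seed: int = 0,
) -> Tuple[List[ScaffoldPlacement], Dict[str, str]]:
    """Cut every chromosome into scaffolds with random orientations.

    The scaffolds tile each chromosome completely (no gaps), so every base
    position lifts to exactly one scaffold and back.  Scaffold sequences are
    written consistently with the placement table (reverse placements store
    the reverse complement of the chromosome slice).
    """
    rng = np.random.default_rng(seed)
    placements, seqs = [], {}
    for chrom, seq in genome.items():
        L = len(seq)
        n_cuts = min(n_per_chrom - 1, L - 1)
        cuts = sorted(rng.choice(np.arange(1, L), size=n_cuts, replace=False))
        bounds = [0, *map(int, cuts), L]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            sid = f"scf_{chrom}_{i:02d}"
            orientation = "+" if rng.integers(0, 2) == 0 else "-"
            piece = seq[a:b]
            placement = ScaffoldPlacement(
                scaffold_id=sid,
                scaffold_len=b - a,
                chrom=chrom,
                chr_start=a + 1,
                chr_end=b,
                orientation=orientation,
            )
            placements.append(placement)
            seqs[sid] = piece if orientation == "+" else revcomp(piece)
    log.placements = placements
    return placements, seqs


def plant_genes(
    genome: Dict[str, str],
    log: PlantLog,
    n: int = 200,
    length_range: Tuple[int, int] = (1, 3000),
    rga_fraction: float = 0.2,
    seed: int = 0,
) -> List[GeneRecord]:
    """Random gene loci (points allowed), a fraction flagged as RGAs."""
    rng = np.random.default_rng(seed)
    classes = ("NBS", "RLK", "TM-CC")
    genes = []
    chroms = list(log.chrom_lengths)
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        L = log.chrom_lengths[chrom]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        length = min(length, L)
        start = int(rng.integers(1, L - length + 2))
        rga = classes[rng.integers(0, 3)] if rng.random() < rga_fraction else None
        gene = GeneRecord(
            gene_id=f"gene{i + 1:04d}",
            locus=GenomicInterval(chrom, start, start + length - 1),
            annotation=f"synthetic gene {i + 1}",
            rga_class=rga,
        )
        genes.append(gene)
        log.gene_sites.append(
            {"gene_id": gene.gene_id, "chrom": chrom, "start": start,
             "end": start + length - 1, "rga_class": rga}
        )
    return genes


def make_qtl_fixture(
    sizes: Sequence[int],
    intra_gap: int = 50_000,
    inter_gap: int = 500_000,
    chrom: str = "chr1",
    start: int = 100_000,
    seed: int = 0,
) -> Tuple[List[QtlRecord], List[int]]:
    """Point QTL laid out as clusters of the requested ``sizes``.

    Consecutive points within a cluster are ``intra_gap`` apart (must be
    within the linkage window) and clusters are separated by ``inter_gap``
    (must exceed it), so the expected cluster sizes are exactly ``sizes``.
    """
    if intra_gap >= inter_gap:
        raise ValueError("intra_gap must be smaller than inter_gap")
    rng = np.random.default_rng(seed)
    traits = ("YLD", "PLH", "OIL", "TSW", "LIN")
    records = []
    pos = start
    qno = 0
    for size in sizes:
        for j in range(size):
            qno += 1
            records.append(
                QtlRecord(
                    qtl_no=qno,
                    trait=traits[rng.integers(0, len(traits))],
                    qtl_id=f"Q{qno:03d}",
                    loci=[GenomicInterval(chrom, pos, pos)],
                )
            )
            if j < size - 1:
                pos += intra_gap
        pos += inter_gap
    return records, list(sizes)
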