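"""Domain types shared across the toolkit.

All genomic coordinates are 1-based and inclusive at both ends, matching the
convention of published QTL tables; the BED writer in :mod:`pseudomap.io`
converts to 0-based half-open on output.  Types validate their invariants at
construction so that malformed records fail at load time, not mid-pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGT")

#: Trait abbreviations used in the published flax QTL compendium.  Unknown
#: codes only warn at load time so tables for other crops remain loadable.
KNOWN_TRAITS = frozenset(
    "YLD TSW SL SW SEB FN BSC NB DTF DTM PLH TL LDG IOD PRO OIL OLE PAL STE "
    "LIO LIN MC HC SC STW FY FC CEW FW PM PAS".split()
)

#: Resistance-gene-analog classes recognised by the gene scanner.
RGA_CLASSES = frozenset({"NBS", "RLK", "TM-CC", "other"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{what}: non-ACGT characters {sorted(bad)} (ambiguity codes are "
            "rejected, not expanded)"
        )
    return seq


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on a chromosome; a point locus has start == end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} < start {self.start} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class PrimerPair:
    """An SSR/AFLP marker given as two 5'->3' PCR primer sequences."""

    marker_id: str
    forward: str
    reverse: str

    def __post_init__(self):
        object.__setattr__(
            self, "forward", _check_dna(self.forward, f"{self.marker_id} forward")
        )
        object.__setattr__(
            self, "reverse", _check_dna(self.reverse, f"{self.marker_id} reverse")
        )


@dataclass(frozen=True)
class FlankSequence:
    """A SNP marker's flanking sequence with the variant base at ``snp_offset``."""

    marker_id: str
    seq: str
    snp_offset: int

    def __post_init__(self):
        object.__setattr__(self, "seq", _check_dna(self.seq, self.marker_id))
        if not 1 <= self.snp_offset <= len(self.seq):
            raise ValueError(
                f"{self.marker_id}: snp_offset {self.snp_offset} outside "
                f"sequence of length {len(self.seq)}"
            )


@dataclass(frozen=True)
class ScaffoldPlacement:
    """One scaffold's span and orientation on a chromosome.

    The placement table is the single source of truth for coordinate
    conversion; ``chr_end - chr_start + 1`` must equal the scaffold length.
    """

    scaffold_id: str
    scaffold_len: int
    chrom: str
    chr_start: int
    chr_end: int
    orientation: str  # '+' or '-'

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError(
                f"{self.scaffold_id}: orientation must be '+' or '-', "
                f"got {self.orientation!r}"
            )
        if self.chr_end - self.chr_start + 1 != self.scaffold_len:
            raise ValueError(
                f"{self.scaffold_id}: span {self.chr_start}-{self.chr_end} "
                f"has length {self.chr_end - self.chr_start + 1}, expected "
                f"scaffold_len {self.scaffold_len}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.chr_start, self.chr_end)


@dataclass
class QtlRecord:
    """A published QTL with zero, one, or many mapped loci.

    ``loci`` empty means the marker could not be mapped; length one is a
    unique placement; length > 1 is a multi-mapped marker, excluded from
    "uniquely mapped" counts.
    """

    qtl_no: int
    trait: str
    qtl_id: str
    source_ref: str = ""
    loci: list = field(default_factory=list)
    cluster_label: Optional[int] = None

    @property
    def is_unmapped(self) -> bool:
        return len(self.loci) == 0

    @property
    def is_unique(self) -> bool:
        return len(self.loci) == 1

    @property
    def is_multi(self) -> bool:
        return len(self.loci) > 1


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene; ``rga_class`` marks resistance gene analogs."""

    gene_id: str
    locus: GenomicInterval
    annotation: str = ""
    rga_class: Optional[str] = None

    def __post_init__(self):
        if self.rga_class is not None and self.rga_class not in RGA_CLASSES:
            raise ValueError(
                f"{self.gene_id}: unknown RGA class {self.rga_class!r}; "
                f"expected one of {sorted(RGA_CLASSES)}"
            )

    @property
    def is_rga(self) -> bool:
        return self.rga_class is not None


@dataclass(frozen=True)
class Cluster:
    """A co-location group of QTL sharing a label, with its spanning interval."""

    label: int
    chrom: str
    span: GenomicInterval
    members: tuple  # qtl_no of member records

    def __post_init__(self):
        if self.label < 1:
            raise ValueError(f"cluster label must be >= 1, got {self.label}")
        if not self.members:
            raise ValueError(f"cluster {self.label}: empty member list")
        if self.span.chrom != self.chrom:
            raise ValueError(
                f"cluster {self.label}: span chromosome {self.span.chrom} "
                f"!= {self.chrom}"
            )


@dataclass(frozen=True)
class WindowConfig:
    """Flanking window applied on each side of a locus (default 100 kb,
    i.e. a 200 kb window centred on the locus)."""

    flank_bp: int = 100_000

    def __post_init__(self):
        if self.flank_bp < 0:
            raise ValueError(f"flank_bp must be >= 0, got {self.flank_bp}")


#: Marker IDs of the form scaffoldNNN_POS / scaffoldNNN-POS encode the
#: scaffold and 1-based position the SNP was called on.
SCAFFOLD_MARKER_RE = re.compile(r"^(?P<scaffold>scaffold\d+)[-_](?P<pos>\d+)$")


def parse_scaffold_marker(marker_id: str):
    """Split ``scaffold116_30201`` style names into (scaffold_id, position).

    Returns None when the name does not follow the convention.
    """
    m = SCAFFOLD_MARKER_RE.match(marker_id)
    if m is None:
        return None
    return m.group("scaffold"), int(m.group("pos"))
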