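"""Readers and writers for the tables and sequence files the toolkit touches.

All tabular formats are plain TSV with a header row; lines starting with
``#`` are comments.  Readers enforce the domain-type invariants at load time
and name the offending row in error messages.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    KNOWN_TRAITS,
    FlankSequence,
    GeneRecord,
    GenomicInterval,
    PrimerPair,
    QtlRecord,
    ScaffoldPlacement,
)


class ParseError(ValueError):
    """Raised when an input file violates its format or a type invariant."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into an ordered mapping of id -> upper-cased sequence.

    Sequence IDs are the first whitespace token of each header.  Malformed
    headers and empty sequences raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def _validate_fasta_lines(path: Path):
    """Cheap pre-scan so errors can report 1-based line numbers."""
    last_header_line = None
    seq_seen = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if not seq_seen:
                    raise ParseError(
                        f"{path}:{last_header_line}: record has empty sequence"
                    )
                if not line[1:].strip():
                    raise ParseError(f"{path}:{lineno}: malformed FASTA header")
                last_header_line, seq_seen = lineno, False
            else:
                if last_header_line is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                seq_seen = True
    if last_header_line is not None and not seq_seen:
        raise ParseError(f"{path}:{last_header_line}: record has empty sequence")


def write_fasta(path, sequences: Dict[str, str], width: int = 60):
    """Write a mapping of id -> sequence as wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# generic TSV plumbing

def _read_rows(path, required: Iterable[str]) -> List[dict]:
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    missing = set(required) - set(reader.fieldnames or ())
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    return list(reader)


def _write_rows(path, fieldnames, rows):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def _int(value: str, path, row_id: str, what: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ParseError(f"{path}: row {row_id}: non-numeric {what} {value!r}")


# ---------------------------------------------------------------------------
# primers / flanks

def read_primer_table(path) -> List[PrimerPair]:
    """TSV with columns marker_id, forward, reverse."""
    pairs, seen = [], set()
    for row in _read_rows(path, ("marker_id", "forward", "reverse")):
        mid = row["marker_id"].strip()
        if mid in seen:
            raise ParseError(f"{path}: duplicate marker_id {mid!r}")
        seen.add(mid)
        try:
            pairs.append(PrimerPair(mid, row["forward"], row["reverse"]))
        except ValueError as exc:
            raise ParseError(f"{path}: row {mid}: {exc}") from exc
    return pairs


def write_primer_table(path, pairs: Iterable[PrimerPair]):
    _write_rows(
        path,
        ("marker_id", "forward", "reverse"),
        (
            {"marker_id": p.marker_id, "forward": p.forward, "reverse": p.reverse}
            for p in pairs
        ),
    )


def read_flank_table(path) -> List[FlankSequence]:
    """TSV with columns marker_id, seq, snp_offset (1-based within seq)."""
    flanks = []
    for row in _read_rows(path, ("marker_id", "seq", "snp_offset")):
        mid = row["marker_id"].strip()
        off = _int(row["snp_offset"], path, mid, "snp_offset")
        try:
            flanks.append(FlankSequence(mid, row["seq"], off))
        except ValueError as exc:
            raise ParseError(f"{path}: row {mid}: {exc}") from exc
    return flanks


def write_flank_table(path, flanks: Iterable[FlankSequence]):
    _write_rows(
        path,
        ("marker_id", "seq", "snp_offset"),
        (
            {"marker_id": f.marker_id, "seq": f.seq, "snp_offset": f.snp_offset}
            for f in flanks
        ),
    )


# ---------------------------------------------------------------------------
# scaffold placements

def read_placement_table(path) -> List[ScaffoldPlacement]:
    """TSV with columns scaffold_id, scaffold_len, chrom, chr_start, chr_end,
    orientation.  Placements on one chromosome must not overlap."""
    placements = []
    for row in _read_rows(
        path,
        ("scaffold_id", "scaffold_len", "chrom", "chr_start", "chr_end", "orientation"),
    ):
        sid = row["scaffold_id"].strip()
        try:
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=sid,
                    scaffold_len=_int(row["scaffold_len"], path, sid, "scaffold_len"),
                    chrom=row["chrom"].strip(),
                    chr_start=_int(row["chr_start"], path, sid, "chr_start"),
                    chr_end=_int(row["chr_end"], path, sid, "chr_end"),
                    orientation=row["orientation"].strip(),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {sid}: {exc}") from exc
    _check_placements_disjoint(placements, path)
    return placements


def _check_placements_disjoint(placements, origin):
    by_chrom: Dict[str, list] = {}
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.chr_start)
        for a, b in zip(ps, ps[1:]):
            if b.chr_start <= a.chr_end:
                raise ParseError(
                    f"{origin}: placements {a.scaffold_id} and {b.scaffold_id} "
                    f"overlap on {chrom}"
                )


def write_placement_table(path, placements: Iterable[ScaffoldPlacement]):
    _write_rows(
        path,
        ("scaffold_id", "scaffold_len", "chrom", "chr_start", "chr_end", "orientation"),
        (
            {
                "scaffold_id": p.scaffold_id,
                "scaffold_len": p.scaffold_len,
                "chrom": p.chrom,
                "chr_start": p.chr_start,
                "chr_end": p.chr_end,
                "orientation": p.orientation,
            }
            for p in placements
        ),
    )


def read_agp(path) -> List[ScaffoldPlacement]:
    """Minimal AGP v2.0 import: W (WGS contig/scaffold) lines become
    placements; gap lines (N/U) are skipped.  Columns: object, object_beg,
    object_end, part_number, component_type, component_id, component_beg,
    component_end, orientation."""
    placements = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 AGP columns")
            if f[4] in ("N", "U"):
                continue
            if int(f[6]) != 1:
                raise ParseError(
                    f"{path}:{lineno}: partial component placements not supported"
                )
            placements.append(
                ScaffoldPlacement(
                    scaffold_id=f[5],
                    scaffold_len=int(f[7]),
                    chrom=f[0],
                    chr_start=int(f[1]),
                    chr_end=int(f[2]),
                    orientation="-" if f[8] == "-" else "+",
                )
            )
    _check_placements_disjoint(placements, path)
    return placements


# ---------------------------------------------------------------------------
# genes

def read_gene_table(path) -> List[GeneRecord]:
    """TSV with columns gene_id, chrom, start, end, annotation, rga_class.

    ``end`` may be empty for point genes; empty rga_class means "not an RGA".
    """
    genes, seen = [], set()
    for row in _read_rows(path, ("gene_id", "chrom", "start")):
        gid = row["gene_id"].strip()
        if gid in seen:
            raise ParseError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        start = _int(row["start"], path, gid, "start")
        end_raw = (row.get("end") or "").strip()
        end = _int(end_raw, path, gid, "end") if end_raw else start
        rga = (row.get("rga_class") or "").strip() or None
        try:
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    locus=GenomicInterval(row["chrom"].strip(), start, end),
                    annotation=(row.get("annotation") or "").strip(),
                    rga_class=rga,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {gid}: {exc}") from exc
    return genes


def write_gene_table(path, genes: Iterable[GeneRecord]):
    _write_rows(
        path,
        ("gene_id", "chrom", "start", "end", "annotation", "rga_class"),
        (
            {
                "gene_id": g.gene_id,
                "chrom": g.locus.chrom,
                "start": g.locus.start,
                "end": g.locus.end,
                "annotation": g.annotation,
                "rga_class": g.rga_class or "",
            }
            for g in genes
        ),
    )


# ---------------------------------------------------------------------------
# QTL tables

def _parse_locus_column(value: str) -> List[str]:
    """Split a possibly dual-valued cell: '7 (4)' -> ['7', '4']."""
    value = value.strip()
    if value.endswith(")") and "(" in value:
        first, rest = value.split("(", 1)
        return [first.strip(), rest[:-1].strip()]
    return [value]


def read_qtl_table(path) -> List[QtlRecord]:
    """TSV with columns qtl_no, trait, qtl_id, chrom, start, end,
    cluster_label, source (extra columns are ignored).

    ``chrom`` may be ``NA`` (unmapped marker -> empty loci) or a dual form
    like ``7 (4)`` with parenthesized alternates in start/end, yielding two
    loci.  Descending printed ranges are normalized to start <= end.
    """
    records, seen = [], set()
    for row in _read_rows(
        path, ("qtl_no", "trait", "qtl_id", "chrom", "start", "end", "cluster_label")
    ):
        qno = _int(row["qtl_no"], path, row["qtl_no"], "qtl_no")
        if qno in seen:
            raise ParseError(f"{path}: duplicate qtl_no {qno}")
        seen.add(qno)
        trait = row["trait"].strip()
        if trait and trait not in KNOWN_TRAITS:
            warnings.warn(f"{path}: row {qno}: unknown trait code {trait!r}")
        chrom_raw = row["chrom"].strip()
        loci = []
        if chrom_raw and chrom_raw != "NA":
            chroms = _parse_locus_column(chrom_raw)
            starts = _parse_locus_column(row["start"])
            ends = _parse_locus_column(row["end"])
            if not len(chroms) == len(starts) == len(ends):
                raise ParseError(
                    f"{path}: row {qno}: chrom/start/end arity mismatch"
                )
            for c, s, e in zip(chroms, starts, ends):
                s_i = _int(s, path, qno, "start")
                e_i = _int(e, path, qno, "end")
                if s_i > e_i:  # a few published rows print descending ranges
                    s_i, e_i = e_i, s_i
                loci.append(GenomicInterval(c, s_i, e_i))
        label_raw = row["cluster_label"].strip()
        label = None if label_raw in ("", "NA") else _int(label_raw, path, qno, "cluster_label")
        records.append(
            QtlRecord(
                qtl_no=qno,
                trait=trait,
                qtl_id=row["qtl_id"].strip(),
                source_ref=(row.get("source") or "").strip(),
                loci=loci,
                cluster_label=label,
            )
        )
    return records


def write_qtl_table(path, records: Iterable[QtlRecord]):
    rows = []
    for r in records:
        if not r.loci:
            chrom = start = end = "NA"
        else:
            chrom = _join_dual(loc.chrom for loc in r.loci)
            start = _join_dual(str(loc.start) for loc in r.loci)
            end = _join_dual(str(loc.end) for loc in r.loci)
        rows.append(
            {
                "qtl_no": r.qtl_no,
                "trait": r.trait,
                "qtl_id": r.qtl_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "cluster_label": "NA" if r.cluster_label is None else r.cluster_label,
                "source": r.source_ref,
            }
        )
    _write_rows(
        path,
        ("qtl_no", "trait", "qtl_id", "chrom", "start", "end", "cluster_label", "source"),
        rows,
    )


def _join_dual(values) -> str:
    values = list(values)
    if len(values) == 1:
        return values[0]
    return f"{values[0]} ({') ('.join(values[1:])})"


# ---------------------------------------------------------------------------
# hit tables

def write_hits(path, hits, bed_path=None):
    """Write e-PCR hits as a 1-based TSV plus a 0-based half-open BED file.

    ``bed_path`` defaults to ``path`` with a ``.bed`` suffix.
    """
    path = Path(path)
    bed_path = Path(bed_path) if bed_path else path.with_suffix(".bed")
    _write_rows(
        path,
        ("marker_id", "chrom", "start", "end", "amplicon_len", "plus_strand_primer"),
        (
            {
                "marker_id": h.marker_id,
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "amplicon_len": h.amplicon_len,
                "plus_strand_primer": h.plus_strand_primer,
            }
            for h in hits
        ),
    )
    with open(bed_path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start - 1}\t{h.interval.end}"
                f"\t{h.marker_id}\n"
            )
    return path, bed_path
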