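"""Packaged catalogs: the published compendium of 200 flax QTL re-mapped to
the chromosome-scale pseudomolecules, and the six resistance-gene-analog
(RGA) candidates reported near the three powdery-mildew QTL.

The TSVs under ``pseudomap/data`` are versioned transcriptions of the
published tables (one curated label fix is documented in the file header);
a SHA-256 test guards them against silent drift.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import List, Tuple

from .io import read_qtl_table, _read_rows
from .model import GeneRecord, GenomicInterval, QtlRecord

_QTL_FILE = "flax_qtl_catalog.tsv"
_RGA_FILE = "flax_rga_candidates.tsv"


def _data_path(name: str) -> Path:
    return Path(resources.files("pseudomap") / "data" / name)


def catalog_sha256(name: str = _QTL_FILE) -> str:
    """Checksum of a packaged data file (drift guard for tests)."""
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def flax_qtl_catalog() -> List[QtlRecord]:
    """The 200 published flax QTL with curated co-location labels.

    Three records are unmapped (empty loci) and one marker, assayed for two
    traits, maps to two chromosomes (two records with two loci each).
    """
    return read_qtl_table(_data_path(_QTL_FILE))


def flax_rga_catalog() -> Tuple[List[QtlRecord], List[GeneRecord]]:
    """The three powdery-mildew QTL and the six RGA candidates near them.

    Returns (qtl_records, gene_records); gene positions are single printed
    coordinates, represented as 1-bp intervals.
    """
    rows = _read_rows(
        _data_path(_RGA_FILE),
        ("qtl_no", "qtl_id", "chrom", "qtl_start", "qtl_end", "gene_id",
         "gene_pos", "rga_class"),
    )
    qtl: dict = {}
    genes: List[GeneRecord] = []
    for row in rows:
        qno = int(row["qtl_no"])
        if qno not in qtl:
            qtl[qno] = QtlRecord(
                qtl_no=qno,
                trait="PM",
                qtl_id=row["qtl_id"],
                loci=[
                    GenomicInterval(
                        row["chrom"], int(row["qtl_start"]), int(row["qtl_end"])
                    )
                ],
            )
        pos = int(row["gene_pos"])
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                locus=GenomicInterval(row["chrom"], pos, pos),
                annotation=row["rga_class"],
                rga_class=row["rga_class"],
            )
        )
    return list(qtl.values()), genes
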