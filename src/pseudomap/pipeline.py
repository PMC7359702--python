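"""End-to-end orchestration: e-PCR / flank mapping -> liftover -> clustering
-> gene scan -> summary, driven by one declarative config.

Every run writes its resolved parameter set and a manifest next to the
outputs, and reruns with an identical config produce byte-identical result
tables (no timestamps are embedded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

from . import catalog, io
from .clustering import WindowConfig, assign_labels, summarize_clusters
from .epcr import DEFAULT_MAX_AMPLICON, DEFAULT_WORD_SIZE, PrimerIndex, epcr
from .flanks import DEFAULT_EVALUE, map_flank, snp_position, top_hits
from .genescan import scan_all
from .liftover import PlacementTable, lift_marker
from .model import QtlRecord

log = logging.getLogger("pseudomap")

_INPUT_KEYS = ("genome", "index", "primers", "flanks", "placements",
               "markers", "qtl", "genes")

DEFAULT_PARAMS = {
    "word_size": DEFAULT_WORD_SIZE,
    "max_amplicon": DEFAULT_MAX_AMPLICON,
    "evalue": DEFAULT_EVALUE,
    "window_bp": 100_000,
    "rga_only": False,
    "use_printed_labels": False,
}


def run_pipeline(config: Dict, out_dir) -> Dict:
    """Run every stage for which the config names an input.

    ``config`` has two sections: ``inputs`` (paths; all optional) and
    ``params`` (overrides of :data:`DEFAULT_PARAMS`).  Returns the summary
    dict; all stage outputs land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {k: v for k, v in (config.get("inputs") or {}).items() if v}
    unknown = set(inputs) - set(_INPUT_KEYS)
    if unknown:
        raise ValueError(f"unknown input keys: {sorted(unknown)}")
    missing = [str(p) for p in inputs.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "missing input file(s): " + ", ".join(missing)
        )
    params = {**DEFAULT_PARAMS, **(config.get("params") or {})}
    manifest = {"params": params, "inputs": {k: str(v) for k, v in inputs.items()},
                "outputs": []}

    def emit(name):
        manifest["outputs"].append(name)
        return out_dir / name

    index: Optional[PrimerIndex] = None
    if "index" in inputs:
        index = PrimerIndex.load(inputs["index"])
    elif "genome" in inputs:
        log.info("indexing genome")
        index = PrimerIndex(io.read_fasta(inputs["genome"]), params["word_size"])

    if "primers" in inputs:
        if index is None:
            raise ValueError("primers given but no genome or index")
        pairs = io.read_primer_table(inputs["primers"])
        hits = [
            h for p in pairs for h in epcr(p, index, params["max_amplicon"])
        ]
        io.write_hits(emit("epcr_hits.tsv"), hits, emit("epcr_hits.bed"))
        log.info("e-PCR: %d pairs -> %d hits", len(pairs), len(hits))

    if "flanks" in inputs:
        if index is None:
            raise ValueError("flanks given but no genome or index")
        flanks = io.read_flank_table(inputs["flanks"])
        rows = []
        for fl in flanks:
            best = top_hits(map_flank(fl, index, params["evalue"]))
            status = ("unmapped", "unique", "multi")[min(len(best), 2)]
            for h in best:
                chrom, pos = snp_position(h, fl.snp_offset)
                rows.append(
                    f"{fl.marker_id}\t{chrom}\t{pos}\t{h.strand}\t{h.score}"
                    f"\t{h.evalue:.3g}\t{status}"
                )
            if not best:
                rows.append(f"{fl.marker_id}\tNA\tNA\tNA\tNA\tNA\tunmapped")
        path = emit("snp_positions.tsv")
        path.write_text(
            "marker_id\tchrom\tpos\tstrand\tscore\tevalue\tstatus\n"
            + "".join(r + "\n" for r in rows)
        )
        log.info("flank mapping: %d flanks", len(flanks))

    if "placements" in inputs and "markers" in inputs:
        table = PlacementTable(io.read_placement_table(inputs["placements"]))
        with open(inputs["markers"]) as fh:
            names = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
        if names and names[0] == "marker_id":
            names = names[1:]
        rows = []
        for name in names:
            lifted = lift_marker(name, table)
            if lifted is None:
                rows.append(f"{name}\tNA\tNA")
            else:
                rows.append(f"{name}\t{lifted[0]}\t{lifted[1]}")
        path = emit("lifted_markers.tsv")
        path.write_text("marker_id\tchrom\tpos\n" + "".join(r + "\n" for r in rows))
        log.info("liftover: %d markers", len(names))

    summary = None
    records = None
    if "qtl" in inputs:
        records = io.read_qtl_table(inputs["qtl"])
        window = WindowConfig(params["window_bp"])
        if not params["use_printed_labels"]:
            records, clusters = assign_labels(records, window)
            with open(emit("clusters.tsv"), "w") as fh:
                fh.write("label\tchrom\tstart\tend\tn_members\tmembers\n")
                for c in clusters:
                    fh.write(
                        f"{c.label}\t{c.chrom}\t{c.span.start}\t{c.span.end}"
                        f"\t{len(c.members)}\t{','.join(map(str, c.members))}\n"
                    )
        io.write_qtl_table(emit("qtl_labeled.tsv"), records)
        summary = summarize_clusters(records)
        (emit("summary.json")).write_text(
            json.dumps(
                {**asdict(summary),
                 "sizes": {str(k): v for k, v in summary.sizes.items()},
                 "n_clusters_min_size_3": summary.n_clusters_min_size(3)},
                indent=2, sort_keys=True,
            ) + "\n"
        )

    if "genes" in inputs and records is not None:
        genes = io.read_gene_table(inputs["genes"])
        window = WindowConfig(params["window_bp"])
        pairs_df, unique = scan_all(records, genes, window, params["rga_only"])
        pairs_df.to_csv(emit("candidate_genes.tsv"), sep="\t", index=False)
        log.info("gene scan: %d pairs, %d unique genes", len(pairs_df), len(unique))

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {"summary": summary, "manifest": manifest}


def write_catalog_inputs(out_dir) -> Dict[str, Path]:
    """Materialize the packaged flax catalogs as pipeline-ready TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qtl_path = out_dir / "qtl.tsv"
    io.write_qtl_table(qtl_path, catalog.flax_qtl_catalog())
    rga_qtl, rga_genes = catalog.flax_rga_catalog()
    genes_path = out_dir / "rga_genes.tsv"
    io.write_gene_table(genes_path, rga_genes)
    rga_qtl_path = out_dir / "pm_qtl.tsv"
    io.write_qtl_table(rga_qtl_path, rga_qtl)
    return {"qtl": qtl_path, "genes": genes_path, "pm_qtl": rga_qtl_path}
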