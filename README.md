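# pseudomap

Re-map PCR- and SNP-based genetic markers onto a chromosome-scale reference
("pseudomolecules"), group the QTL they tag into co-location clusters, and
scan candidate genes around them.

## The problem

QTL for crop traits accumulate across studies that used different reference
frames: PCR primer pairs tied to no reference at all, SNPs called on
scaffold assemblies, SNPs called on earlier pseudomolecule drafts.  Once a
chromosome-scale assembly exists (the motivating case is cultivated flax,
*Linum usitatissimum*, with 622 scaffolds ordered into 15 chromosomes),
all of those markers must be placed on the *same* coordinate system before
QTL can be compared across studies, grouped, or linked to candidate genes.
`pseudomap` implements the four operations that re-mapping needs:

1. **Electronic PCR** (`pseudomap.epcr`) — index the genome by k-mers and
   locate each primer pair in valid head-to-head orientation with zero
   mismatches or gaps.  A hit is an amplicon: the plus-strand primer's
   5′ end to the image of the other primer's 5′ end, with inward-facing
   3′ ends and span ≤ `max_amplicon` (default 10 kb).
2. **Flank alignment** (`pseudomap.flanks`) — seed-and-extend, ungapped
   alignment of SNP flanking sequences (match +1 / mismatch −2, X-drop 10)
   filtered by the Karlin–Altschul expectation
   `E = K·m·n·e^(−λS)` with the standard ungapped constants λ = 1.374,
   K = 0.711 and a default cutoff of E ≤ 10⁻³⁰; the SNP offset within the
   flank is then converted to a chromosome position.
3. **Lift-over** (`pseudomap.liftover`) — deterministic scaffold ↔
   chromosome conversion through a placement table (span + orientation per
   scaffold): `chr_pos = chr_start + pos − 1` on `+` placements and
   `chr_pos = chr_end − pos + 1` on `−` placements, with the exact inverse
   and length-preserving interval lifts.
4. **Window clustering and gene scanning** (`pseudomap.clustering`,
   `pseudomap.genescan`) — QTL within ±100 kb of each other (single
   linkage, so clusters chain) are co-located; genes intersecting the
   ±100 kb window of a QTL interval are its candidates, with resistance
   gene analogs (NBS / RLK / TM-CC classes) as an optional filter.

The package also ships, under `pseudomap.catalog`, a curated transcription
of the published flax compendium: 200 QTL for 30 traits with their
re-mapped coordinates and co-location labels, and the six RGA candidates
reported near the three powdery-mildew QTL.  Synthetic fixture generators
with complete ground-truth logs (`pseudomap.synthetic`) stand in for the
real 316 Mb flax reference, which is not required for anything here.

## Worked example

```python
>>> import pseudomap as pm

>>> records = pm.flax_qtl_catalog()
>>> s = pm.summarize_clusters(records)
>>> (s.n_records, s.n_unmapped, s.n_multi, s.n_mapped_unique)
(200, 3, 2, 195)
>>> (s.n_clusters, s.n_clusters_min_size(3), s.n_traits)
(132, 15, 26)
```

Of the 200 catalogued QTL, 3 markers could not be placed (missing primer
sequences, or a primer designed from a different genotype) and one SNP
marker — assayed for two traits, hence two records — maps to both
chromosomes 4 and 7, leaving 195 uniquely mapped QTL covering 26 traits.
Their curated co-location labels form 132 clusters, 15 of which contain at
least three QTL; the largest, on chromosome 4, holds eight QTL for six
yield-related traits:

```python
>>> label = {r.qtl_id: r.cluster_label for r in records}["QDm.BM.crc-LG4"]
>>> sorted(r.qtl_id for r in records if r.is_unique and r.cluster_label == label)
['QCw.BM.crc-LG4', 'QDTM-Lu4.1', 'QDm.BM.crc-LG4', 'QPLH-Lu4.3',
 'QSpb.BM.crc-LG4', 'QSw.BM.crc-LG4', 'QYLD-Lu4.1', 'QYld.BM.crc-LG4']
```

Gene scanning on the printed coordinates recovers all six published
(powdery-mildew QTL, RGA) pairs:

```python
>>> qtl, genes = pm.flax_rga_catalog()
>>> pairs, unique = pm.scan_all(qtl, genes, rga_only=True)
>>> len(pairs), sorted(unique)[:2]
(6, ['Lus10001677', 'Lus10009703'])
```

The same operations are exposed as a CLI:

```bash
pseudomap build-db --fasta genome.fa --word-size 12 --out genome.idx
pseudomap epcr --index genome.idx --primers primers.tsv --out hits.tsv
pseudomap map-flanks --index genome.idx --flanks flanks.tsv --evalue 1e-30 --out snp.tsv
pseudomap liftover --placements placements.tsv --in markers.tsv --out lifted.tsv
pseudomap cluster --qtl qtl.tsv --window 100000 --out clusters.tsv
pseudomap scan-genes --qtl qtl.tsv --genes genes.tsv --rga-only --out candidates.tsv
pseudomap make-fixture --preset epcr --seed 1 --out fixture/
pseudomap pipeline --config config.yaml --out results/
```

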