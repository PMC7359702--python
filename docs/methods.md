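# Methods

## Coordinate conventions

All coordinates are 1-based and inclusive at both ends, matching the
convention of published QTL tables; a point locus has `start == end`.  The
only 0-based, half-open representation in the package is the BED export of
e-PCR hits.  A handful of published rows print descending coordinate
ranges (a strand artifact of the original mapping); the QTL reader
normalizes these to `start <= end` on load and the packaged catalog keeps
them as printed.

## Electronic PCR

The engine implements the exact-match special case of electronic PCR:
the motivating workflow fixed mismatches and gaps to zero, so the general
mismatch/gap machinery of classical e-PCR tools is unnecessary, and exact
k-mer anchoring plus full-length string comparison is both simpler and
provably complete for this case.

* **Index.** Every k-mer of the genome (default `word_size = 12`) maps to
  its sorted (chromosome, start) occurrence list.  K-mers containing any
  non-ACGT base are omitted, so masked regions never seed a hit.  The
  index is a plain Python mapping, pickled for persistence; it targets
  genomes up to the tens of megabases on a workstation, which covers the
  fixture scales used here (the 316 Mb flax reference would want a
  succinct index, a deliberate non-goal).
* **Search.** Each primer is anchored at its 3′-terminal k-mer — the
  PCR-relevant end, where a mismatch aborts extension — and candidates are
  verified by full-length exact comparison.  Both arrangements are
  searched: forward primer on the plus strand with the reverse primer
  annealing downstream on the minus strand, and the mirror case.  A valid
  hit has inward-facing 3′ ends, amplicon length at least the sum of the
  two primer lengths (overlapping primer footprints are rejected as
  physically meaningless), and at most `max_amplicon`.
* **`max_amplicon` default 10,000 bp.**  No bound is stated in the
  motivating workflow; unbounded search would join unrelated primer sites
  across a chromosome, and 10 kb comfortably exceeds any PCR-practical
  amplicon.  CLI-overridable.
* **Ambiguity codes** in primers are rejected at load, not expanded:
  zero-mismatch semantics are ambiguous for degenerate bases.
* A marker is *unmapped* (0 hits), *unique* (1), or *multi* (≥ 2, whether
  on one chromosome or several); multi-mapped markers are excluded from
  "uniquely mapped" counts downstream.

## Flank alignment

SNP flanking sequences are placed by seed-and-extend: exact k-mer seeds
from the shared index on both strands, deduplicated per diagonal, then
ungapped X-drop extension (match +1, mismatch −2, X-drop 10).  Published
flank placements are near-exact, so gapped alignment is out of scope; the
hit schema (subject interval, query span, strand, score, E-value) is
aligner-agnostic, and a gapped aligner could be slotted in behind it.

Significance uses the Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` with the standard ungapped +1/−2 constants λ = 1.374
and K = 0.711 (declared in `pseudomap.flanks`, not tuned), `m` the flank
length and `n` twice the genome length (both strands searched).  The
default cutoff E ≤ 10⁻³⁰ is the one the motivating workflow used for its
flank searches; a 200 bp perfect match against a 30 Mb genome scores
E ≈ 10⁻¹⁰⁹, so genuine placements pass with enormous margin.  "Top hits"
are all hits within 10⁻³ relative score of the best; more than one top hit
across loci marks the marker multi-mapped rather than silently picking
one — the package reports ambiguity instead of emulating the manual
verification the original workflow applied.

The variant base's chromosome position follows from the aligned span:
`subject.start + (offset − query_start)` on `+`, mirrored through
`subject.end` on `−`; an offset outside the aligned span is an error (the
SNP fell off the alignment), never a silent extrapolation.

## Lift-over

The placement table — scaffold length, chromosome span, orientation — is
the single source of truth; no sequence comparison is performed during
conversion (an optional `verify_placements` checks scaffold sequences
against oriented chromosome slices when both FASTAs are available).
Placements must tile without overlap; chromosome positions between
placements are reported "unplaced" rather than raising, since
inter-scaffold gaps are expected in real assemblies.  Interval lifts move
both endpoints independently and re-order them (reverse placements flip
intervals), which preserves length exactly.  Marker names of the form
`scaffoldNNN_POS` / `scaffoldNNN-POS` (the convention of scaffold-called
SNPs) are parsed by a documented regex so whole tables lift in one pass.
Each scaffold is assumed placed exactly once; chained or partial
placements are a non-goal.

## Co-location clustering

Two QTL co-locate when the gap between their intervals (bases strictly
between nearest ends; 0 on overlap; infinite across chromosomes) is at
most `flank_bp`, default 100,000 — the "100 kb upstream and downstream"
window read inclusively, so point QTL printed 100 kb apart (gap 99,999)
link.  Clusters are connected components under single linkage, computed by
a per-chromosome sweep with a running maximum end, which is exactly the
transitive closure in one dimension; chains can therefore span far more
than one window, and published clusters wider than 200 kb are the expected
product of chaining over intervals.  QTL intervals are used as printed
(flanking-marker spans), never reduced to midpoints.  Labels are assigned
1..N by (chromosome order of first appearance, leftmost member), so
membership is permutation-invariant and labels change only by that
deterministic relabeling.  Multi-mapped markers are excluded by default
and can be included (each locus independently) with a flag.

The packaged catalog carries *curated* labels, which the summary
operations treat as ground truth; the rule-based clusterer is validated by
oracle equivalence on synthetic data rather than by reproduction of every
curated label, because the curated labels do not everywhere follow the
stated rule (see "Catalog notes").

## Gene scanning

A gene is a candidate for a QTL when its locus intersects
`[qtl.start − flank_bp, qtl.end + flank_bp]`, boundaries inclusive, on the
same chromosome — the window wraps the QTL *interval* as printed, not an
inferred peak (a published RGA candidate lies inside its QTL's printed
interval, which only interval semantics produces).  Genes given as single
positions are 1-bp intervals.  Lookup uses a per-chromosome interval tree;
the reported `distance_bp` is the same gap statistic as clustering (0 on
overlap).  The unique-candidate set deduplicates genes shared by several
QTL windows.  Functional annotation itself (protein-level orthology
searches) is consumed as a provided column, never computed.

## Synthetic fixtures

Generators produce genomes, primer pairs, flanks, scaffold decompositions,
genes, and QTL layouts, all driven by seeded PCG64 streams and logged in a
`PlantLog` that predicts every module's correct output exactly.  Genomes
are uniform random ACGT with no repeat or GC structure — sufficient
because every algorithm here is exact-match based; what passing tests on
these fixtures show is algorithmic correctness (completeness of the
anchored search, exactness of coordinate arithmetic), not robustness to
repetitive or biased real genomes.  Multi-mapping behaviour is exercised
by an explicit duplication mode rather than by chance repeats.  Planted
primers and flanks are rejection-sampled (bounded retries) to be unique
genome-wide so that recall/precision against the plant log are
well-defined; fixture scales (tens of kb to 1 Mb, 20 primer pairs, 50
flanks, 200-record QTL sets) keep the full suite under a minute while
staying large enough that naive-oracle comparisons are meaningful.

## Catalog notes

The packaged QTL catalog is a transcription of the published compendium of
200 re-mapped flax QTL: 3 records unmapped, 2 records (one marker, two
traits) on two chromosomes, 195 uniquely mapped covering 26 traits, with
the printed co-location labels.  Two caveats are documented rather than
hidden:

* One row (QTL 139, chromosome 9) prints cluster label 80, which belongs
  to a chromosome-8 cluster, while chromosome-9 labels otherwise run 83–90
  with 89 absent; the packaged file corrects this single label to 89 and
  says so in its header.
* The curated labels yield **132** distinct clusters (label 125 never
  occurs) of which **15** have ≥ 3 members, whereas the accompanying prose
  reports 133 and 13; re-clustering the 195 loci strictly by the ±100 kb
  rule gives 126 and 14 (the curated labels both merge pairs with gaps
  over 100 kb and split overlapping intervals).  The package reports what
  the table contains and, separately, what the rule computes; it does not
  guess which per-case curation produced the prose counts.

A SHA-256 test pins both packaged files so the transcriptions cannot
drift silently.

## Known limitations

* The k-mer index is memory-naive; indexing full plant genomes is out of
  scope.
* The flank aligner is ungapped by design; indel-containing flanks will
  map partially or not at all (the SNP-offset conversion then errors
  rather than extrapolating).
* E-values use fixed ungapped constants; no length-adjusted "effective"
  search space correction is applied, which is conservative at these
  scales.
* Trait codes are validated against the published abbreviation list but
  unknown codes only warn, keeping tables for other crops loadable.
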