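"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: plain string
scans, all-pairs distance checks, and transitive closure over an explicit
link matrix.
"""

import math

from pseudomap.model import revcomp


def find_all(haystack: str, needle: str):
    """All 1-based start positions of overlapping exact occurrences."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i + 1)
        i = haystack.find(needle, i + 1)
    return out


def naive_epcr(genome, forward, reverse, max_amplicon):
    """O(n*m) two-strand scan: every placement of one primer on the plus
    strand paired with the other primer's reverse complement downstream."""
    hits = set()
    for chrom, seq in genome.items():
        for plus, minus in ((forward, reverse), (reverse, forward)):
            for fstart in find_all(seq, plus):
                for mstart in find_all(seq, revcomp(minus)):
                    end = mstart + len(minus) - 1
                    amp = end - fstart + 1
                    if len(plus) + len(minus) <= amp <= max_amplicon:
                        hits.add((chrom, fstart, end))
    return sorted(hits)


def transitive_closure_clusters(loci, flank_bp):
    """Connected components of the pairwise-link relation, by label
    propagation over an explicit adjacency matrix.

    ``loci`` is a list of (chrom, start, end, ident); returns a sorted list
    of frozensets of idents.
    """
    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = loci[i]
            cj, sj, ej, _ = loci[j]
            if ci != cj:
                continue
            if si <= ej and sj <= ei:
                gap = 0
            else:
                gap = max(si, sj) - min(ei, ej) - 1
            if gap <= flank_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(loci[i][3])
    return sorted(
        (frozenset(g) for g in groups.values()), key=lambda g: sorted(g)
    )


def quadratic_gene_scan(qtl_loci, genes, flank_bp):
    """All (qtl, gene) pairs whose window intersection holds, by checking
    every pair directly.  ``qtl_loci``: (qtl_id, chrom, start, end);
    ``genes``: (gene_id, chrom, start, end)."""
    pairs = set()
    for qid, qc, qs, qe in qtl_loci:
        lo, hi = qs - flank_bp, qe + flank_bp
        for gid, gc, gs, ge in genes:
            if gc == qc and gs <= hi and ge >= lo:
                pairs.add((qid, gid))
    return pairs


def karlin_altschul_evalue(score, m, genome_len, lam=1.374, kappa=0.711):
    return kappa * m * (2 * genome_len) * math.exp(-lam * score)
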