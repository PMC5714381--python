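"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive results by explicit enumeration or base-set
materialization, sharing no code with the package's own algorithms.
"""

from __future__ import annotations

import math
from itertools import combinations

FEATURE_ORDER = (
    "Promoter",
    "FivePrimeUTR",
    "ThreePrimeUTR",
    "Exon",
    "Intron",
    "Downstream",
    "DistalIntergenic",
)


def brute_force_feature_sets(gene, promoter_window=3000, downstream_window=3000):
    """Materialize each feature's base set for one gene as explicit sets."""
    s, e, strand = gene.span.start, gene.span.end, gene.span.strand
    tss = s if strand == "+" else e - 1
    exonic = set()
    for ex in gene.exons:
        exonic |= set(range(ex.start, ex.end))
    sets = {
        "Promoter": {
            x for x in range(max(0, tss - promoter_window), tss + promoter_window + 1)
        },
        "Exon": set(exonic),
        "Intron": set(range(s, e)) - exonic,
    }
    if gene.cds_start is not None:
        cds = set(range(gene.cds_start, gene.cds_end))
        left = {x for x in exonic if x < gene.cds_start}
        right = {x for x in exonic if x >= gene.cds_end}
        if strand == "+":
            sets["FivePrimeUTR"], sets["ThreePrimeUTR"] = left, right
        else:
            sets["FivePrimeUTR"], sets["ThreePrimeUTR"] = right, left
    else:
        sets["FivePrimeUTR"] = sets["ThreePrimeUTR"] = set()
    if strand == "+":
        sets["Downstream"] = set(range(e, e + downstream_window))
    else:
        sets["Downstream"] = set(range(max(0, s - downstream_window), s))
    return sets, tss


def brute_force_classify(chrom, summit, genes, promoter_window=3000,
                         downstream_window=3000):
    """Classify a summit against explicit base sets; returns (feature, gene_id)."""
    chrom_genes = [g for g in genes if g.span.chrom == chrom]
    if not chrom_genes:
        raise ValueError(f"no genes on {chrom}")
    per_gene = {
        g.gene_id: brute_force_feature_sets(g, promoter_window, downstream_window)
        for g in chrom_genes
    }
    for feature in FEATURE_ORDER[:-1]:
        hits = [
            (abs(summit - tss), gid)
            for gid, (sets, tss) in per_gene.items()
            if summit in sets[feature]
        ]
        if hits:
            return feature, min(hits)[1]
    dist, gid = min((abs(summit - tss), gid) for gid, (_, tss) in per_gene.items())
    return "DistalIntergenic", gid


def brute_force_merge(intervals, max_gap):
    """Single-linkage closure of the 'gap < max_gap' relation.

    ``intervals``: list of (chrom, start, end, sample).  Returns a list
    of frozenset memberships, one per connected component.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = intervals[i]
            cj, sj, ej, _ = intervals[j]
            if ci != cj:
                continue
            gap = max(sj - ei, si - ej, 0)
            if gap < max_gap:
                union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(intervals[i][3])
    return [frozenset(m) for m in comps.values()]


def hypergeom_enumerate(N_pop, K, n, k):
    """Exact hypergeometric tails by summation of combinatorial mass."""

    def pmf(x):
        if x < max(0, n - (N_pop - K)) or x > min(n, K):
            return 0.0
        return math.comb(K, x) * math.comb(N_pop - K, n - x) / math.comb(N_pop, n)

    p_enrich = sum(pmf(x) for x in range(k, min(n, K) + 1))
    p_deplete = sum(pmf(x) for x in range(0, k + 1))
    return p_enrich, p_deplete


def ranksum_exact_p_greater(a, b):
    """One-sided p(a stochastically greater) by enumerating rank assignments."""
    pooled = sorted(a) + sorted(b)
    na = len(a)
    obs = sum(sorted(pooled).index(x) + 1 for x in sorted(a))  # no ties assumed
    count = total = 0
    ranks = range(1, len(pooled) + 1)
    for combo in combinations(ranks, na):
        total += 1
        if sum(combo) >= obs:
            count += 1
    return count / total
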