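"""Brute-force reference implementations used as independent cross-checks.

These materialize answers by explicit enumeration (base sets, pairwise
closure, combinatorial sums) and share no logic with the package's
algorithms; the experiment drivers compare the two routes.
"""

from __future__ import annotations

import math

from .genome_annotation import FEATURE_CLASSES, GeneModel


def feature_base_sets(gene: GeneModel, promoter_window: int = 3000,
                      downstream_window: int = 3000) -> tuple[dict, int]:
    """Explicit per-base feature membership sets for one gene."""
    s, e, strand = gene.span.start, gene.span.end, gene.span.strand
    tss = s if strand == "+" else e - 1
    exonic: set[int] = set()
    for ex in gene.exons:
        exonic |= set(range(ex.start, ex.end))
    sets = {
        "Promoter": set(range(max(0, tss - promoter_window),
                              tss + promoter_window + 1)),
        "Exon": set(exonic),
        "Intron": set(range(s, e)) - exonic,
    }
    if gene.cds_start is not None:
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


def precompute_base_sets(genes, chrom: str, promoter_window: int = 3000,
                         downstream_window: int = 3000) -> dict:
    """Materialize base sets once for repeated classification queries."""
    return {
        g.gene_id: feature_base_sets(g, promoter_window, downstream_window)
        for g in genes if g.span.chrom == chrom
    }


def classify_by_base_sets(chrom: str, summit: int, genes,
                          promoter_window: int = 3000,
                          downstream_window: int = 3000,
                          per_gene: dict | None = None) -> tuple[str, str]:
    """Summit classification by materialized base sets; (feature, gene_id)."""
    if per_gene is None:
        per_gene = precompute_base_sets(genes, chrom, promoter_window,
                                        downstream_window)
    for feature in FEATURE_CLASSES[:-1]:
        hits = [
            (abs(summit - tss), gid)
            for gid, (sets, tss) in per_gene.items()
            if summit in sets[feature]
        ]
        if hits:
            return feature, min(hits)[1]
    _, gid = min((abs(summit - tss), gid) for gid, (_, tss) in per_gene.items())
    return "DistalIntergenic", gid


def merge_by_closure(intervals, max_gap: int):
    """Union-find single-linkage closure of 'gap < max_gap' over
    (chrom, start, end, sample) tuples; returns membership multiset."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = intervals[i]
            cj, sj, ej, _ = intervals[j]
            if ci != cj:
                continue
            if max(sj - ei, si - ej, 0) < max_gap:
                parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(intervals[i][3])
    out: dict[frozenset, int] = {}
    for members in comps.values():
        key = frozenset(members)
        out[key] = out.get(key, 0) + 1
    return out


def hypergeom_tails_by_enumeration(N_pop: int, K: int, n: int, k: int):
    """Exact tails by direct summation of combinatorial probability mass."""

    def pmf(x: int) -> float:
        if x < max(0, n - (N_pop - K)) or x > min(n, K):
            return 0.0
        return (
            math.comb(K, x) * math.comb(N_pop - K, n - x) / math.comb(N_pop, n)
        )

    p_enrich = sum(pmf(x) for x in range(k, min(n, K) + 1))
    p_deplete = sum(pmf(x) for x in range(0, k + 1))
    return p_enrich, p_deplete
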