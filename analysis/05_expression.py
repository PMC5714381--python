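#!/usr/bin/env python
"""Expression side: clustering, differential expression, set tests.

Clusters the gene correlation structure (complete linkage, 1-r
distance) to recover the two anti-correlated blocks, computes
differential expression between the planted sample groups (moderated t,
BH, adjusted p<0.05 & |log2FC|>1.5), and runs directed and undirected
gene-set perturbation tests for both signature sets.

Reads results/simulated/, writes results/expression/.
"""

import json
from pathlib import Path

import peaklink as pl

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = ROOT / "simulated", ROOT / "expression"


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = pl.load_expression_tsv(SIM / "expression.tsv")
    truth = json.loads((SIM / "expression.truth.json").read_text())
    sets = {
        name: pl.read_gene_set(SIM / f"gene_set_{name}.txt")
        for name in ("epithelial", "mesenchymal")
    }

    block_genes = list(sets["epithelial"].gene_ids) + list(
        sets["mesenchymal"].gene_ids
    )
    corr = pl.pairwise_correlation(expr, block_genes)
    res = pl.hier_cluster(corr, input_type="correlation", k=2)
    with open(OUT / "gene_clusters.tsv", "w") as fh:
        fh.write("gene_id\tcluster\n")
        for g in res.labels:
            fh.write(f"{g}\t{res.flat[g]}\n")
    epi_clusters = {res.flat[g] for g in sets["epithelial"].gene_ids}
    mes_clusters = {res.flat[g] for g in sets["mesenchymal"].gene_ids}
    print(f"correlation clustering: epithelial genes -> cluster(s) "
          f"{sorted(epi_clusters)}, mesenchymal -> {sorted(mes_clusters)}")

    g = truth["group_samples"]
    de = pl.differential_expression(expr, g["group1"], g["group2"])
    de.to_csv(OUT / "de.tsv", sep="\t")
    n_up = int(((de["significant"]) & (de["log2fc"] > 0)).sum())
    n_dn = int(((de["significant"]) & (de["log2fc"] < 0)).sum())
    print(f"differential expression: {n_up} up, {n_dn} down at "
          "adjusted p<0.05 and |log2FC|>1.5")

    with open(OUT / "geneset_tests.tsv", "w") as fh:
        fh.write("set\tmode\tn_set\tt\tdf\tpvalue\n")
        for name, gs in sets.items():
            for mode in ("directed", "undirected"):
                r = pl.geneset_perturbation_test(de, gs, mode=mode)
                fh.write(f"{name}\t{mode}\t{r.n_set}\t{r.t:.6g}\t"
                         f"{r.df:.6g}\t{r.pvalue:.6g}\n")
                print(f"set test {name} ({mode}): p = {r.pvalue:.3g}")
    print("expression results written to", OUT)


if __name__ == "__main__":
    run()
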