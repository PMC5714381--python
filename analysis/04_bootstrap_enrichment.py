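#!/usr/bin/env python
"""Bootstrap test: are peak counts at the gene sets unusually high?

For each sample and gene set, counts the peaks associated with the set
genes, builds the null distribution of that count over 10,000 random
same-size gene groups drawn from the full annotated-gene universe, fits
a skew-normal to the null, and reports both fitted and empirical tail
p-values.  The simulation planted a threefold peak-density enrichment
on the epithelial set, so p_high should be small for it and unremarkable
for the mesenchymal set.

Reads results/simulated/ + results/peaks/, writes results/bootstrap/.
"""

import json
from pathlib import Path

import peaklink as pl
from peaklink.genome_annotation import read_annotated_peaks

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, PEAKS, OUT = ROOT / "simulated", ROOT / "peaks", ROOT / "bootstrap"
SEED = 20260919
B = 10000


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    annotation = pl.read_gene_models(SIM / "genome.bed12")
    results = {}
    for sid in ("sampleA", "sampleB"):
        annotated = read_annotated_peaks(PEAKS / f"annotated_{sid}.tsv")
        assoc = pl.associate_peaks(annotated, annotation)
        for name in ("epithelial", "mesenchymal"):
            gs = pl.read_gene_set(SIM / f"gene_set_{name}.txt")
            res = pl.bootstrap_enrichment_test(assoc, gs, B=B, seed=SEED)
            results[f"{sid}:{name}"] = res.to_dict()
            print(f"{sid}/{name}: observed={res.observed} "
                  f"null mean={res.null_counts.mean():.1f} "
                  f"p_high={res.p_high:.3g} p_low={res.p_low:.3g}")
    with open(OUT / "bootstrap.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print("bootstrap results written to", OUT)


if __name__ == "__main__":
    run()
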