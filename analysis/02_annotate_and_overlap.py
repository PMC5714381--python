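#!/usr/bin/env python
"""Classify peaks into genomic features and build the cross-sample Venn.

For each simulated sample the peak summits are classified into the
seven genomic features (promoter, 5'/3' UTR, exon, intron, downstream,
distal intergenic; 3-kb promoter window), and the two samples' peaks
are merged under the <1000-bp overlap rule to count common and
sample-specific binding regions.

Reads results/simulated/, writes feature tables and the overlap table
under results/peaks/.
"""

from pathlib import Path

import peaklink as pl

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = ROOT / "simulated", ROOT / "peaks"


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    annotation = pl.read_gene_models(SIM / "genome.bed12")
    sets = []
    for sid in ("sampleA", "sampleB"):
        ps = pl.read_narrowpeak(SIM / f"peaks_{sid}.narrowPeak", sid)
        sets.append(ps)
        annotated = pl.classify_peaks(ps.peaks, annotation)
        pl.genome_annotation.write_annotated_peaks(
            annotated, OUT / f"annotated_{sid}.tsv"
        )
        dist = pl.feature_distribution(annotated)
        with open(OUT / f"feature_distribution_{sid}.tsv", "w") as fh:
            fh.write("feature\tcount\tfraction\n")
            for f in pl.FEATURE_CLASSES:
                fh.write(f"{f}\t{dist.counts[f]}\t{dist.fractions[f]:.6f}\n")
        top = max(dist.fractions, key=dist.fractions.get)
        print(f"{sid}: {dist.total} peaks; most frequent feature {top} "
              f"({100 * dist.fractions[top]:.1f}%)")
    table = pl.cluster_overlapping(sets, max_gap=1000)
    table.to_tsv(OUT / "overlap.tsv")
    table.to_json(OUT / "overlap.json")
    print(f"overlap: {table.n_regions} merged regions, "
          f"{100 * table.fraction_common:.1f}% common to both samples")


if __name__ == "__main__":
    run()
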