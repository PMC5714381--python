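#!/usr/bin/env python
"""Feature-bias tests and chromatin-state profiles for the gene sets.

Asks whether peaks assigned to the epithelial or mesenchymal gene set
fall into each genomic feature more or less often than all peaks
(hypergeometric tails), profiles the chromatin states under distal
intergenic peaks of each set, and compares pileup values between
epithelial- and mesenchymal-associated peaks (rank-sum test).

Reads results/simulated/ + results/peaks/, writes results/feature_bias/.
"""

import json
from pathlib import Path

import peaklink as pl
from peaklink.genome_annotation import read_annotated_peaks

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM, PEAKS, OUT = ROOT / "simulated", ROOT / "peaks", ROOT / "feature_bias"


def run() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seg = pl.read_segmentation(SIM / "segmentation.bed")
    sets = {
        name: pl.read_gene_set(SIM / f"gene_set_{name}.txt")
        for name in ("epithelial", "mesenchymal")
    }
    pileups = {}
    with open(OUT / "feature_tests.tsv", "w") as fh:
        fh.write("sample\tgene_set\tfeature\tk\tn\tK\tN_pop\tp_enrich\tp_deplete\n")
        for sid in ("sampleA", "sampleB"):
            annotated = read_annotated_peaks(PEAKS / f"annotated_{sid}.tsv")
            bg = pl.feature_distribution(annotated)
            for name, gs in sets.items():
                sd = pl.feature_distribution(annotated, restrict_to=gs)
                for feature in pl.FEATURE_CLASSES:
                    r = pl.hypergeom_feature_test(sd, bg, feature)
                    fh.write(
                        f"{sid}\t{name}\t{feature}\t{r.k}\t{r.n}\t{r.K}\t"
                        f"{r.N_pop}\t{r.p_enrich:.6g}\t{r.p_deplete:.6g}\n"
                    )
                profile = pl.state_abundance(
                    annotated, seg, feature_filter="DistalIntergenic", gene_set=gs
                )
                profile.to_tsv(OUT / f"state_profile_{sid}_{name}.tsv")
                top = max(profile.abundance, key=profile.abundance.get)
                print(f"{sid}/{name}: {profile.n_peaks} distal intergenic peaks, "
                      f"top state {top} ({profile.abundance[top]:.1f}%)")
            # pileup comparison between set-associated peak groups
            ps = pl.read_narrowpeak(SIM / f"peaks_{sid}.narrowPeak", sid)
            by_name = {p.name: p for p in ps.peaks}
            epi = set(sets["epithelial"].gene_ids)
            mes = set(sets["mesenchymal"].gene_ids)
            # annotated TSV has no names; use positions to match pileups
            pos = {(p.interval.start, p.summit): p.pileup for p in ps.peaks}
            a = [pos[(x.peak.interval.start, x.peak.summit)]
                 for x in annotated if x.gene_id in epi]
            b = [pos[(x.peak.interval.start, x.peak.summit)]
                 for x in annotated if x.gene_id in mes]
            r = pl.pileup_rank_test(a, b)
            pileups[sid] = {
                "n_epithelial": r.n_a, "n_mesenchymal": r.n_b,
                "median_epithelial": r.median_a, "median_mesenchymal": r.median_b,
                "p_two_sided": r.p_two_sided,
                "p_epithelial_greater": r.p_a_greater,
            }
    with open(OUT / "pileup_tests.json", "w") as fh:
        json.dump(pileups, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print("feature tests and state profiles written to", OUT)


if __name__ == "__main__":
    run()
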