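# peaklink

Downstream analysis toolkit linking transcription-factor ChIP-seq peaks
to gene sets, chromatin states and expression — the computational core
of a pioneer-factor (FOXA-class) regulatory study, rebuilt as a tested,
reusable pipeline that runs end-to-end on synthetic data with planted
ground truth.

## What it computes

Given called peaks (ENCODE narrowPeak/BED), gene models (BED12), a
fixed-bin chromatin-state segmentation (4-column BED) and gene sets:

* **Genomic-feature classification** — every peak summit is assigned one
  of seven features with precedence
  Promoter ≻ 5′UTR ≻ 3′UTR ≻ Exon ≻ Intron ≻ Downstream ≻ DistalIntergenic,
  where the promoter is ±3 kb around the strand-aware TSS and each peak
  also receives an assigned gene (nearest TSS for distal peaks).
* **Cross-sample overlap (Venn)** — peaks from different samples count as
  overlapping when less than 1000 bp apart; regions are the
  single-linkage closure of that relation.
* **Chromatin-state profiles** — each summit takes the state of its
  200-bp bin from a 15-state segmentation (Roadmap mnemonics,
  TssA … Quies); relative state abundance is profiled for peak subsets.
* **Hypergeometric feature bias** — with k of n set-gene peaks in a
  feature against K of N background peaks,
  p_enrich = P[X ≥ k], p_deplete = P[X ≤ k], X ~ Hypergeom(N, K, n).
* **Bootstrap gene-set peak enrichment** — the observed number of peaks
  associated with an N-gene set is compared against the null count
  distribution over B = 10,000 random N-gene groups drawn without
  replacement from all annotated genes; tail p-values come from a
  maximum-likelihood skew-normal fit
  f(x) = (2/ω) φ((x−ξ)/ω) Φ(α(x−ξ)/ω) to the null, with add-one
  empirical companions.
* **Expression analyses** — largest-IQR probe collapse; gene-wise
  z-scaling; Pearson correlation with complete-linkage clustering
  (distance 1 − r); two-group differential expression (empirical-Bayes
  moderated t, Benjamini–Hochberg, significance at adjusted p < 0.05 and
  |log2FC| > 1.5); directed/undirected gene-set perturbation tests
  (one-sided Welch t of the set's log2FC — or |log2FC| — against all
  measured genes, usable set sizes 5 < n < 500).
* **Synthetic data** — generators for annotated genomes, peak sets with
  per-feature placement bias and a per-gene-set density multiplier ρ,
  feature-conditional 15-state segmentations, and expression matrices
  with two anti-correlated gene blocks plus spiked DE; all record the
  planted truth and are pure functions of their seeds.

## Worked example

```bash
peaklink simulate --outdir sim --seed 5 --n-genes 600 --n-peaks 3000 --rho 3.0
peaklink run-all --simdir sim --outdir results --trials 10000 --seed 5
```

or, as a library (the numbered scripts under `analysis/` run exactly
this on `results/simulated/`):

```python
import peaklink as pl

annotation = pl.read_gene_models("sim/genome.bed12")
peaks = pl.read_narrowpeak("sim/peaks_sampleA.narrowPeak", "sampleA")
annotated = pl.classify_peaks(peaks.peaks, annotation)
assoc = pl.associate_peaks(annotated, annotation)
gs = pl.read_gene_set("sim/gene_set_epithelial.txt")
res = pl.bootstrap_enrichment_test(assoc, gs, B=10000, seed=20260919)
print(res.observed, res.null_counts.mean(), res.p_high)
```

On the shipped simulation (threefold peak density planted on the
45-gene epithelial set) this prints, per sample:

```
sampleA/epithelial: observed=613 null mean=225.0 p_high=2.5e-47 p_low=1
sampleA/mesenchymal: observed=235 null mean=269.9 p_high=0.942 p_low=0.0581
```

i.e. the epithelial set carries ~2.7× the peak count expected for a
random 45-gene group (observed 613 vs null mean 225, fitted upper-tail
p ≈ 10⁻⁴⁷), while the un-enriched mesenchymal set is compatible with
the null — exactly the planted structure.  The companion expression run
recovers the two anti-correlated blocks as clean clusters and flags
exactly the 20 spiked genes (20 up, 0 down) at the 0.05 / 1.5
thresholds.

## Layout

```
src/peaklink/        library: genome_annotation, peak_toolkit,
                     chromatin_states, geneset_enrichment,
                     expression_analysis, synthetic_data, experiments,
                     bruteforce (reference oracles), cli
analysis/            numbered narrative drivers writing results/
scripts/acceptance.py  validation battery -> JSON
docs/methods.md      models, parameters, numerical choices, limitations
tests/               pytest suite (unit + property + acceptance)
```
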