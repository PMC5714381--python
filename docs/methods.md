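# Methods

This note documents the models and procedures peaklink implements, the
parameters that matter, the synthetic-data design, and the numerical
choices made where the design was genuinely open.

## Coordinate conventions

All coordinates are BED-style 0-based half-open; a peak summit is a
single base offset inside its interval. narrowPeak summits come from
the column-10 offset (−1 falls back to the interval midpoint); plain
BED peaks use the midpoint.

## Feature classification

A peak is classified by its **summit** (one peak → one feature; no
fractional assignment) against seven feature classes built from gene
models:

| feature | definition |
|---|---|
| Promoter | summit within ±`promoter_window` (default 3000 bp) of the strand-aware TSS, inclusive |
| 5′/3′ UTR | exonic sequence outside the CDS on the respective side (none for non-coding genes) |
| Exon | any exonic base |
| Intron | genic, non-exonic |
| Downstream | within `downstream_window` (default 3000 bp) past the gene end, in gene orientation |
| DistalIntergenic | everything else; assigned to the nearest-TSS gene |

Overlaps resolve by the precedence order Promoter ≻ 5′UTR ≻ 3′UTR ≻
Exon ≻ Intron ≻ Downstream ≻ DistalIntergenic — genic-first, as
annotation tools in this field conventionally rank categories. Ties
between genes offering the same winning feature break by smaller
|distance to TSS|, then lexicographic gene id, making output fully
deterministic. `dist_to_tss` is signed in gene orientation (negative =
upstream). "Downstream" is a *bounded* window: an unbounded downstream
category would swallow the intergenic space and is not a meaningful
Venn partner to DistalIntergenic.

Internally, candidate regions per gene are indexed in an interval tree
for per-summit queries; `feature_map` materializes the same geometry as
a disjoint genome-wide labeled partition (used by the peak simulator,
so generator and analyzer share one geometry definition). An
independent base-set materialization (`bruteforce.classify_by_base_sets`)
re-derives classification per base for cross-checking; the two agree on
100% of 10,000 random summits in the validation battery.

## Overlap (Venn) rule

Peaks from different samples overlap when their intervals are less than
`max_gap` = 1000 bp apart (intersection = gap 0; the comparison is
strict, so a gap of exactly 1000 separates). Because pairwise
"< 1000 bp" is not transitive, merged regions are the single-linkage
closure of the relation; each region contributes to exactly one Venn
membership cell. Closure makes region counts monotone non-increasing
in `max_gap` and independent of sample order.

## Chromatin states

Segmentations are hard per-bin labels (bin size 200 bp) over a 15-state
vocabulary defaulting to the Roadmap core-model mnemonics
(TssA, TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, ZNF/Rpts, Het, TssBiv,
BivFlnk, EnhBiv, ReprPC, ReprPCWk, Quies). A peak takes the state of
bin ⌊summit / bin_size⌋. Bins without a record carry an "Unannotated"
sentinel that is excluded from abundance denominators by default
(profiles report only model states represented under the peaks), with a
flag to include it. HMM training and posterior decoding are upstream;
the segmentation is an input.

## Hypergeometric feature bias

For a gene set's peaks against all peaks: k of n set peaks in the
feature, K of N_pop background peaks. p_enrich = P[X ≥ k] and
p_deplete = P[X ≤ k] under X ~ Hypergeometric(N_pop, K, n); both
include the observed point mass, so p_enrich + p_deplete ≥ 1. Tails
are computed by scipy's exact hypergeometric implementation and are
verified against full combinatorial enumeration for every parameter
combination with N_pop ≤ 12 (agreement ≤ 1e-12).

## Bootstrap gene-set peak enrichment

"Associated peak" = a peak whose classifier-assigned gene is the gene
in question, under any of the seven features (distal peaks associate by
nearest TSS). This is stated prominently because association rules
vary across tools; the choice keeps one peak → one gene and uses the
same assignment everywhere in the pipeline.

The test statistic is the summed associated-peak count over the set's N
genes. The null draws B (default 10,000) random N-gene groups
uniformly *without replacement within a trial* from the full annotated
gene universe — all genes, not just peak-bearing ones — and records
each group's summed count. Trials are generated in fixed 512-trial
chunks, each from its own `SeedSequence(seed).spawn()` stream, so
results are reproducible, independent of execution order, and
parallelizable without 10,000 per-trial streams.

Tail p-values come from a maximum-likelihood skew-normal fit to the
null sample: p_high = 1 − F(observed), p_low = F(observed). Both
one-sided values are always reported (the question is "significantly
high or low"); no automatic two-siding. Empirical companions use the
add-one convention p_emp = (1 + #{null beyond}) / (B + 1) with ties
counting toward both tails, bounding them in [1/(B+1), 1].

### Skew-normal fitting

Density f(x) = (2/ω) φ(z) Φ(αz), z = (x−ξ)/ω. The fit maximizes the
log-likelihood over (ξ, log ω, α) by Nelder–Mead from a
method-of-moments start (sample skewness clipped below the theoretical
supremum ≈ 0.9952); |α| is capped at 50 to avoid boundary divergence.
Constant samples set a degenerate flag (no fit; empirical tails only);
fewer than 10 samples is an error; optimizer failure raises an error
carrying the method-of-moments fallback.

A caveat documented deliberately: at α = 0 the skew-normal information
matrix is singular, so on symmetric data the *direct* parameters are
weakly identified — the MLE of α on 10,000 standard-normal draws
typically lands anywhere in ±0.6 (at the n^(−1/6) convergence rate),
with compensating shifts in ξ and ω. The fitted *distribution* is
nevertheless accurate: centered mean/SD recover (0, 1) to ~0.02 and
tail probabilities at the 95th percentile are within a few 10⁻³ of
0.05. Downstream inference uses only the fitted CDF, so this
non-identifiability does not affect p-values. When comparing fitted to
empirical tails of the integer-valued bootstrap null, thresholds are
placed at half-integers so both routes measure the same probability
mass rather than the tie-counting convention at a lattice atom.

## Expression analyses

* **Probe collapse**: per gene, keep the probe with the largest
  interquartile range across samples; equal IQRs break by
  lexicographically smaller probe id; unmapped probes are dropped with
  a logged count. Rows with missing values are dropped at load (all
  downstream statistics assume complete rows).
* **Scaling**: gene-wise to mean 0, sample SD 1; zero-variance rows
  become all-zeros with a warning. Idempotent to 1e-12.
* **Clustering**: agglomerative complete linkage; Euclidean distance on
  z-scaled rows for expression input, 1 − r for correlation input.
* **Differential expression**: log2FC = mean(group2) − mean(group1) on
  the log2 matrix. The default per-gene statistic is an
  empirical-Bayes **moderated t**: pooled per-gene variances s²_g
  (d = n₁+n₂−2 df) are shrunk toward a prior (d₀, s₀²) estimated by
  moment-matching the marginal scaled-F distribution of s²_g on the log
  scale (solve trigamma(d₀/2) = var(log s²) − trigamma(d/2));
  s̃² = (d₀s₀² + d s²)/(d₀+d) with d + d₀ df. Moderation is the
  standard remedy for triplicate designs, where a plain Welch t has so
  few effective df that BH-adjusted significance at p < 0.05 is nearly
  unreachable even for 8σ effects; the implementation agrees with the
  Bioconductor limma reference to ~1e-4 in t and p (tested). Welch's t
  remains available via `method="welch"`. BH correction across all
  genes; the significance flag requires adjusted p < 0.05 **and**
  |log2FC| > 1.5.
* **Gene-set perturbation**: one-sided Welch two-sample t of the set's
  per-gene statistics against all measured genes — log2FC in directed
  mode (set mean greater), |log2FC| in undirected mode (perturbation
  greater). Usable sets satisfy 5 < |set ∩ measured| < 500. The
  directed p is antisymmetric under sign flip of the statistics.

## Synthetic data: what it emulates, what it does not

The generators realize, at desk scale, the statistical structure the
pipeline is meant to detect:

* **Genome** (`GenomeSimParams`): non-overlapping genes on one or more
  chromosomes; log-normal gene lengths (μ = 9.2, σ = 0.5 in log-bp,
  median ≈ 10 kb) and intergenic spacings (μ = 9.9, σ = 0.5, median
  ≈ 20 kb — wide enough that neighboring promoter/downstream windows
  rarely collide); 2–8 exons per gene with ≥50-bp pieces via a
  Dirichlet split; 90% coding with CDS bounds leaving non-empty UTRs.
* **Peaks** (`PeakSimParams`): each peak draws a gene (probability ∝ ρ
  for set genes, 1 otherwise; ρ is a *density multiplier*, chosen over
  an additive model because the bootstrap statistic sums per-gene
  counts and a multiplicative factor gives a clean power dial), then a
  feature stratum from a weight vector (defaults mimic pioneer-factor
  peaks: 40% distal intergenic, 25% intronic, 20% promoter), then a
  summit uniformly within that stratum of that gene from the shared
  feature map. Empty strata redraw the feature only, preserving the
  gene-draw marginal so the expected set fraction is exactly
  ρ·|S| / (ρ·|S| + G − |S|). Log-normal widths (median ≈ 330 bp) and
  pileups.
* **Segmentation** (`SegSimParams`): per-bin states drawn from
  feature-conditional emission distributions (promoter bins
  TssA/TssAFlnk-heavy, genic bins transcription states, distal
  intergenic 70% quiescent with an enhancer component).
* **Expression** (`ExprSimParams`): two gene blocks on a shared latent
  factor per sample with loadings set so within-block correlation is
  r_w and cross-block correlation r_b (feasible when r_b² ≤ r_w²;
  defaults +0.8 / −0.8, block sizes 45 and 54 mirroring
  epithelial/mesenchymal signature sizes); unstructured background
  genes at noise σ; planted DE adds Δ (default 2.0, σ = 0.25,
  triplicate groups) to group-2 samples.

Every generator is a pure function of its parameter object including
the seed (single root seed expanded via `SeedSequence`), and each
returns a truth record sufficient to score recovery without
re-derivation.

Passing on these data shows the *algorithms* are correct and calibrated
under the stated models. Real data differ in ways the generators do
not emulate: peak-width/pileup signal correlations, copy-number and
mappability artifacts, overlapping and isoform-rich gene models,
correlated (LD-like) peak placement, heteroscedastic microarray noise,
batch structure. Results on real data inherit those caveats.

## Validation battery and problem sizes

The package validates itself with the experiments in
`peaklink.experiments` (reported by `scripts/acceptance.py` and
asserted in `tests/test_acceptance.py`):

* hypergeometric tails vs enumeration — every (N_pop ≤ 12, K, n, k),
  1,729 cases;
* classifier vs base-set oracle — 10,000 random summits on a 5-gene
  genome; strata recovery on 10,000 peaks over 200 genes (≥ 99%);
* overlap rule vs union-find closure — 100 random 30-peak instances
  stressing 999/1000/1001-bp gaps;
* state lookup vs record scan, and recovery of a planted 0.9 TssA
  promoter emission within 3 binomial SE;
* bootstrap calibration — 2,000-gene genome, ~2 peaks per gene, ρ = 1,
  random 50-gene sets, B = 2,000, 200 replicates; fitted p_high tested
  for uniformity (KS) and median near 0.5. The observed count is an
  integer while the fitted CDF is continuous, so p_high carries a
  lattice granularity of roughly half the local point mass (~0.01
  here); this shifts the median slightly above 0.5 without breaking
  uniformity at the tested resolution;
* bootstrap power — ρ = 3, |set| = 50, B = 2,000, 100 replicates,
  detection at p_high < 0.01;
* expression — exact block recovery (ARI 1.0 at ≥ 50 samples), DE
  sensitivity/false positives on 20 planted vs 500 null genes, directed
  set-test power for a +1.0 log2FC shift on 40 genes over a 2,000-gene
  background (100 replicates);
* end-to-end determinism — `simulate` + `run-all` twice, byte-identical
  outputs (provenance records carry parameters and seeds but no
  wallclock times or absolute paths, precisely so reruns are
  comparable).

These sizes are the package's validation conditions; they were chosen
once as realistic desk-scale stand-ins for the genome-scale originals
(tens of thousands of peaks, 22,000 genes) and are not tuned per run.

## Known limitations

* Transcript-isoform-aware annotation, liftover, and alternative
  nearest-gene association modes are out of scope.
* The peak-gene association rule (classifier assignment, no distance
  cap beyond the classifier's own geometry) is one defensible choice
  among several; counts change under distance-capped rules.
* Direct skew-normal parameters are not interpretable near α = 0 (see
  above); report centered moments if parameters themselves matter.
* The moderated t assumes roughly exchangeable gene variances; strong
  variance heterogeneity weakens the shrinkage benefit.
* Single-set inference only; no FDR across collections of gene sets.
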