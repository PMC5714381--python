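"""Property-based validation experiments run on synthetic data.

Each experiment exercises one pipeline stage end-to-end under planted
conditions and returns summary metrics: oracle agreement rates,
calibration and power of the bootstrap enrichment test, recovery of
planted expression structure, and end-to-end determinism.  The analysis
drivers and the acceptance script are thin wrappers around these.

Problem sizes are the package's validation conditions: a 2,000-gene
single-chromosome genome with ~2 peaks per gene for bootstrap
calibration/power (200 and 100 replicates), 10,000 random summits for
classifier checks, and the triplicate 520-gene design for differential
expression.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import bruteforce
from .chromatin_states import read_segmentation, state_abundance
from .expression_analysis import (
    differential_expression,
    geneset_perturbation_test,
    hier_cluster,
)
from .genome_annotation import (
    AnnotationParams,
    FEATURE_CLASSES,
    classify_peaks,
    classify_summit,
)
from .geneset_enrichment import (
    GeneSet,
    associate_peaks,
    bootstrap_enrichment_test,
    hypergeom_feature_test,
)
from .genome_annotation import FeatureDistribution
from .peak_toolkit import GenomicInterval, Peak, PeakSet, cluster_overlapping
from .synthetic_data import (
    ExprSimParams,
    GenomeSimParams,
    PeakSimParams,
    SegSimParams,
    generate_expression,
    generate_genome,
    generate_peaks,
    generate_segmentation,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def hypergeom_oracle_check(max_pop: int = 12) -> dict:
    """Compare both hypergeometric tails with exhaustive enumeration for
    every (N_pop <= max_pop, K, n, k)."""
    max_err = 0.0
    n_cases = 0
    for N_pop in range(1, max_pop + 1):
        for K in range(0, N_pop + 1):
            for n in range(1, N_pop + 1):
                for k in range(max(0, n - (N_pop - K)), min(n, K) + 1):
                    sd = FeatureDistribution({"Intron": k, "Exon": n - k}, n)
                    bg = FeatureDistribution({"Intron": K, "Exon": N_pop - K}, N_pop)
                    r = hypergeom_feature_test(sd, bg, "Intron")
                    e, d = bruteforce.hypergeom_tails_by_enumeration(N_pop, K, n, k)
                    max_err = max(max_err, abs(r.p_enrich - e), abs(r.p_deplete - d))
                    n_cases += 1
    return {"max_abs_err": max_err, "n_cases": n_cases}


def classifier_oracle_check(seed: int, n_summits: int = 10000) -> dict:
    """Summit classification vs the base-set oracle on a tiny genome, and
    recovery of generator-intended strata at n=10,000 peaks."""
    seeds = _child_seeds(seed, 4)
    ann, _ = generate_genome(
        GenomeSimParams(n_genes=5, spacing_mu=8.5, seed=seeds[0])
    )
    extent = ann.chrom_lengths["chr1"]
    rng = np.random.default_rng(seeds[1])
    genes = list(ann.genes.values())
    base_sets = bruteforce.precompute_base_sets(genes, "chr1")
    agree = 0
    for summit in rng.integers(0, extent, size=n_summits):
        want = bruteforce.classify_by_base_sets(
            "chr1", int(summit), genes, per_gene=base_sets
        )
        got = classify_summit("chr1", int(summit), ann)
        agree += (got[0], got[1]) == want
    big_ann, _ = generate_genome(GenomeSimParams(n_genes=200, seed=seeds[2]))
    peaks, truth = generate_peaks(
        big_ann, PeakSimParams(n_peaks=10000, seed=seeds[3])
    )
    annotated = classify_peaks(peaks.peaks, big_ann)
    recovered = float(np.mean(
        [a.feature == f for a, f in zip(annotated, truth.peak_features)]
    ))
    return {
        "oracle_agreement": agree / n_summits,
        "n_summits": n_summits,
        "strata_recovery": recovered,
        "n_peaks": len(annotated),
    }


def venn_oracle_check(seed: int, n_instances: int = 100) -> dict:
    """Random 30-peak 3-sample instances (plus 999/1000 boundary gaps)
    vs the union-find closure oracle."""
    seeds = _child_seeds(seed, n_instances)
    ok = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        recs = []
        per_sample: dict[str, list[Peak]] = {"A": [], "B": [], "C": []}
        pos = 0
        for i in range(30):
            # force frequent 999/1000/1001 boundary gaps between intervals
            gap = int(rng.choice([999, 1000, 1001, 0, 50, 300, 2500]))
            width = int(rng.integers(100, 600))
            start = pos + gap
            pos = start + width
            sid = "ABC"[int(rng.integers(3))]
            recs.append(("chr1", start, pos, sid))
            per_sample[sid].append(
                Peak(interval=GenomicInterval("chr1", start, pos),
                     summit=start + width // 2)
            )
        sets = [PeakSet(sid, ps) for sid, ps in per_sample.items() if ps]
        if len(sets) < 2:
            continue
        ours = cluster_overlapping(sets, max_gap=1000)
        ok += ours.counts == bruteforce.merge_by_closure(recs, 1000)
    return {"instances_agreeing": ok, "n_instances": n_instances,
            "agreement": ok / n_instances}


def state_recovery_check(seed: int) -> dict:
    """Summit-bin state assignment vs a record scan, and recovery of a
    planted 0.9 TssA promoter emission within binomial error."""
    seeds = _child_seeds(seed, 3)
    ann, _ = generate_genome(GenomeSimParams(n_genes=40, seed=seeds[0]))
    em = {f: {"Quies": 1.0} for f in FEATURE_CLASSES}
    em["Promoter"] = {"TssA": 0.9, "Quies": 0.1}
    seg, truth = generate_segmentation(ann, SegSimParams(emissions=em, seed=seeds[1]))
    # record-scan agreement over a lattice of summits
    arr = seg.bins["chr1"]
    agree = 0
    n_checked = 0
    rng = np.random.default_rng(seeds[2])
    for summit in rng.integers(0, arr.size * seg.bin_size, size=2000):
        b = int(summit) // seg.bin_size
        want = seg.states[arr[b]] if arr[b] != -1 else "Unannotated"
        got = seg.state_at("chr1", int(summit))
        agree += got == want
        n_checked += 1
    feats = np.array(truth.bin_features["chr1"])
    mask = feats == "Promoter"
    n_bins = int(mask.sum())
    frac = float(np.mean(arr[mask] == seg.states.index("TssA")))
    se = float(np.sqrt(0.9 * 0.1 / n_bins))
    return {
        "assign_agreement": agree / n_checked,
        "tssa_fraction": frac,
        "tssa_target": 0.9,
        "n_promoter_bins": n_bins,
        "within_3se": abs(frac - 0.9) < 3 * se,
    }


def _calibration_genome(seed: int):
    ann, _ = generate_genome(GenomeSimParams(n_genes=2000, seed=seed))
    return ann


def bootstrap_calibration(seed: int, n_reps: int = 200, B: int = 2000,
                          set_size: int = 50, n_peaks: int = 4000) -> dict:
    """Fitted p_high under the no-enrichment null (rho=1, random sets)
    over independent replicates; uniformity by KS test."""
    seeds = _child_seeds(seed, n_reps + 1)
    ann = _calibration_genome(seeds[0])
    p_high = []
    for s in seeds[1:]:
        sub = _child_seeds(s, 3)
        peaks, _ = generate_peaks(
            ann, PeakSimParams(n_peaks=n_peaks, rho=1.0, seed=sub[0])
        )
        annotated = classify_peaks(peaks.peaks, ann)
        assoc = associate_peaks(annotated, ann)
        rng = np.random.default_rng(sub[1])
        members = tuple(
            np.array(ann.gene_ids)[rng.choice(len(ann.gene_ids), set_size,
                                              replace=False)]
        )
        res = bootstrap_enrichment_test(
            assoc, GeneSet("random", members), B=B, seed=sub[2]
        )
        p_high.append(res.p_high)
    p_high = np.array(p_high, dtype=float)
    ks = sps.kstest(p_high, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "median_p_high": float(np.median(p_high)),
        "n_reps": n_reps,
        "B": B,
    }


def bootstrap_power(seed: int, n_reps: int = 100, B: int = 2000,
                    set_size: int = 50, rho: float = 3.0,
                    n_peaks: int = 4000) -> dict:
    """Detection rate (fitted p_high < 0.01) for a planted density ratio
    rho on random same-size gene sets."""
    seeds = _child_seeds(seed, n_reps + 1)
    ann = _calibration_genome(seeds[0])
    hits = 0
    for s in seeds[1:]:
        sub = _child_seeds(s, 3)
        rng = np.random.default_rng(sub[1])
        members = tuple(
            np.array(ann.gene_ids)[rng.choice(len(ann.gene_ids), set_size,
                                              replace=False)]
        )
        gs = GeneSet("planted", members)
        peaks, _ = generate_peaks(
            ann, PeakSimParams(n_peaks=n_peaks, rho=rho, seed=sub[0]), gene_set=gs
        )
        annotated = classify_peaks(peaks.peaks, ann)
        assoc = associate_peaks(annotated, ann)
        res = bootstrap_enrichment_test(assoc, gs, B=B, seed=sub[2])
        if res.p_high is not None and res.p_high < 0.01:
            hits += 1
    return {"significant": hits, "n_reps": n_reps, "power": hits / n_reps}


def skewnorm_normal_limit(seed: int, n: int = 10000) -> dict:
    """MLE skew-normal fit to standard-normal draws: direct parameters,
    centered parameters, and tail accuracy at the 95th percentile."""
    from .geneset_enrichment import fit_skew_normal

    x = np.random.default_rng(seed).standard_normal(n)
    f = fit_skew_normal(x)
    d = f.alpha / np.sqrt(1 + f.alpha**2)
    mean = f.xi + f.omega * d * np.sqrt(2 / np.pi)
    sd = f.omega * np.sqrt(1 - 2 * d * d / np.pi)
    tail = float(sps.skewnorm.sf(np.quantile(x, 0.95), f.alpha, f.xi, f.omega))
    return {
        "alpha_abs": abs(f.alpha),
        "xi": f.xi,
        "omega": f.omega,
        "centered_mean": float(mean),
        "centered_sd": float(sd),
        "tail95": tail,
        "tail95_abs_err": abs(tail - 0.05),
        "n": n,
    }


def skewnorm_tail_agreement(seed: int, B: int = 5000) -> dict:
    """Fitted vs empirical tails of a real bootstrap null at B >= 5000."""
    from .geneset_enrichment import bootstrap_null, bootstrap_p, fit_skew_normal

    seeds = _child_seeds(seed, 3)
    ann, _ = generate_genome(GenomeSimParams(n_genes=300, seed=seeds[0]))
    peaks, _ = generate_peaks(ann, PeakSimParams(n_peaks=1200, seed=seeds[1]))
    assoc = associate_peaks(classify_peaks(peaks.peaks, ann), ann)
    null = bootstrap_null(assoc, set_size=30, B=B, seed=seeds[2])
    fit = fit_skew_normal(null)
    gap = 0.0
    # thresholds at half-integers: the null is lattice-valued, so comparing
    # between atoms measures distribution agreement rather than the
    # tie-counting convention at an atom
    for q in (0.05, 0.25, 0.5, 0.75, 0.95):
        x = float(np.quantile(null, q)) + 0.5
        fitted = float(sps.skewnorm.sf(x, fit.alpha, loc=fit.xi, scale=fit.omega))
        empirical = float(np.mean(null > x))
        gap = max(gap, abs(fitted - empirical))
    return {"max_tail_gap": gap, "B": B}


def expression_recovery(seed: int, n_reps: int = 100) -> dict:
    """Planted expression structure: block clustering ARI, DE sensitivity
    and false positives under the 0.05 / 1.5 thresholds, and directed
    set-test power for a +1 log2FC shift."""
    from sklearn.metrics import adjusted_rand_score

    seeds = _child_seeds(seed, n_reps + 2)
    expr, truth = generate_expression(
        ExprSimParams(n_samples=60, block_sizes=(45, 54), n_null_genes=0,
                      seed=seeds[0])
    )
    A, B_ = truth.block_members["A"], truth.block_members["B"]
    res = hier_cluster(expr.loc[A + B_], k=2)
    ari = adjusted_rand_score(
        [0] * len(A) + [1] * len(B_), [res.flat[g] for g in A + B_]
    )

    expr2, truth2 = generate_expression(
        ExprSimParams(n_samples=6, block_sizes=(0, 0), n_null_genes=500,
                      n_de_genes=20, delta=2.0, sigma=0.25,
                      group_sizes=(3, 3), seed=seeds[1])
    )
    g = truth2.group_samples
    de = differential_expression(expr2, g["group1"], g["group2"])
    planted = set(truth2.de_genes)
    flagged = set(de.index[de["significant"]])
    sens = len(flagged & planted) / len(planted)
    fps = len(flagged - planted)

    hits = 0
    for s in seeds[2:]:
        e3, t3 = generate_expression(
            ExprSimParams(n_samples=6, block_sizes=(0, 40), within_r=0.01,
                          between_r=0.0, n_null_genes=2000, n_de_genes=0,
                          sigma=0.5, group_sizes=(3, 3), seed=s)
        )
        # plant a +1 shift on the 40-gene set in group 2
        set_genes = t3.block_members["B"]
        e3.loc[set_genes, t3.group_samples["group2"]] += 1.0
        de3 = differential_expression(
            e3, t3.group_samples["group1"], t3.group_samples["group2"]
        )
        r3 = geneset_perturbation_test(de3, GeneSet("shift", tuple(set_genes)),
                                       mode="directed")
        if r3.pvalue < 0.01:
            hits += 1
    return {
        "cluster_ari": float(ari),
        "de_sensitivity": sens,
        "de_false_positives": fps,
        "n_null_genes": 500,
        "directed_power": hits / n_reps,
        "n_reps": n_reps,
    }


def endtoend_determinism(seed: int, tmp_root) -> dict:
    """simulate + run-all twice with the same seed: outputs byte-identical."""
    from pathlib import Path

    from click.testing import CliRunner
    from .cli import main

    root = Path(tmp_root)
    runner = CliRunner()
    digests = []
    for tag in ("run1", "run2"):
        sim = root / tag / "sim"
        out = root / tag / "out"
        r = runner.invoke(main, [
            "simulate", "--outdir", str(sim), "--seed", str(seed),
            "--n-genes", "150", "--n-peaks", "800", "--n-samples", "12",
        ])
        if r.exit_code != 0:
            raise RuntimeError(f"simulate failed: {r.output}")
        r = runner.invoke(main, [
            "run-all", "--simdir", str(sim), "--outdir", str(out),
            "--trials", "300", "--seed", str(seed),
        ])
        if r.exit_code != 0:
            raise RuntimeError(f"run-all failed: {r.output}")
        digest = {
            p.name: p.read_bytes()
            for d in (sim, out) for p in sorted(d.iterdir())
        }
        digests.append(digest)
    identical = (
        digests[0].keys() == digests[1].keys()
        and all(digests[0][k] == digests[1][k] for k in digests[0])
    )
    return {"identical": bool(identical), "n_files": len(digests[0])}
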