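"""Synthetic genomes, peak sets, segmentations and expression matrices.

Generators plant known structure — per-feature peak placement bias,
gene-set peak-density enrichment (a multiplicative factor rho on set
genes), feature-dependent chromatin-state emission, anti-correlated
expression blocks and spiked differential expression — so every
pipeline stage can be tested against recorded truth without external
data.  Every generator is a pure function of its parameter object,
including the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .chromatin_states import ChromatinSegmentation, ROADMAP_15_STATES
from .genome_annotation import (
    AnnotationParams,
    FEATURE_CLASSES,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    feature_map,
)
from .geneset_enrichment import GeneSet
from .peak_toolkit import Peak, PeakSet

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    """Infeasible simulation parameters."""


@dataclass
class SimulationTruth:
    """Planted ground truth, sufficient to score any recovery test."""

    gene_strands: Optional[dict[str, str]] = None
    chrom_lengths: Optional[dict[str, int]] = None
    peak_genes: Optional[list[str]] = None          # intended gene per peak
    peak_features: Optional[list[str]] = None       # intended stratum per peak
    peaks_per_gene: Optional[dict[str, int]] = None
    set_gene_ids: Optional[list[str]] = None
    rho: Optional[float] = None
    n_feature_redraws: Optional[int] = None
    emission: Optional[dict[str, dict[str, float]]] = None
    bin_features: Optional[dict[str, list[str]]] = None  # per-chrom underlying feature
    block_members: Optional[dict[str, list[str]]] = None
    de_genes: Optional[dict[str, float]] = None     # gene -> planted effect
    group_samples: Optional[dict[str, list[str]]] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# -- genome ------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimParams:
    """Parameters of the toy multi-gene genome.

    Gene lengths are log-normal (median ~10 kb), intergenic spacing
    log-normal (median ~20 kb) so promoter/downstream windows of
    neighboring genes rarely collide, exon counts uniform on a range.
    """

    n_chromosomes: int = 1
    n_genes: int = 200
    gene_length_mu: float = 9.2     # log bp; median ~9.9 kb
    gene_length_sigma: float = 0.5
    spacing_mu: float = 9.9         # log bp; median ~20 kb
    spacing_sigma: float = 0.5
    exons_per_gene: tuple[int, int] = (2, 8)
    coding_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise SimulationError("counts must be >= 1")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise SimulationError("invalid exons_per_gene range")


_MIN_PART = 50  # minimum exon/intron piece, bp


def generate_genome(params: GenomeSimParams) -> tuple[GenomeAnnotation, SimulationTruth]:
    """Generate non-overlapping gene models on one or more chromosomes."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    strands: dict[str, str] = {}
    per_chrom = np.full(params.n_chromosomes, params.n_genes // params.n_chromosomes)
    per_chrom[: params.n_genes % params.n_chromosomes] += 1
    gid = 0
    for ci in range(params.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.lognormal(params.spacing_mu, params.spacing_sigma))
        for _ in range(int(per_chrom[ci])):
            gid += 1
            gene_id = f"g{gid:05d}"
            k = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
            n_parts = 2 * k - 1
            L = int(rng.lognormal(params.gene_length_mu, params.gene_length_sigma))
            L = max(L, _MIN_PART * n_parts + n_parts)
            w = rng.dirichlet(np.ones(n_parts))
            lens = (_MIN_PART + np.floor(w * (L - _MIN_PART * n_parts))).astype(int)
            lens[-1] += L - int(lens.sum())
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            exons = []
            pos = start
            for i, ln in enumerate(lens):
                if i % 2 == 0:  # exon part
                    exons.append(GenomicInterval(chrom, pos, pos + int(ln), strand))
                pos += int(ln)
            end = pos
            cds_start = cds_end = None
            if rng.random() < params.coding_fraction:
                # CDS begins inside the first exon and ends inside the last,
                # leaving non-empty UTR pieces on both sides
                first, last = exons[0], exons[-1]
                cds_start = first.start + 1 + int(
                    rng.integers(0, max(1, len(first) - 2))
                )
                cds_end = last.end - 1 - int(rng.integers(0, max(1, len(last) - 2)))
                if cds_end <= cds_start:  # single short exon: keep a 1-bp CDS
                    cds_start = first.start + max(1, len(first) // 3)
                    cds_end = min(end - 1, cds_start + max(1, len(first) // 3))
                    if cds_end <= cds_start:
                        cds_start = cds_end = None
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    span=GenomicInterval(chrom, start, end, strand),
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    symbol=f"GENE{gid}",
                )
            )
            strands[gene_id] = strand
            cursor = end + int(rng.lognormal(params.spacing_mu, params.spacing_sigma))
        chrom_lengths[chrom] = cursor
    annotation = GenomeAnnotation(genes, chrom_lengths=chrom_lengths)
    truth = SimulationTruth(gene_strands=strands, chrom_lengths=chrom_lengths)
    return annotation, truth


# -- peaks -------------------------------------------------------------


def _default_feature_weights() -> dict[str, float]:
    # mimics the prevalent distal-intergenic / intronic / promoter
    # association of pioneer-factor peaks
    return {
        "Promoter": 0.20,
        "FivePrimeUTR": 0.02,
        "ThreePrimeUTR": 0.03,
        "Exon": 0.05,
        "Intron": 0.25,
        "Downstream": 0.05,
        "DistalIntergenic": 0.40,
    }


@dataclass(frozen=True)
class PeakSimParams:
    """Peak-placement parameters.

    ``feature_weights`` gives the marginal placement bias over the seven
    feature classes; ``rho`` multiplies the density on gene-set genes
    (rho = 1 means no set preference).  Pileup values are log-normal
    with an optional per-feature scale factor.
    """

    n_peaks: int = 2000
    feature_weights: dict[str, float] = field(default_factory=_default_feature_weights)
    rho: float = 1.0
    width_mu: float = 5.8       # log bp; median ~330 bp
    width_sigma: float = 0.35
    pileup_mu: float = 3.0
    pileup_sigma: float = 0.5
    pileup_feature_scale: dict[str, float] = field(default_factory=dict)
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise SimulationError("n_peaks must be >= 1")
        if self.rho < 0:
            raise SimulationError("rho must be >= 0")
        total = sum(self.feature_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"feature weights must sum to 1 (got {total})")
        unknown = set(self.feature_weights) - set(FEATURE_CLASSES)
        if unknown:
            raise SimulationError(f"unknown features in weights: {sorted(unknown)}")


def _strata_index(annotation, ann_params):
    """gene_id -> feature -> (starts, lengths, total_len) from the feature map."""
    fmap = feature_map(annotation, ann_params)
    idx: dict[str, dict[str, tuple[np.ndarray, np.ndarray, int, str]]] = {}
    for chrom, segments in fmap.items():
        for a, b, feat, gid in segments:
            idx.setdefault(gid, {}).setdefault(feat, []).append((chrom, a, b))
    out = {}
    for gid, feats in idx.items():
        out[gid] = {}
        for feat, segs in feats.items():
            starts = np.array([a for _, a, _ in segs], dtype=np.int64)
            lens = np.array([b - a for _, a, b in segs], dtype=np.int64)
            out[gid][feat] = (segs[0][0], starts, lens, int(lens.sum()))
    return out


def generate_peaks(
    annotation: GenomeAnnotation,
    params: PeakSimParams,
    gene_set: Optional[GeneSet] = None,
    ann_params: AnnotationParams = AnnotationParams(),
) -> tuple[PeakSet, SimulationTruth]:
    """Place peaks with per-feature bias and optional gene-set enrichment.

    Each peak draws a gene (probability proportional to rho for set
    genes, 1 otherwise), then a feature stratum from the weight vector,
    then a summit uniformly within that stratum of that gene (strata
    come from the same feature map the classifier defines).  Empty
    strata trigger a feature redraw for the same gene, keeping the
    gene-draw marginal exact; redraws are counted in the truth record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    gene_ids = annotation.gene_ids
    G = len(gene_ids)
    set_members = set(gene_set.gene_ids) if gene_set is not None else set()
    missing = set_members - set(gene_ids)
    if missing:
        raise SimulationError(f"set genes absent from annotation: {sorted(missing)[:5]}")
    weights = np.array(
        [params.rho if g in set_members else 1.0 for g in gene_ids], dtype=float
    )
    if weights.sum() == 0:
        raise SimulationError("all gene weights are zero")
    gene_draws = rng.choice(G, size=params.n_peaks, p=weights / weights.sum())
    feat_names = list(FEATURE_CLASSES)
    feat_p = np.array([params.feature_weights.get(f, 0.0) for f in feat_names])
    feat_draws = rng.choice(len(feat_names), size=params.n_peaks, p=feat_p)
    strata = _strata_index(annotation, ann_params)

    peaks: list[Peak] = []
    truth_genes: list[str] = []
    truth_feats: list[str] = []
    per_gene: dict[str, int] = {g: 0 for g in gene_ids}
    n_redraws = 0
    for i in range(params.n_peaks):
        gid = gene_ids[int(gene_draws[i])]
        gene_strata = strata.get(gid, {})
        feat = feat_names[int(feat_draws[i])]
        tries = 0
        while feat not in gene_strata:
            n_redraws += 1
            tries += 1
            if tries > 100:
                avail = sorted(gene_strata)
                if not avail:
                    raise SimulationError(f"gene {gid} has no placeable strata")
                feat = avail[int(rng.integers(len(avail)))]
                break
            feat = feat_names[int(rng.choice(len(feat_names), p=feat_p))]
        chrom, starts, lens, total = gene_strata[feat]
        offset = int(rng.integers(total))
        seg = int(np.searchsorted(np.cumsum(lens), offset, side="right"))
        summit = int(starts[seg] + offset - (np.cumsum(lens)[seg] - lens[seg]))
        half = max(50, int(rng.lognormal(params.width_mu, params.width_sigma)) // 2)
        start = max(0, summit - half)
        end = summit + half + 1
        scale = params.pileup_feature_scale.get(feat, 1.0)
        pileup = float(rng.lognormal(params.pileup_mu, params.pileup_sigma)) * scale
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                summit=summit,
                score=pileup,
                pileup=pileup,
                name=f"{params.sample_id}_peak_{i + 1}",
            )
        )
        truth_genes.append(gid)
        truth_feats.append(feat)
        per_gene[gid] += 1
    if n_redraws:
        logger.info("generate_peaks: %d feature redraws for empty strata", n_redraws)
    # PeakSet sorts by position; keep the truth lists aligned with it
    order = sorted(
        range(len(peaks)),
        key=lambda i: (peaks[i].interval.chrom, peaks[i].interval.start,
                       peaks[i].interval.end),
    )
    peaks = [peaks[i] for i in order]
    truth_genes = [truth_genes[i] for i in order]
    truth_feats = [truth_feats[i] for i in order]
    truth = SimulationTruth(
        peak_genes=truth_genes,
        peak_features=truth_feats,
        peaks_per_gene=per_gene,
        set_gene_ids=sorted(set_members) or None,
        rho=params.rho,
        n_feature_redraws=n_redraws,
    )
    return PeakSet(sample_id=params.sample_id, peaks=peaks), truth


# -- segmentation ------------------------------------------------------


def _default_emissions() -> dict[str, dict[str, float]]:
    """Feature-conditional state emission probabilities.

    Promoter bins are TssA/TssAFlnk-heavy, genic bins transcription-
    state-heavy, distal intergenic mostly quiescent with an enhancer
    component — mirroring the structure of real peak/state overlap.
    """
    return {
        "Promoter": {"TssA": 0.55, "TssAFlnk": 0.30, "TxFlnk": 0.05, "Enh": 0.05, "Quies": 0.05},
        "FivePrimeUTR": {"TssA": 0.35, "TssAFlnk": 0.30, "Tx": 0.20, "TxWk": 0.15},
        "ThreePrimeUTR": {"Tx": 0.45, "TxWk": 0.35, "Enh": 0.05, "Quies": 0.15},
        "Exon": {"Tx": 0.50, "TxWk": 0.30, "EnhG": 0.10, "Quies": 0.10},
        "Intron": {"TxWk": 0.35, "Tx": 0.15, "EnhG": 0.10, "Enh": 0.15, "Quies": 0.25},
        "Downstream": {"TxWk": 0.30, "Tx": 0.10, "Enh": 0.10, "Quies": 0.50},
        "DistalIntergenic": {"Quies": 0.70, "Enh": 0.12, "EnhG": 0.03, "Het": 0.10, "ReprPCWk": 0.05},
    }


@dataclass(frozen=True)
class SegSimParams:
    """Feature-dependent chromatin-state emission parameters."""

    bin_size: int = 200
    emissions: dict[str, dict[str, float]] = field(default_factory=_default_emissions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise SimulationError("bin_size must be positive")
        for feat, dist in self.emissions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError(f"emission for {feat!r} does not sum to 1")
            unknown = set(dist) - set(ROADMAP_15_STATES)
            if unknown:
                raise SimulationError(f"unknown states for {feat!r}: {sorted(unknown)}")


def generate_segmentation(
    annotation: GenomeAnnotation,
    params: SegSimParams,
    ann_params: AnnotationParams = AnnotationParams(),
) -> tuple[ChromatinSegmentation, SimulationTruth]:
    """Emit one state per bin from the bin's underlying feature.

    A bin's feature is the feature-map label at the bin midpoint; the
    whole genome grid is covered.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    fmap = feature_map(annotation, ann_params)
    seg = ChromatinSegmentation(bin_size=params.bin_size, states=ROADMAP_15_STATES)
    state_idx = {s: i for i, s in enumerate(ROADMAP_15_STATES)}
    bin_features: dict[str, list[str]] = {}
    for chrom, segments in fmap.items():
        extent = segments[-1][1]
        n_bins = (extent + params.bin_size - 1) // params.bin_size
        seg_starts = np.array([a for a, _, _, _ in segments], dtype=np.int64)
        midpoints = np.arange(n_bins, dtype=np.int64) * params.bin_size + params.bin_size // 2
        which = np.clip(np.searchsorted(seg_starts, midpoints, side="right") - 1, 0, None)
        feats = [segments[int(j)][2] for j in which]
        states = np.empty(n_bins, dtype=np.int16)
        feats_arr = np.array(feats)
        for feat in sorted(set(feats)):  # sorted: draw order must not depend on hashing
            dist = params.emissions.get(feat)
            if dist is None:
                raise SimulationError(f"no emission distribution for feature {feat!r}")
            names = sorted(dist)
            probs = np.array([dist[s] for s in names])
            mask = feats_arr == feat
            draws = rng.choice(len(names), size=int(mask.sum()), p=probs)
            states[mask] = [state_idx[names[d]] for d in draws]
        seg.set_chromosome(chrom, states)
        bin_features[chrom] = feats
    truth = SimulationTruth(emission=params.emissions, bin_features=bin_features)
    return seg, truth


# -- expression --------------------------------------------------------


@dataclass(frozen=True)
class ExprSimParams:
    """Two anti-correlated gene blocks plus planted differential expression.

    Block structure comes from a shared latent factor per sample: block
    A genes load +sqrt(r_within); block B genes load so that within-
    block correlation is ``within_r`` and cross-block correlation is
    ``between_r`` (feasible when between_r**2 <= within_r**2).  DE is
    planted by adding ``delta`` to group-2 samples of ``n_de_genes``
    genes drawn from the unstructured background.
    """

    n_samples: int = 60
    block_sizes: tuple[int, int] = (45, 54)
    within_r: float = 0.8
    between_r: float = -0.8
    n_null_genes: int = 500
    n_de_genes: int = 0
    delta: float = 2.0
    sigma: float = 0.25
    group_sizes: Optional[tuple[int, int]] = None
    base_mu: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise SimulationError("need >= 2 samples")
        if not (0 < self.within_r < 1):
            raise SimulationError("within_r must be in (0, 1)")
        if self.between_r**2 > self.within_r**2 + 1e-12:
            raise SimulationError(
                "infeasible correlation targets: need between_r**2 <= within_r**2"
            )
        if self.sigma <= 0:
            raise SimulationError("sigma must be > 0")
        if self.group_sizes is not None and sum(self.group_sizes) > self.n_samples:
            raise SimulationError("group sizes exceed n_samples")
        if self.n_de_genes > 0 and self.group_sizes is None:
            raise SimulationError("planted DE requires group_sizes")


def generate_expression(
    params: ExprSimParams,
    gene_ids: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a log2 expression matrix with planted structure.

    Row order: block A genes, block B genes, background genes (the last
    ``n_de_genes`` of which carry the planted effect).  Pass ``gene_ids``
    to name rows after an annotation's genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    nA, nB = params.block_sizes
    n_genes = nA + nB + params.n_null_genes + params.n_de_genes
    samples = [f"s{i + 1:03d}" for i in range(params.n_samples)]
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise SimulationError(
            f"need {n_genes} gene ids, got {len(gene_ids)}"
        )
    rw, rb = params.within_r, params.between_r
    f = rng.standard_normal(params.n_samples)   # shared latent factor
    g = rng.standard_normal(params.n_samples)   # block-B residual factor
    X = np.empty((n_genes, params.n_samples))
    loadA = np.sqrt(rw)
    loadB_f = rb / np.sqrt(rw) if rw > 0 else 0.0
    loadB_g = np.sqrt(max(rw - loadB_f**2, 0.0))
    for i in range(nA):
        eps = rng.standard_normal(params.n_samples)
        X[i] = loadA * f + np.sqrt(1 - rw) * eps
    for i in range(nB):
        eps = rng.standard_normal(params.n_samples)
        X[nA + i] = loadB_f * f + loadB_g * g + np.sqrt(1 - rw) * eps
    n_bg = params.n_null_genes + params.n_de_genes
    X[nA + nB:] = rng.standard_normal((n_bg, params.n_samples)) * params.sigma
    base = params.base_mu + rng.uniform(-2.0, 2.0, size=n_genes)
    X += base[:, None]
    truth = SimulationTruth(
        block_members={
            "A": gene_ids[:nA],
            "B": gene_ids[nA: nA + nB],
        }
    )
    if params.group_sizes is not None:
        n1, n2 = params.group_sizes
        g1, g2 = samples[:n1], samples[n1: n1 + n2]
        truth.group_samples = {"group1": g1, "group2": g2}
        if params.n_de_genes > 0:
            de_ids = gene_ids[nA + nB + params.n_null_genes:]
            X[nA + nB + params.n_null_genes:, n1: n1 + n2] += params.delta
            truth.de_genes = {gid: params.delta for gid in de_ids}
    df = pd.DataFrame(X, index=gene_ids, columns=samples)
    df.index.name = "gene_id"
    return df, truth
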