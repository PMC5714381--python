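"""Gene-set peak enrichment: hypergeometric feature bias and bootstrap test.

Two complementary tests link a peak collection to a gene set:

* a hypergeometric test asking whether peaks assigned to set genes fall
  into a genomic feature (e.g. distal intergenic) more or less often
  than all peaks do;

* a bootstrap test asking whether the *number* of peaks associated with
  the set is unusually high or low: the null distribution is built by
  repeatedly drawing same-size random gene groups from the full
  annotated-gene universe and summing their peak counts, and tail
  p-values come from a maximum-likelihood skew-normal fit to that
  null (with empirical add-one companions).

A peak is "associated" with a gene when the feature classifier assigned
it that gene, whichever of the seven feature classes it landed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .genome_annotation import AnnotatedPeak, FeatureDistribution, GenomeAnnotation


class EnrichmentError(ValueError):
    """Invalid enrichment-test input."""


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene identifiers."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise EnrichmentError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise EnrichmentError(f"gene set {self.name!r} has duplicate ids")

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a gene set: one gene id per line, '#' comments allowed."""
    ids: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    import os

    return GeneSet(
        name=name or os.path.splitext(os.path.basename(str(path)))[0],
        gene_ids=tuple(dict.fromkeys(ids)),
    )


@dataclass(frozen=True)
class PeakGeneAssociation:
    """Per-gene associated-peak counts over a fixed gene universe."""

    counts: dict[str, int]
    universe: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def total_peaks(self) -> int:
        return sum(self.counts.values())

    def count_vector(self) -> np.ndarray:
        return np.array([self.counts.get(g, 0) for g in self.universe], dtype=np.int64)

    def set_count(self, gene_set: GeneSet) -> int:
        return sum(self.counts.get(g, 0) for g in gene_set.gene_ids)


def associate_peaks(
    annotated_peaks: Sequence[AnnotatedPeak], annotation: GenomeAnnotation
) -> PeakGeneAssociation:
    """Count peaks per assigned gene over the annotation's full gene list.

    Genes without peaks are present with count 0; the universe is all
    annotated genes, not just those with peaks.
    """
    counts: dict[str, int] = {}
    for ap in annotated_peaks:
        if not ap.gene_id:
            raise EnrichmentError("peak without gene assignment; classify first")
        counts[ap.gene_id] = counts.get(ap.gene_id, 0) + 1
    unknown = set(counts) - set(annotation.genes)
    if unknown:
        raise EnrichmentError(
            f"peaks assigned to genes absent from the annotation: {sorted(unknown)[:5]}"
        )
    return PeakGeneAssociation(counts=counts, universe=tuple(annotation.gene_ids))


@dataclass(frozen=True)
class HypergeomTestResult:
    """Hypergeometric tail test of a feature's share among set peaks."""

    feature: str
    k: int       # set peaks in the feature
    n: int       # set peaks, total
    K: int       # background peaks in the feature
    N_pop: int   # background peaks, total
    p_enrich: float
    p_deplete: float


def hypergeom_feature_test(
    set_dist: FeatureDistribution,
    bg_dist: FeatureDistribution,
    feature: str,
) -> HypergeomTestResult:
    """Test whether set-gene peaks are biased toward a feature class.

    With X ~ Hypergeometric(N_pop, K, n): p_enrich = P[X >= k],
    p_deplete = P[X <= k]; both include P[X = k].
    """
    k = set_dist.count(feature)
    n = set_dist.total
    K = bg_dist.count(feature)
    N_pop = bg_dist.total
    if n > N_pop or k > K or (n - k) > (N_pop - K):
        raise EnrichmentError(
            f"set distribution is not a subset of the background for {feature!r} "
            f"(k={k}, n={n}, K={K}, N_pop={N_pop})"
        )
    rv = stats.hypergeom(N_pop, K, n)
    return HypergeomTestResult(
        feature=feature, k=k, n=n, K=K, N_pop=N_pop,
        p_enrich=float(min(1.0, rv.sf(k - 1))),
        p_deplete=float(min(1.0, rv.cdf(k))),
    )


# -- bootstrap null ----------------------------------------------------

_CHUNK = 512  # trials per RNG substream; fixed so results don't depend on memory


def bootstrap_null(
    assoc: PeakGeneAssociation,
    set_size: int,
    B: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Null peak-count samples for random same-size gene groups.

    Each of the B trials draws ``set_size`` distinct genes uniformly
    without replacement from the full universe and records the summed
    peak count.  Trials are generated in fixed-size chunks, each from
    its own spawned RNG stream, so output is reproducible and
    independent of execution order.
    """
    G = assoc.n_genes
    if set_size > G:
        raise EnrichmentError(f"set_size {set_size} exceeds universe size {G}")
    if B < 1:
        raise EnrichmentError("B must be >= 1")
    counts = assoc.count_vector()
    n_chunks = (B + _CHUNK - 1) // _CHUNK
    streams = np.random.SeedSequence(seed).spawn(n_chunks)
    out = np.empty(B, dtype=np.int64)
    pos = 0
    for ss in streams:
        b = min(_CHUNK, B - pos)
        rng = np.random.default_rng(ss)
        # Gumbel-top-k: the set_size smallest of G uniform keys per row
        # is a uniform without-replacement sample of gene indices.
        keys = rng.random((b, G))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[pos: pos + b] = counts[idx].sum(axis=1)
        pos += b
    return out


# -- skew-normal fit ---------------------------------------------------


@dataclass(frozen=True)
class SkewNormalFit:
    """MLE skew-normal parameters: location xi, scale omega, shape alpha."""

    xi: float
    omega: float
    alpha: float
    loglik: float
    degenerate: bool = False


class SkewNormalFitError(RuntimeError):
    """Optimizer failure; carries method-of-moments fallback parameters."""

    def __init__(self, message: str, fallback: tuple[float, float, float]):
        super().__init__(message)
        self.fallback = fallback


_MAX_ABS_SKEW = 0.9952  # supremum of skew-normal skewness, open bound
_ALPHA_CAP = 50.0


def _moments_init(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments start values (xi, omega, alpha)."""
    m, s = float(np.mean(x)), float(np.std(x))
    g1 = float(np.clip(stats.skew(x), -0.99 * _MAX_ABS_SKEW, 0.99 * _MAX_ABS_SKEW))
    r = abs(g1) ** (2.0 / 3.0)
    delta2 = (np.pi / 2.0) * r / (r + ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0))
    delta = np.sign(g1) * np.sqrt(min(delta2, 0.999))
    alpha = float(delta / np.sqrt(1.0 - delta**2))
    omega = s / np.sqrt(max(1.0 - 2.0 * delta**2 / np.pi, 1e-6))
    xi = m - omega * delta * np.sqrt(2.0 / np.pi)
    return xi, float(omega), alpha


def fit_skew_normal(
    samples: Sequence[float], maxiter: int = 2000
) -> SkewNormalFit:
    """Maximum-likelihood skew-normal fit.

    Density f(x) = (2/omega) phi(z) Phi(alpha z), z = (x - xi)/omega.
    Initialized by method of moments; |alpha| capped at 50 to avoid
    boundary divergence.  Constant samples return a degenerate fit with
    no parameters attempted.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise EnrichmentError(f"need >= 10 samples to fit, got {x.size}")
    if np.var(x) == 0:
        return SkewNormalFit(
            xi=float(x[0]), omega=0.0, alpha=0.0, loglik=np.inf, degenerate=True
        )
    xi0, omega0, alpha0 = _moments_init(x)
    alpha0 = float(np.clip(alpha0, -_ALPHA_CAP, _ALPHA_CAP))

    def nll(theta: np.ndarray) -> float:
        xi, log_omega, alpha = theta
        if abs(alpha) > _ALPHA_CAP:
            return np.inf
        return -float(
            np.sum(stats.skewnorm.logpdf(x, alpha, loc=xi, scale=np.exp(log_omega)))
        )

    res = optimize.minimize(
        nll,
        x0=np.array([xi0, np.log(omega0), alpha0]),
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-8},
    )
    if not res.success or not np.isfinite(res.fun):
        raise SkewNormalFitError(
            f"skew-normal MLE did not converge: {res.message}",
            fallback=(xi0, omega0, alpha0),
        )
    xi, log_omega, alpha = res.x
    return SkewNormalFit(
        xi=float(xi), omega=float(np.exp(log_omega)),
        alpha=float(np.clip(alpha, -_ALPHA_CAP, _ALPHA_CAP)),
        loglik=-float(res.fun),
    )


# -- bootstrap p-values ------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    """Observed set peak count against the bootstrap null.

    Fitted tails come from the skew-normal CDF; empirical tails carry an
    add-one correction and count ties toward both tails.
    """

    observed: int
    B: int
    null_counts: np.ndarray
    fit: Optional[SkewNormalFit]
    p_high: Optional[float]
    p_low: Optional[float]
    p_high_emp: float
    p_low_emp: float
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        null = np.asarray(self.null_counts)
        return {
            "observed": int(self.observed),
            "B": int(self.B),
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=1)) if self.B > 1 else 0.0,
            "fit": None
            if self.fit is None or self.fit.degenerate
            else {
                "xi": self.fit.xi,
                "omega": self.fit.omega,
                "alpha": self.fit.alpha,
                "loglik": self.fit.loglik,
            },
            "p_high": self.p_high,
            "p_low": self.p_low,
            "p_high_emp": self.p_high_emp,
            "p_low_emp": self.p_low_emp,
            "seed": self.seed,
        }


def bootstrap_p(
    observed: int,
    fit: Optional[SkewNormalFit],
    null_counts: np.ndarray,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Tail probabilities of the observed count under the bootstrap null."""
    null = np.asarray(null_counts)
    B = null.size
    p_high_emp = (1 + int(np.sum(null >= observed))) / (B + 1)
    p_low_emp = (1 + int(np.sum(null <= observed))) / (B + 1)
    p_high = p_low = None
    if fit is not None and not fit.degenerate:
        p_high = float(stats.skewnorm.sf(observed, fit.alpha, loc=fit.xi, scale=fit.omega))
        p_low = float(stats.skewnorm.cdf(observed, fit.alpha, loc=fit.xi, scale=fit.omega))
    return BootstrapResult(
        observed=int(observed), B=B, null_counts=null, fit=fit,
        p_high=p_high, p_low=p_low,
        p_high_emp=p_high_emp, p_low_emp=p_low_emp, seed=seed,
    )


def bootstrap_enrichment_test(
    assoc: PeakGeneAssociation,
    gene_set: GeneSet,
    B: int = 10000,
    seed: int = 0,
) -> BootstrapResult:
    """End-to-end bootstrap gene-set peak-enrichment test."""
    missing = [g for g in gene_set.gene_ids if g not in set(assoc.universe)]
    if missing:
        raise EnrichmentError(
            f"gene set {gene_set.name!r} has ids outside the universe: {missing[:5]}"
        )
    observed = assoc.set_count(gene_set)
    null = bootstrap_null(assoc, gene_set.size, B=B, seed=seed)
    fit = fit_skew_normal(null) if np.var(null) > 0 else SkewNormalFit(
        xi=float(null[0]), omega=0.0, alpha=0.0, loglik=np.inf, degenerate=True
    )
    return bootstrap_p(observed, fit, null, seed=seed)
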