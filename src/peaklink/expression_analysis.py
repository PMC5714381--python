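"""Expression-side analyses: probe collapse, scaling, clustering, DE, set tests.

Operates on log2-scale expression matrices (pandas DataFrame, genes x
samples).  Probes mapping to the same gene collapse to the probe with
the largest interquartile range.  Differential expression between two
groups uses a Welch t-test per gene with Benjamini-Hochberg correction
and the significance thresholds adjusted p < 0.05 and |log2 FC| > 1.5.
Gene-set perturbation is tested GAGE-style: a one-sided Welch t
comparing the set's per-gene fold changes (directed) or their absolute
values (undirected) against all measured genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .geneset_enrichment import GeneSet

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Invalid expression-analysis input."""


def load_expression_tsv(path) -> pd.DataFrame:
    """Load an expression TSV (first column = gene/probe id, header = samples).

    Rows containing any missing value are dropped with a logged count;
    downstream statistics assume complete rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        df = df.dropna(axis=0)
    return df.astype(float)


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe rows to genes, keeping the largest-IQR probe per gene.

    Unmapped probes are dropped (count logged).  Equal IQRs break by
    lexicographically smaller probe id.
    """
    if not probe_to_gene:
        raise ExpressionError("empty probe-to-gene mapping")
    mapped = [p for p in matrix.index if p in probe_to_gene]
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probes", n_dropped)
    if not mapped:
        raise ExpressionError("no probes map to genes")
    sub = matrix.loc[mapped]
    iqr = sub.quantile(0.75, axis=1) - sub.quantile(0.25, axis=1)
    choice = (
        pd.DataFrame(
            {
                "probe": sub.index,
                "gene": [probe_to_gene[p] for p in sub.index],
                "iqr": iqr.values,
            }
        )
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = sub.loc[choice["probe"]]
    out.index = choice["gene"].values
    return out.sort_index()


def zscale_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to zero mean, unit sample SD across samples.

    Zero-variance rows become all-zeros (with a warning); idempotent on
    already-scaled input.
    """
    if matrix.shape[1] < 2:
        raise ExpressionError("need >= 2 samples to scale")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance rows scaled to all-zeros",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    out = (vals - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pairwise_correlation(
    matrix: pd.DataFrame, gene_subset: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Symmetric gene x gene Pearson correlation matrix (unit diagonal)."""
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in matrix.index]
        if missing:
            raise ExpressionError(f"genes absent from matrix: {missing[:10]}")
        matrix = matrix.loc[list(gene_subset)]
    if matrix.shape[1] < 3:
        raise ExpressionError("need >= 3 samples for correlation")
    r = np.corrcoef(matrix.to_numpy(dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


@dataclass
class ClusterResult:
    """Complete-linkage hierarchical clustering of matrix rows."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    leaf_order: tuple[str, ...]
    flat: Optional[dict[str, int]] = None  # label -> cluster id at k


def hier_cluster(
    data: pd.DataFrame,
    input_type: Literal["expression", "correlation"] = "expression",
    k: Optional[int] = None,
) -> ClusterResult:
    """Agglomerative complete-linkage clustering of rows.

    Distance is Euclidean on gene-wise z-scaled rows for expression
    input, and 1 - r for a correlation-matrix input.
    """
    if data.shape[0] < 2:
        raise ExpressionError("need >= 2 items to cluster")
    if input_type == "expression":
        scaled = zscale_genes(data)
        Z = hierarchy.linkage(scaled.to_numpy(dtype=float), method="complete",
                              metric="euclidean")
    elif input_type == "correlation":
        d = 1.0 - data.to_numpy(dtype=float)
        np.fill_diagonal(d, 0.0)
        if not np.all(np.isfinite(d)):
            raise ExpressionError("non-finite distances")
        Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    else:
        raise ExpressionError(f"unknown input_type {input_type!r}")
    if not np.all(np.isfinite(Z)):
        raise ExpressionError("non-finite distances")
    labels = tuple(data.index)
    order = tuple(labels[i] for i in hierarchy.leaves_list(Z))
    flat = None
    if k is not None:
        assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        flat = {lab: int(c) for lab, c in zip(labels, assignments)}
    return ClusterResult(labels=labels, linkage=Z, leaf_order=order, flat=flat)


def _moderated_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated t for a two-group comparison.

    Per-gene pooled variances s2_g (d = n1 + n2 - 2 df) are shrunk
    toward a prior (d0, s0^2) estimated by moment-matching the marginal
    scaled-F distribution of s2_g on the log scale (Smyth-style):
    solve trigamma(d0/2) = var(log s2) - trigamma(d/2), then
    s2_tilde = (d0 s0^2 + d s2) / (d0 + d) and t uses d + d0 df.
    """
    from scipy.special import polygamma
    from scipy.optimize import brentq

    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / d
    ok = s2 > 0
    if ok.sum() < 3:  # not enough genes to estimate a prior
        d0, s0 = 0.0, 0.0
    else:
        z = np.log(s2[ok])
        target = float(np.var(z, ddof=1)) - float(polygamma(1, d / 2))
        if target <= 1e-8:
            d0 = np.inf
            s0 = float(np.exp(np.mean(z) - polygamma(0, d / 2) + np.log(d / 2)))
        else:
            d0 = 2.0 * brentq(
                lambda y: float(polygamma(1, y)) - target, 1e-4, 1e7
            )
            s0 = float(
                np.exp(
                    np.mean(z)
                    - polygamma(0, d / 2) + np.log(d / 2)
                    + polygamma(0, d0 / 2) - np.log(d0 / 2)
                )
            )
    if d0 == 0.0:
        s2_tilde, df = s2, float(d)
    elif np.isinf(d0):
        s2_tilde, df = np.full_like(s2, s0), 1e6
    else:
        s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
        df = float(d + d0)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b.mean(axis=1) - a.mean(axis=1)) / se
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def differential_expression(
    matrix: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.5,
    method: Literal["moderated", "welch"] = "moderated",
) -> pd.DataFrame:
    """Two-group differential expression on a log2 matrix.

    Per gene: log2FC = mean(group2) - mean(group1); a moderated t-test
    (empirical-Bayes variance shrinkage, the default, needed for usable
    power at the triplicate scale) or Welch's t; BH adjustment across
    all genes; ``significant`` flags genes at adjusted p < ``alpha``
    and |log2FC| > ``lfc_threshold``.
    """
    for grp, name in ((group1, "group1"), (group2, "group2")):
        if len(grp) < 2:
            raise ExpressionError(f"{name} needs >= 2 samples, got {len(grp)}")
        missing = [s for s in grp if s not in matrix.columns]
        if missing:
            raise ExpressionError(f"{name} samples absent from matrix: {missing}")
    a = matrix[list(group1)].to_numpy(dtype=float)
    b = matrix[list(group2)].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    if method == "moderated":
        t, p = _moderated_t(a, b)
    elif method == "welch":
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    else:
        raise ExpressionError(f"unknown method {method!r}")
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both genes
    t = np.where(np.isnan(t), 0.0, t)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "pvalue": p,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(log2fc) > lfc_threshold),
        },
        index=matrix.index,
    )
    table.index.name = "gene_id"
    return table


@dataclass(frozen=True)
class GeneSetTestResult:
    """GAGE-style perturbation test of a gene set against all genes."""

    set_name: str
    mode: Literal["directed", "undirected"]
    n_set: int
    n_background: int
    t: float
    df: float
    pvalue: float


def geneset_perturbation_test(
    de_table: pd.DataFrame,
    gene_set: GeneSet,
    mode: Literal["directed", "undirected"] = "directed",
    min_size: int = 5,
    max_size: int = 500,
) -> GeneSetTestResult:
    """Test whether a gene set is perturbed relative to all measured genes.

    Gene statistics are log2 fold changes (directed) or their absolute
    values (undirected).  A one-sided Welch two-sample t compares the
    set's statistics against all measured genes' statistics (set mean
    greater).  Sets must satisfy ``min_size < |set ∩ measured| < max_size``.
    """
    if mode not in ("directed", "undirected"):
        raise ExpressionError(f"unknown mode {mode!r}")
    measured = [g for g in gene_set.gene_ids if g in de_table.index]
    if not (min_size < len(measured) < max_size):
        raise ExpressionError(
            f"gene set {gene_set.name!r}: {len(measured)} measured members "
            f"outside the usable size bounds ({min_size}, {max_size})"
        )
    all_stats = de_table["log2fc"].to_numpy(dtype=float)
    set_stats = de_table.loc[measured, "log2fc"].to_numpy(dtype=float)
    if mode == "undirected":
        all_stats = np.abs(all_stats)
        set_stats = np.abs(set_stats)
    res = stats.ttest_ind(set_stats, all_stats, equal_var=False, alternative="greater")
    return GeneSetTestResult(
        set_name=gene_set.name,
        mode=mode,
        n_set=len(measured),
        n_background=int(all_stats.size),
        t=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
    )
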