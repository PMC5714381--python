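"""Gene models and genomic-feature classification of ChIP-seq peaks.

Peaks are assigned to one of seven genomic features — Promoter, 5'UTR,
3'UTR, Exon, Intron, Downstream, DistalIntergenic — based on the position
of the peak *summit* relative to an annotation of gene models.  The
promoter is a symmetric window around the transcription start site
(default +/-3 kb); "Downstream" is a bounded window past the gene end in
gene orientation.  Overlaps between features and between genes are
resolved by a fixed precedence order, so every summit receives exactly
one feature and one assigned gene.

All coordinates are BED-style: 0-based, half-open intervals; summits are
single base offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: The seven feature classes, in classification precedence order
#: (earlier wins when a summit lies in several candidate regions).
FEATURE_CLASSES = (
    "Promoter",
    "FivePrimeUTR",
    "ThreePrimeUTR",
    "Exon",
    "Intron",
    "Downstream",
    "DistalIntergenic",
)

_FEATURE_RANK = {f: i for i, f in enumerate(FEATURE_CLASSES)}


class AnnotationError(ValueError):
    """Invalid gene-model input or an unclassifiable peak."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure and optional coding region.

    ``tss`` is the strand-aware transcription start site: ``span.start``
    on the plus strand, ``span.end - 1`` on the minus strand.  ``cds_start``
    and ``cds_end`` are genomic bounds of the coding region; both ``None``
    for non-coding genes.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.span.strand!r}"
            )
        prev_end = self.span.start - 1
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise AnnotationError(f"gene {self.gene_id}: exon outside span")
            if ex.start <= prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons must be ordered and non-overlapping"
                )
            prev_end = ex.end - 1
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"gene {self.gene_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.span.start <= self.cds_start < self.cds_end <= self.span.end):
                raise AnnotationError(f"gene {self.gene_id}: CDS outside span")

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class AnnotationParams:
    """Window sizes (bp) controlling classification.

    ``promoter_window``: half-width of the symmetric promoter window
    around the TSS.  ``downstream_window``: extent of the Downstream
    region past the gene end, in gene orientation.
    """

    promoter_window: int = 3000
    downstream_window: int = 3000

    def __post_init__(self) -> None:
        if self.promoter_window <= 0 or self.downstream_window <= 0:
            raise AnnotationError("annotation windows must be positive")


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its feature class, assigned gene, and TSS distance.

    ``dist_to_tss`` is signed in gene orientation: negative means the
    summit lies upstream of the assigned gene's TSS.
    """

    peak: "Peak"  # noqa: F821 - peak_toolkit.Peak, avoided circular import
    feature: str
    gene_id: str
    dist_to_tss: int


class GenomeAnnotation:
    """A collection of gene models indexed for summit classification."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Optional[dict[str, int]] = None,
    ):
        self.genes: dict[str, GeneModel] = {}
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            self.by_chrom.setdefault(g.span.chrom, []).append(g)
        for chrom_genes in self.by_chrom.values():
            chrom_genes.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else {}
        self._trees: dict[tuple[int, int], dict[str, IntervalTree]] = {}
        self._feature_maps: dict = {}

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    # -- candidate feature regions -------------------------------------

    def _candidate_intervals(
        self, gene: GeneModel, params: AnnotationParams
    ) -> list[tuple[int, int, str]]:
        """Half-open (start, end, feature) candidate regions for one gene."""
        s, e, strand = gene.span.start, gene.span.end, gene.span.strand
        out: list[tuple[int, int, str]] = []
        # promoter: summit within +/- promoter_window of the TSS, inclusive
        p0 = max(0, gene.tss - params.promoter_window)
        p1 = gene.tss + params.promoter_window + 1
        out.append((p0, p1, "Promoter"))
        # UTRs: exonic sequence outside the CDS on the respective side
        if gene.is_coding:
            five = (s, gene.cds_start) if strand == "+" else (gene.cds_end, e)
            three = (gene.cds_end, e) if strand == "+" else (s, gene.cds_start)
            for (lo, hi), feat in ((five, "FivePrimeUTR"), (three, "ThreePrimeUTR")):
                for ex in gene.exons:
                    a, b = max(ex.start, lo), min(ex.end, hi)
                    if a < b:
                        out.append((a, b, feat))
        for ex in gene.exons:
            out.append((ex.start, ex.end, "Exon"))
        # introns: span minus exons
        cursor = s
        for ex in gene.exons:
            if cursor < ex.start:
                out.append((cursor, ex.start, "Intron"))
            cursor = ex.end
        if cursor < e:
            out.append((cursor, e, "Intron"))
        # downstream window past the gene end, in gene orientation
        if strand == "+":
            out.append((e, e + params.downstream_window, "Downstream"))
        else:
            d0 = max(0, s - params.downstream_window)
            if d0 < s:
                out.append((d0, s, "Downstream"))
        return out

    def _tree(self, params: AnnotationParams) -> dict[str, IntervalTree]:
        key = (params.promoter_window, params.downstream_window)
        if key not in self._trees:
            trees: dict[str, IntervalTree] = {}
            for chrom, chrom_genes in self.by_chrom.items():
                t = IntervalTree()
                for g in chrom_genes:
                    for a, b, feat in self._candidate_intervals(g, params):
                        t.addi(a, b, (_FEATURE_RANK[feat], g.gene_id))
                trees[chrom] = t
            self._trees[key] = trees
        return self._trees[key]

    def nearest_tss_gene(self, chrom: str, pos: int) -> GeneModel:
        chrom_genes = self.by_chrom.get(chrom)
        if not chrom_genes:
            raise AnnotationError(
                f"unassignable chromosome: no genes annotated on {chrom!r}"
            )
        return min(chrom_genes, key=lambda g: (abs(pos - g.tss), g.gene_id))


def _signed_dist(summit: int, gene: GeneModel) -> int:
    d = summit - gene.tss
    return d if gene.span.strand == "+" else -d


def classify_summit(
    chrom: str,
    summit: int,
    annotation: GenomeAnnotation,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[str, str, int]:
    """Classify a single summit; returns (feature, gene_id, dist_to_tss).

    Overlaps resolve by feature precedence; ties between genes offering
    the same winning feature break by smaller ``|dist_to_tss|``, then
    lexicographic gene_id.
    """
    tree = annotation._tree(params).get(chrom)
    hits = tree[summit] if tree is not None else set()
    if hits:
        best_rank = min(h.data[0] for h in hits)
        candidates = sorted(
            {h.data[1] for h in hits if h.data[0] == best_rank},
            key=lambda gid: (
                abs(summit - annotation.genes[gid].tss),
                gid,
            ),
        )
        gene = annotation.genes[candidates[0]]
        return FEATURE_CLASSES[best_rank], gene.gene_id, _signed_dist(summit, gene)
    gene = annotation.nearest_tss_gene(chrom, summit)
    return "DistalIntergenic", gene.gene_id, _signed_dist(summit, gene)


def classify_peak(
    peak,
    annotation: GenomeAnnotation,
    params: AnnotationParams = AnnotationParams(),
) -> AnnotatedPeak:
    """Classify one peak by its summit position."""
    feature, gene_id, dist = classify_summit(
        peak.interval.chrom, peak.summit, annotation, params
    )
    return AnnotatedPeak(peak=peak, feature=feature, gene_id=gene_id, dist_to_tss=dist)


def classify_peaks(
    peaks, annotation: GenomeAnnotation, params: AnnotationParams = AnnotationParams()
) -> list[AnnotatedPeak]:
    return [classify_peak(p, annotation, params) for p in peaks]


@dataclass(frozen=True)
class FeatureDistribution:
    """Per-feature peak counts and fractions over a peak collection."""

    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        return {f: c / self.total for f, c in self.counts.items()}

    def count(self, feature: str) -> int:
        return self.counts.get(feature, 0)


def feature_distribution(
    annotated_peaks: Sequence[AnnotatedPeak],
    restrict_to=None,
) -> FeatureDistribution:
    """Count peaks per feature class, optionally restricted to a gene set."""
    peaks = list(annotated_peaks)
    if restrict_to is not None:
        members = set(restrict_to.gene_ids)
        peaks = [p for p in peaks if p.gene_id in members]
    if not peaks:
        raise AnnotationError("no peaks associated with gene set")
    counts = {f: 0 for f in FEATURE_CLASSES}
    for p in peaks:
        counts[p.feature] += 1
    return FeatureDistribution(counts=counts, total=len(peaks))


# -- BED12 I/O ----------------------------------------------------------


def read_gene_models(path) -> GenomeAnnotation:
    """Read gene models from a BED12 file.

    Exons come from the block fields; the CDS from thickStart/thickEnd
    (equal bounds mean a non-coding gene).  Track/browser/comment lines
    are skipped.  Duplicate gene ids are rejected.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"BED12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: malformed BED12 field ({exc})"
                ) from None
            if start >= end:
                raise AnnotationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            if len(sizes) != block_count or len(starts) != block_count:
                raise AnnotationError(
                    f"{path}: line {lineno}: blockSizes/blockStarts inconsistent "
                    f"with blockCount={block_count}"
                )
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            )
            cds_start = cds_end = None
            if thick_start != thick_end:
                cds_start, cds_end = thick_start, thick_end
            try:
                genes.append(
                    GeneModel(
                        gene_id=name,
                        span=GenomicInterval(chrom, start, end, strand),
                        exons=exons,
                        cds_start=cds_start,
                        cds_end=cds_end,
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from None
    return GenomeAnnotation(genes)


def write_gene_models(annotation: GenomeAnnotation, path) -> None:
    """Write an annotation to BED12 (inverse of :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        for gid in annotation.gene_ids:
            g = annotation.genes[gid]
            s = g.span.start
            sizes = ",".join(str(len(ex)) for ex in g.exons)
            starts = ",".join(str(ex.start - s) for ex in g.exons)
            thick = (g.cds_start, g.cds_end) if g.is_coding else (s, s)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.span.chrom,
                        s,
                        g.span.end,
                        gid,
                        0,
                        g.span.strand,
                        thick[0],
                        thick[1],
                        0,
                        len(g.exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


def write_annotated_peaks(annotated: Sequence[AnnotatedPeak], path) -> None:
    """Write annotated peaks as TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsummit\tfeature\tgene_id\tdist_to_tss\n")
        for ap in annotated:
            iv = ap.peak.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ap.peak.summit}\t"
                f"{ap.feature}\t{ap.gene_id}\t{ap.dist_to_tss}\n"
            )


def read_annotated_peaks(path) -> list[AnnotatedPeak]:
    """Read the TSV written by :func:`write_annotated_peaks`."""
    from .peak_toolkit import Peak

    out: list[AnnotatedPeak] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]))
            peak = Peak(interval=iv, summit=int(f[idx["summit"]]))
            out.append(
                AnnotatedPeak(
                    peak=peak,
                    feature=f[idx["feature"]],
                    gene_id=f[idx["gene_id"]],
                    dist_to_tss=int(f[idx["dist_to_tss"]]),
                )
            )
    return out


# -- genome-wide feature map -------------------------------------------


def feature_map(
    annotation: GenomeAnnotation,
    params: AnnotationParams = AnnotationParams(),
    chrom_lengths: Optional[dict[str, int]] = None,
) -> dict[str, list[tuple[int, int, str, str]]]:
    """Materialize the classification as disjoint labeled intervals.

    Returns, per chromosome, an ordered list of (start, end, feature,
    gene_id) intervals tiling [0, chrom_length).  Interval labels are
    evaluated with :func:`classify_summit` at segment midpoints; segment
    breakpoints include all candidate-region endpoints and the midpoints
    between neighboring TSSs, so the winning feature is constant within
    each segment.  Used by the peak simulator so generator and analyzer
    share one geometry.
    """
    key = (params.promoter_window, params.downstream_window, id(chrom_lengths))
    if key in annotation._feature_maps:
        return annotation._feature_maps[key]
    lengths = dict(annotation.chrom_lengths)
    if chrom_lengths:
        lengths.update(chrom_lengths)
    result: dict[str, list[tuple[int, int, str, str]]] = {}
    for chrom, chrom_genes in annotation.by_chrom.items():
        extent = lengths.get(chrom)
        if extent is None:
            extent = max(
                g.span.end + params.downstream_window + params.promoter_window
                for g in chrom_genes
            )
        breaks = {0, extent}
        for g in chrom_genes:
            for a, b, _ in annotation._candidate_intervals(g, params):
                breaks.add(max(0, min(a, extent)))
                breaks.add(max(0, min(b, extent)))
        tss_sorted = sorted(g.tss for g in chrom_genes)
        for t0, t1 in zip(tss_sorted, tss_sorted[1:]):
            mid = (t0 + t1 + 1) // 2  # equidistance boundary for nearest-TSS
            breaks.add(max(0, min(mid, extent)))
        bp = sorted(breaks)
        segments: list[tuple[int, int, str, str]] = []
        for a, b in zip(bp, bp[1:]):
            if a >= b:
                continue
            feat, gid, _ = classify_summit(chrom, (a + b) // 2, annotation, params)
            if segments and segments[-1][2] == feat and segments[-1][3] == gid:
                prev = segments.pop()
                segments.append((prev[0], b, feat, gid))
            else:
                segments.append((a, b, feat, gid))
        result[chrom] = segments
    annotation._feature_maps[key] = result
    return result
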