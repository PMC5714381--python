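"""Peak file I/O, cross-sample overlap (Venn) tables, and pileup comparison.

Peaks from different samples are counted as overlapping if they lie less
than ``max_gap`` bp apart (default 1000 bp, with interval intersection
counting as gap 0).  Overlap regions are formed by single-linkage closure
of that relation so the Venn cells partition the merged regions.  Pileup
(read-depth) values of two peak groups are compared with a Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import chain
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .genome_annotation import GenomicInterval


class PeakError(ValueError):
    """Invalid peak input."""


@dataclass(frozen=True)
class Peak:
    """A called peak with summit, score and pileup (read-depth proxy)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    pileup: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise PeakError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.pileup < 0:
            raise PeakError("pileup must be non-negative")


@dataclass
class PeakSet:
    """Peaks of one sample (cell line x factor), sorted by position."""

    sample_id: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise PeakError("sample_id must be non-empty")
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)


def read_narrowpeak(path, sample_id: str) -> PeakSet:
    """Read an ENCODE narrowPeak (10-column) or BED3+ file.

    narrowPeak: summit = start + column-10 offset (offset -1 falls back
    to the interval midpoint); signalValue is stored as pileup.  Plain
    BED: summit = interval midpoint, pileup 0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise PeakError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise PeakError(f"{path}: line {lineno}: start >= end")
            name = f[3] if len(f) > 3 else f"peak_{lineno}"
            score = float(f[4]) if len(f) > 4 else 0.0
            if len(f) >= 10:
                pileup = float(f[6])
                offset = int(f[9])
                if offset == -1:
                    summit = start + (end - start) // 2
                elif offset >= end - start:
                    raise PeakError(
                        f"{path}: line {lineno}: summit offset {offset} >= "
                        f"peak length {end - start}"
                    )
                else:
                    summit = start + offset
            else:
                pileup = 0.0
                summit = start + (end - start) // 2
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit=summit,
                    score=score,
                    pileup=pileup,
                    name=name,
                )
            )
    return PeakSet(sample_id=sample_id, peaks=peaks)


def write_narrowpeak(peak_set: PeakSet, path) -> None:
    """Write a PeakSet in 10-column narrowPeak format."""
    with open(path, "w") as fh:
        for p in peak_set.peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iv.chrom,
                        iv.start,
                        iv.end,
                        p.name,
                        int(p.score),
                        ".",
                        p.pileup,
                        -1,
                        -1,
                        p.summit - iv.start,
                    )
                )
                + "\n"
            )


@dataclass
class OverlapTable:
    """Venn cell counts over single-linkage merged peak regions."""

    sample_ids: tuple[str, ...]
    counts: dict[frozenset, int]
    max_gap: int

    @property
    def n_regions(self) -> int:
        return sum(self.counts.values())

    @property
    def n_common(self) -> int:
        return self.counts.get(frozenset(self.sample_ids), 0)

    @property
    def fraction_common(self) -> float:
        return self.n_common / self.n_regions if self.n_regions else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("membership\tcount\n")
            for key in sorted(self.counts, key=lambda k: sorted(k)):
                fh.write("+".join(sorted(key)) + f"\t{self.counts[key]}\n")

    def to_json(self, path) -> None:
        obj = {
            "sample_ids": list(self.sample_ids),
            "max_gap": self.max_gap,
            "n_regions": self.n_regions,
            "fraction_common": self.fraction_common,
            "cells": {"+".join(sorted(k)): v for k, v in sorted(
                self.counts.items(), key=lambda kv: sorted(kv[0])
            )},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")


def cluster_overlapping(
    peak_sets: Sequence[PeakSet], max_gap: int = 1000
) -> OverlapTable:
    """Merge peaks across samples into regions; count Venn membership cells.

    Two peaks link if their intervals intersect or the gap between them
    is strictly less than ``max_gap``; regions are the single-linkage
    closure of that relation, so each merged region contributes to
    exactly one membership cell.
    """
    if len(peak_sets) < 2:
        raise PeakError("need at least two peak sets for an overlap table")
    for ps in peak_sets:
        if not ps.peaks:
            raise PeakError(f"peak set {ps.sample_id!r} is empty")
    ids = tuple(ps.sample_id for ps in peak_sets)
    if len(set(ids)) != len(ids):
        raise PeakError("duplicate sample_ids")
    all_peaks = sorted(
        chain.from_iterable(
            ((p, ps.sample_id) for p in ps.peaks) for ps in peak_sets
        ),
        key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end),
    )
    counts: dict[frozenset, int] = {}
    cur_chrom = None
    cur_end = -1
    cur_members: set[str] = set()

    def flush() -> None:
        if cur_members:
            key = frozenset(cur_members)
            counts[key] = counts.get(key, 0) + 1

    for peak, sid in all_peaks:
        iv = peak.interval
        if iv.chrom != cur_chrom or iv.start - cur_end >= max_gap:
            flush()
            cur_chrom = iv.chrom
            cur_end = iv.end
            cur_members = {sid}
        else:
            cur_end = max(cur_end, iv.end)
            cur_members.add(sid)
    flush()
    return OverlapTable(sample_ids=ids, counts=counts, max_gap=max_gap)


@dataclass(frozen=True)
class RankTestResult:
    """Wilcoxon rank-sum comparison of two pileup groups."""

    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    statistic: float
    p_two_sided: float
    p_a_greater: float
    degenerate: bool = False


def pileup_rank_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankTestResult:
    """Compare two groups of pileup values by Wilcoxon rank-sum.

    Accepts raw values or Peak objects.  Uses the exact null for small
    tie-free samples and the tie-corrected normal approximation
    otherwise.  If all values across both groups are identical the
    result is flagged degenerate with p = 1.
    """
    a = np.asarray([getattr(x, "pileup", x) for x in group_a], dtype=float)
    b = np.asarray([getattr(x, "pileup", x) for x in group_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise PeakError("both groups must be non-empty")

    def iqr(v: np.ndarray) -> float:
        q75, q25 = np.percentile(v, [75, 25])
        return float(q75 - q25)

    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return RankTestResult(
            n_a=a.size, n_b=b.size,
            median_a=float(np.median(a)), median_b=float(np.median(b)),
            iqr_a=iqr(a), iqr_b=iqr(b),
            statistic=float(a.size * b.size / 2), p_two_sided=1.0,
            p_a_greater=1.0, degenerate=True,
        )
    two = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    one = stats.mannwhitneyu(a, b, alternative="greater", method="auto")
    return RankTestResult(
        n_a=a.size, n_b=b.size,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        iqr_a=iqr(a), iqr_b=iqr(b),
        statistic=float(two.statistic),
        p_two_sided=float(min(1.0, two.pvalue)),
        p_a_greater=float(min(1.0, one.pvalue)),
    )
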