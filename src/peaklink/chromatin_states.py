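"""Fixed-bin chromatin-state segmentations and peak-state profiling.

A segmentation labels every 200-bp genomic bin with one state from a
15-state vocabulary (the Roadmap core model: TssA ... Quies).  Each peak
is assigned the state of the bin containing its summit; relative state
abundance is profiled for peak subsets (e.g. distal intergenic peaks of
an epithelial gene set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

#: Roadmap 15-state core-model mnemonics, active TSS -> quiescent.
ROADMAP_15_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: Sentinel label for bins with no segmentation record.
UNANNOTATED = "Unannotated"


class SegmentationError(ValueError):
    """Invalid segmentation input or query."""


class ChromatinSegmentation:
    """Dense per-chromosome state labels on a fixed bin grid.

    Bins without a record carry the :data:`UNANNOTATED` sentinel
    (state index -1).
    """

    def __init__(
        self,
        bin_size: int = 200,
        states: Sequence[str] = ROADMAP_15_STATES,
    ):
        if bin_size <= 0:
            raise SegmentationError("bin_size must be positive")
        self.bin_size = bin_size
        self.states = tuple(states)
        self._index = {s: i for i, s in enumerate(self.states)}
        self.bins: dict[str, np.ndarray] = {}  # int8/int16 state indices, -1 sentinel

    def set_chromosome(self, chrom: str, state_indices: np.ndarray) -> None:
        self.bins[chrom] = np.asarray(state_indices, dtype=np.int16)

    def add_record(self, chrom: str, start: int, end: int, state: str) -> None:
        if start % self.bin_size or end % self.bin_size:
            raise SegmentationError(
                f"record {chrom}:{start}-{end} is off the {self.bin_size}-bp grid"
            )
        if state not in self._index:
            raise SegmentationError(f"unknown state label {state!r}")
        b0, b1 = start // self.bin_size, end // self.bin_size
        arr = self.bins.get(chrom)
        if arr is None or arr.size < b1:
            grown = np.full(max(b1, 1), -1, dtype=np.int16)
            if arr is not None:
                grown[: arr.size] = arr
            arr = grown
            self.bins[chrom] = arr
        if np.any(arr[b0:b1] != -1):
            raise SegmentationError(
                f"record {chrom}:{start}-{end} overlaps an existing record"
            )
        arr[b0:b1] = self._index[state]

    def state_at(self, chrom: str, pos: int) -> str:
        """State label of the bin containing ``pos``."""
        arr = self.bins.get(chrom)
        if arr is None:
            raise SegmentationError(f"chromosome {chrom!r} absent from segmentation")
        b = pos // self.bin_size
        if b >= arr.size or arr[b] == -1:
            return UNANNOTATED
        return self.states[arr[b]]


def read_segmentation(
    paths: Union[str, Sequence[str]],
    bin_size: int = 200,
    states: Sequence[str] = ROADMAP_15_STATES,
) -> ChromatinSegmentation:
    """Read one or more 4-column BED segmentation files onto one grid.

    Every record must start and end on multiples of ``bin_size`` and
    records must not overlap (across files too).
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    seg = ChromatinSegmentation(bin_size=bin_size, states=states)
    for path in paths:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise SegmentationError(
                        f"{path}: line {lineno}: expected 4 columns"
                    )
                try:
                    seg.add_record(f[0], int(f[1]), int(f[2]), f[3])
                except SegmentationError as exc:
                    raise SegmentationError(f"{path}: line {lineno}: {exc}") from None
    return seg


def write_segmentation(seg: ChromatinSegmentation, path) -> None:
    """Write a segmentation as 4-column BED, merging equal-state runs."""
    with open(path, "w") as fh:
        for chrom in sorted(seg.bins):
            arr = seg.bins[chrom]
            run_start = 0
            for i in range(1, arr.size + 1):
                if i == arr.size or arr[i] != arr[run_start]:
                    if arr[run_start] != -1:
                        fh.write(
                            f"{chrom}\t{run_start * seg.bin_size}\t"
                            f"{i * seg.bin_size}\t{seg.states[arr[run_start]]}\n"
                        )
                    run_start = i


def assign_state(peak, seg: ChromatinSegmentation) -> str:
    """State of the bin containing the peak summit."""
    return seg.state_at(peak.interval.chrom, peak.summit)


@dataclass(frozen=True)
class StateProfile:
    """Per-state peak counts and relative abundance (%) for a peak subset."""

    counts: dict[str, int]
    n_peaks: int
    states: tuple[str, ...]

    @property
    def abundance(self) -> dict[str, float]:
        return {s: 100.0 * c / self.n_peaks for s, c in self.counts.items()}

    @property
    def states_represented(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def to_tsv(self, path) -> None:
        ab = self.abundance
        with open(path, "w") as fh:
            fh.write("state\tcount\tpercent\n")
            for s in self.states:
                if s in self.counts:
                    fh.write(f"{s}\t{self.counts[s]}\t{ab[s]:.6f}\n")


def state_abundance(
    annotated_peaks,
    seg: ChromatinSegmentation,
    feature_filter: Optional[str] = None,
    gene_set=None,
    include_unannotated: bool = False,
) -> StateProfile:
    """Profile chromatin-state abundance of a (filtered) peak collection.

    Peaks may be filtered to one feature class and/or to peaks assigned
    to genes of a set.  Unannotated summit bins are excluded from the
    denominator unless ``include_unannotated``.
    """
    peaks = list(annotated_peaks)
    if feature_filter is not None:
        peaks = [p for p in peaks if p.feature == feature_filter]
        if not peaks:
            raise SegmentationError(
                f"no peaks remain after feature filter {feature_filter!r}"
            )
    if gene_set is not None:
        members = set(gene_set.gene_ids)
        peaks = [p for p in peaks if p.gene_id in members]
        if not peaks:
            raise SegmentationError(
                f"no peaks remain after gene-set filter {gene_set.name!r}"
            )
    labels = [assign_state(p.peak, seg) for p in peaks]
    if not include_unannotated:
        labels = [s for s in labels if s != UNANNOTATED]
        if not labels:
            raise SegmentationError(
                "no peaks remain after excluding unannotated summit bins"
            )
    vocab = seg.states + ((UNANNOTATED,) if include_unannotated else ())
    counts = {s: 0 for s in vocab}
    for s in labels:
        counts[s] += 1
    return StateProfile(counts=counts, n_peaks=len(labels), states=vocab)
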