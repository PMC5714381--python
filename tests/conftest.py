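import numpy as np
import pytest

import peaklink as pl


@pytest.fixture
def toy_bed12(tmp_path):
    """Two coding genes (one per strand) and one non-coding gene on chr1."""
    lines = [
        # geneA: + strand, span [10000,20000), 3 exons, CDS [10600,19400)
        "chr1\t10000\t20000\tgeneA\t0\t+\t10600\t19400\t0\t3\t"
        "1000,800,1200\t0,4000,8800",
        # geneB: - strand, span [40000,48000), 2 exons, CDS [40500,47500)
        "chr1\t40000\t48000\tgeneB\t0\t-\t40500\t47500\t0\t2\t"
        "1000,1000\t0,7000",
        # geneC: non-coding single exon on chr2
        "chr2\t5000\t7000\tgeneC\t0\t+\t5000\t5000\t0\t1\t2000\t0",
        # geneD: + strand with a 4 kb 5'UTR reaching beyond the promoter window
        "chr1\t60000\t70000\tgeneD\t0\t+\t64000\t69000\t0\t2\t"
        "6000,2000\t0,8000",
    ]
    p = tmp_path / "genes.bed12"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def toy_annotation(toy_bed12):
    return pl.read_gene_models(toy_bed12)


@pytest.fixture
def small_genome():
    """A 40-gene single-chromosome synthetic genome (fixed seed)."""
    return pl.generate_genome(pl.GenomeSimParams(n_genes=40, seed=11))


def make_peak(chrom, start, end, summit=None, pileup=0.0, name="p"):
    if summit is None:
        summit = start + (end - start) // 2
    return pl.Peak(
        interval=pl.GenomicInterval(chrom, start, end),
        summit=summit,
        pileup=pileup,
        name=name,
    )


@pytest.fixture
def peak_factory():
    return make_peak


def set_counts(annotation, counts):
    """Build a PeakGeneAssociation with explicit per-gene counts."""
    return pl.PeakGeneAssociation(
        counts=dict(counts), universe=tuple(annotation)
    )


@pytest.fixture
def assoc_factory():
    return set_counts
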