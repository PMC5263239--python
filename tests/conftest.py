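"""Shared construction helpers for the test suite."""

import numpy as np
import pytest

from fpspread.core import CoverageTrack, GeneModel, GenomicInterval, Peak


def gi(start, end, strand=".", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def peak(start, end, name=".", score=None, chrom="chr1"):
    return Peak(gi(start, end, chrom=chrom), name=name, score=score)


def gene(start, end, strand, gene_id="g", isoform_id=None, chrom="chr1"):
    return GeneModel(
        gene_id=gene_id,
        isoform_id=isoform_id or f"{gene_id}.1",
        interval=gi(start, end, strand, chrom=chrom),
    )


def track(values, bin_size=1, total_reads=None, chrom="chr1", normalized=False):
    arr = np.asarray(values, dtype=float)
    if total_reads is None:
        total_reads = float(arr.sum())
    return CoverageTrack(
        data={chrom: arr}, bin_size=bin_size, total_reads=total_reads, normalized=normalized
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
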