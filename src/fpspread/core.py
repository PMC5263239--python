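"""Core genomic domain types and interval arithmetic.

All coordinates are 0-based, half-open (BED convention) on named sequences.
GTF input is shifted to this convention at read time; nothing downstream
ever sees 1-based coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class Peak:
    """A called region with an optional summed normalized signal.

    ``score`` is in tags per bp per 10^7 reads summed over the peak when set.
    """

    interval: GenomicInterval
    name: str = "."
    score: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class GeneModel:
    """One transcript isoform with strand-aware TSS/TES.

    The TSS/TES are single-bp positions inside [start, end): for a plus-strand
    isoform tss = start and tes = end - 1; for minus strand tss = end - 1 and
    tes = start. "Into the gene body" always means in the direction of
    transcription.
    """

    gene_id: str
    isoform_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(
                f"gene model {self.isoform_id} requires explicit strand +/-, "
                f"got {self.interval.strand!r}"
            )
        if self.interval.width < 2:
            raise ValueError("gene model needs width >= 2 so tss != tes")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass
class CoverageTrack:
    """Binned read counts per chromosome.

    ``data`` maps chromosome name to a 1-D array; bin i covers
    [i * bin_size, (i + 1) * bin_size). Values are raw read counts until
    :func:`fpspread.signals.normalize_track` converts them to
    tags per bp per 10^7 reads and sets ``normalized``.
    """

    data: dict[str, np.ndarray]
    bin_size: int
    total_reads: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative bin values on {chrom}")
            self.data[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; intervals on different chromosomes never overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _sector_label(names: Iterable[str]) -> str:
    return "&".join(sorted(names))


def build_peak_trees(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)
    return trees


def overlap_venn(
    peak_sets: Mapping[str, Sequence[Peak]],
    min_frac: float = 0.0,
) -> tuple[dict[str, Counter], list[dict]]:
    """Label every region of every set with the subset of sets it overlaps.

    Returns ``(sector_counts, memberships)`` where ``sector_counts[name]`` is
    a Counter of sector label -> number of regions of set *name* in that
    sector (each set's own perspective: peak-count Venns per assay), and
    ``memberships`` is one record per region with its sector label.

    A region counts as overlapping another set if some region of that set
    overlaps it by at least 1 bp and by at least ``min_frac`` of the region's
    own width.
    """
    if len(peak_sets) < 2:
        raise ValueError("overlap_venn needs at least 2 peak sets")
    trees = {name: build_peak_trees(peaks) for name, peaks in peak_sets.items()}

    sector_counts: dict[str, Counter] = {name: Counter() for name in peak_sets}
    memberships: list[dict] = []
    for name, peaks in peak_sets.items():
        for p in peaks:
            hit_sets = [name]
            for other, other_trees in trees.items():
                if other == name:
                    continue
                tree = other_trees.get(p.chrom)
                if tree is None:
                    continue
                best = 0
                for iv in tree.overlap(p.start, p.end):
                    best = max(best, min(iv.end, p.end) - max(iv.begin, p.start))
                if best >= 1 and best >= min_frac * p.width:
                    hit_sets.append(other)
            label = _sector_label(hit_sets)
            sector_counts[name][label] += 1
            memberships.append(
                {
                    "set": name,
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "name": p.name,
                    "sector": label,
                }
            )
    return sector_counts, memberships
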