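"""Coverage normalization, anchored signal matrices, composite profiles.

Signal is expressed in tags per bp per 10^7 reads throughout: raw bin
counts v become v / bin_size / total_reads * 1e7. Matrices are strand
aware — minus-strand rows are flipped so transcription always runs left to
right — and rows can be ordered by an arbitrary key such as spreading
length, which reproduces the characteristic wedge of length-sorted
spreading heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak

NORM_DENOM = 1e7


@dataclass
class SignalMatrix:
    regions: list
    values: np.ndarray  # regions x bins, tags per bp per 1e7 reads
    bin_size: float
    offsets: np.ndarray  # bp offset of each column's left edge from the anchor
    order_key: np.ndarray | None = None


def normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Convert raw bin counts to tags per bp per 10^7 reads."""
    if track.normalized:
        return track
    if track.total_reads <= 0:
        raise ValueError("cannot normalize a track with total_reads <= 0")
    factor = NORM_DENOM / (track.bin_size * track.total_reads)
    data = {chrom: arr * factor for chrom, arr in track.data.items()}
    return CoverageTrack(
        data=data, bin_size=track.bin_size, total_reads=track.total_reads, normalized=True
    )


def per_bp_values(track: CoverageTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-bp signal over [start, end); positions outside the track are 0."""
    n = end - start
    out = np.zeros(n)
    arr = track.data.get(chrom)
    if arr is None:
        return out
    length = len(arr) * track.bin_size
    lo, hi = max(start, 0), min(end, length)
    if lo >= hi:
        if start < 0 or end > length:
            warnings.warn(f"region [{start},{end}) beyond {chrom} bounds; zero-padded", stacklevel=2)
        return out
    expanded = np.repeat(arr[lo // track.bin_size : -(-hi // track.bin_size)], track.bin_size)
    offset = lo - (lo // track.bin_size) * track.bin_size
    out[lo - start : hi - start] = expanded[offset : offset + (hi - lo)]
    if start < 0 or end > length:
        warnings.warn(f"region [{start},{end}) beyond {chrom} bounds; zero-padded", stacklevel=2)
    return out


def peak_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Summed normalized per-bp signal over an interval."""
    if not track.normalized:
        track = normalize_track(track)
    return float(per_bp_values(track, interval.chrom, interval.start, interval.end).sum())


def _anchor_of(region, anchor: str) -> tuple[str, int, str]:
    if anchor == "tss":
        if not isinstance(region, GeneModel):
            raise ValueError("anchor='tss' requires GeneModel regions")
        return region.chrom, region.tss, region.strand
    iv = region.interval if hasattr(region, "interval") else region
    strand = iv.strand
    if anchor == "center":
        return iv.chrom, (iv.start + iv.end) // 2, strand
    if anchor == "start":
        pos = iv.start if strand != "-" else iv.end - 1
        return iv.chrom, pos, strand
    raise ValueError(f"unknown anchor {anchor!r}")


def region_matrix(
    track: CoverageTrack,
    regions: Sequence,
    window: int = 5000,
    n_bins: int = 100,
    anchor: str = "center",
    order_key: Sequence[float] | None = None,
) -> SignalMatrix:
    """Anchored region x bin matrix of normalized signal.

    Each row covers [anchor - window, anchor + window) averaged into
    ``n_bins`` equal bins; minus-strand rows are reversed. When
    ``order_key`` is given rows are sorted by it, descending.
    """
    if (2 * window) % n_bins:
        raise ValueError("2 * window must be divisible by n_bins")
    if not track.normalized:
        track = normalize_track(track)
    bin_bp = 2 * window // n_bins
    rows = []
    for region in regions:
        chrom, pos, strand = _anchor_of(region, anchor)
        vals = per_bp_values(track, chrom, pos - window, pos + window)
        row = vals.reshape(n_bins, bin_bp).mean(axis=1)
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    values = np.array(rows) if rows else np.zeros((0, n_bins))
    offsets = np.arange(n_bins) * bin_bp - window
    key_arr = None
    region_list = list(regions)
    if order_key is not None:
        key_arr = np.asarray(order_key, dtype=float)
        order = np.argsort(-key_arr, kind="stable")
        values = values[order]
        key_arr = key_arr[order]
        region_list = [region_list[i] for i in order]
    return SignalMatrix(
        regions=region_list, values=values, bin_size=bin_bp, offsets=offsets, order_key=key_arr
    )


def composite_profile(
    track: CoverageTrack,
    gene_groups: dict[str, Sequence[GeneModel]],
    window: int = 5000,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Per-group mean TSS-anchored signal, tidy long format (group, offset, mean)."""
    records = []
    for group, genes in gene_groups.items():
        if len(genes) == 0:
            warnings.warn(f"composite_profile: empty group {group!r} omitted", stacklevel=2)
            continue
        mat = region_matrix(track, list(genes), window=window, n_bins=n_bins, anchor="tss")
        means = mat.values.mean(axis=0)
        for off, m in zip(mat.offsets, means):
            records.append({"group": group, "offset": int(off), "mean": m})
    return pd.DataFrame(records, columns=["group", "offset", "mean"])


def peak_signal_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    peaks: Sequence[Peak],
    log_transform: bool = True,
) -> float:
    """Squared Pearson correlation of per-peak summed signal between two tracks.

    By default the correlation is computed on log2(signal + 1); ChIP signal
    is heavy-tailed and logging is the standard stabilizer. Returns NaN when
    either per-peak vector has zero variance.
    """
    if len(peaks) < 3:
        raise ValueError("need >= 3 peaks for a correlation")
    track_a = track_a if track_a.normalized else normalize_track(track_a)
    track_b = track_b if track_b.normalized else normalize_track(track_b)
    x = np.array([peak_signal(track_a, p.interval) for p in peaks])
    y = np.array([peak_signal(track_b, p.interval) for p in peaks])
    if log_transform:
        x = np.log2(x + 1)
        y = np.log2(y + 1)
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def matrix_to_table(matrix: SignalMatrix, ids: Sequence[str] | None = None) -> pd.DataFrame:
    cols = {f"offset_{int(o)}": matrix.values[:, j] for j, o in enumerate(matrix.offsets)}
    df = pd.DataFrame(cols)
    if ids is not None:
        df.insert(0, "region", list(ids))
    if matrix.order_key is not None:
        df.insert(1 if ids is not None else 0, "order_key", matrix.order_key)
    return df
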