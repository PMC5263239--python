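"""Super-enhancer stitching and calling, broad-H3K4me3 domains, partitions.

Super-enhancers are called ROSE-style: enhancer peaks within a stitching
distance (default 12.5 kb) are merged — optionally not across promoter
windows — ranked by background-subtracted signal, and cut where the scaled
rank-signal curve has tangent slope 1. Broad domains are the widest
``quantile`` fraction of a peak set. A three-way gene-id partition relates
spreading targets to both domain classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak

DEFAULT_STITCH_DISTANCE = 12500
DEFAULT_TSS_EXCLUSION = 2500


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: list[Peak]
    signal: float = 0.0
    rank: int | None = None  # 1 = strongest
    is_super: bool = False


@dataclass
class BroadDomainSet:
    peaks: list[Peak]  # ranked by width, descending
    width_cutoff: float
    quantile: float
    selected: list[Peak]


def _tss_windows(genes: Sequence[GeneModel] | None, pad: int) -> dict[str, np.ndarray]:
    """Per-chromosome sorted array of [tss - pad, tss + pad + 1) windows."""
    wins: dict[str, list[tuple[int, int]]] = {}
    for g in genes or []:
        wins.setdefault(g.chrom, []).append((max(0, g.tss - pad), g.tss + pad + 1))
    return {c: np.array(sorted(v)) for c, v in wins.items()}


def _gap_blocked(chrom: str, gap_start: int, gap_end: int, wins: dict[str, np.ndarray]) -> bool:
    arr = wins.get(chrom)
    if arr is None or gap_end <= gap_start:
        return False
    return bool(np.any((arr[:, 0] < gap_end) & (arr[:, 1] > gap_start)))


def stitch_enhancers(
    peaks: Sequence[Peak],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
    genes: Sequence[GeneModel] | None = None,
) -> list[StitchedEnhancer]:
    """Merge peaks whose gaps are <= stitch_distance into stitched enhancers.

    When ``genes`` is given, two peaks are not merged if the gap between
    them overlaps a +/- ``tss_exclusion`` window around any TSS (merging is
    not performed across promoters). Overlapping peaks always merge.
    """
    wins = _tss_windows(genes, tss_exclusion) if genes is not None else {}
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    stitched: list[StitchedEnhancer] = []
    current: list[Peak] = []
    cur_end = None
    for p in ordered:
        if current and p.chrom == current[0].chrom:
            gap_start, gap_end = cur_end, p.start
            mergeable = p.start - cur_end <= stitch_distance and not (
                p.start > cur_end and _gap_blocked(p.chrom, gap_start, gap_end, wins)
            )
        else:
            mergeable = False
        if mergeable:
            current.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if current:
                stitched.append(_finish(current, cur_end))
            current = [p]
            cur_end = p.end
    if current:
        stitched.append(_finish(current, cur_end))
    return stitched


def _finish(constituents: list[Peak], end: int) -> StitchedEnhancer:
    start = min(p.start for p in constituents)
    return StitchedEnhancer(
        interval=GenomicInterval(constituents[0].chrom, start, end),
        constituents=list(constituents),
    )


def rank_signal_cutoff(signals: np.ndarray) -> float | None:
    """Signal value at the slope-1 tangent point of the scaled rank curve.

    Signals are sorted ascending and both axes scaled to [0, 1]; on a convex
    curve the tangent of slope 1 touches at the point lying farthest below
    the diagonal, which is how the cutoff is located here. Exact ties (e.g.
    a perfectly linear curve, slope 1 everywhere) are broken at the median
    tied rank, so a linear curve cuts at its midpoint. Returns None when the
    curve is degenerate (all signals equal).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return None
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    below = x - y
    ties = np.flatnonzero(np.isclose(below, below.max()))
    idx = int(ties[len(ties) // 2])
    return float(s[idx])


def call_super_enhancers(
    stitched: Sequence[StitchedEnhancer],
    signal_track: CoverageTrack,
    control_track: CoverageTrack | None = None,
) -> list[StitchedEnhancer]:
    """Rank stitched enhancers by signal and flag those above the slope-1 cutoff.

    Signal is the summed normalized track signal over the stitched region,
    minus the control track's when one is provided, clipped at 0.
    """
    from .signals import normalize_track, peak_signal

    signal_track = signal_track if signal_track.normalized else normalize_track(signal_track)
    if control_track is not None and not control_track.normalized:
        control_track = normalize_track(control_track)
    for e in stitched:
        s = peak_signal(signal_track, e.interval)
        if control_track is not None:
            s -= peak_signal(control_track, e.interval)
        e.signal = max(0.0, s)
    signals = np.array([e.signal for e in stitched])
    for rank0, i in enumerate(np.argsort(-signals, kind="stable")):
        stitched[i].rank = rank0 + 1
    if len(stitched) < 3:
        warnings.warn("fewer than 3 stitched enhancers; none called super", stacklevel=2)
        for e in stitched:
            e.is_super = False
        return list(stitched)
    cutoff = rank_signal_cutoff(signals)
    if cutoff is None:
        warnings.warn("degenerate rank-signal curve (all-equal); none called super", stacklevel=2)
        for e in stitched:
            e.is_super = False
        return list(stitched)
    for e in stitched:
        e.is_super = e.signal > cutoff
    return list(stitched)


def broad_domains(peaks: Sequence[Peak], quantile: float = 0.05) -> BroadDomainSet:
    """Select the widest ``quantile`` fraction of peaks (default 5% broadest).

    The width cutoff is the (1 - quantile) empirical quantile of widths;
    ties at the cutoff are all included.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    widths = np.array([p.width for p in peaks], dtype=float)
    if len(widths) == 0:
        return BroadDomainSet(peaks=[], width_cutoff=float("nan"), quantile=quantile, selected=[])
    cutoff = float(np.quantile(widths, 1 - quantile, method="higher"))
    ranked = sorted(peaks, key=lambda p: -p.width)
    selected = [p for p in ranked if p.width >= cutoff]
    if len(selected) == len(peaks):
        warnings.warn("broad-domain tie rule selected every peak (all-equal widths?)", stacklevel=2)
    return BroadDomainSet(peaks=ranked, width_cutoff=cutoff, quantile=quantile, selected=selected)


def assign_region_targets(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = 50000,
) -> set[str]:
    """Gene targets of regions: nearest TSS within max_distance of each region."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    targets: set[str] = set()
    for region in regions:
        candidates = by_chrom.get(region.chrom, [])
        best, best_d = None, None
        for g in candidates:
            d = max(region.start - g.tss, g.tss - (region.end - 1), 0)
            if d <= max_distance and (best_d is None or d < best_d):
                best, best_d = g, d
        if best is not None:
            targets.add(best.gene_id)
    return targets


def three_way_partition(
    spreading_genes: set[str], se_genes: set[str], broad_genes: set[str]
) -> tuple[dict[str, int], pd.DataFrame, float]:
    """Seven-sector Venn of gene-id sets and the spreading-in-broad fraction.

    Returns (sector counts, per-gene membership table, fraction of spreading
    genes that are also broad-domain genes).
    """
    names = {"spreading": spreading_genes, "super_enhancer": se_genes, "broad_h3k4me3": broad_genes}
    union = spreading_genes | se_genes | broad_genes
    rows = []
    sectors: dict[str, int] = {}
    for gene in sorted(union):
        members = sorted(n for n, s in names.items() if gene in s)
        label = "&".join(members)
        sectors[label] = sectors.get(label, 0) + 1
        rows.append({"gene_id": gene, "sector": label})
    frac = (
        len(spreading_genes & broad_genes) / len(spreading_genes) if spreading_genes else float("nan")
    )
    table = pd.DataFrame(rows, columns=["gene_id", "sector"])
    return sectors, table, frac
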