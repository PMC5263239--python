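"""Gene-target assignment and the spreading / non-spreading classification.

A gene isoform is a target of a peak when its single-bp TSS lies inside the
peak. A target peak is *spreading* when it extends strictly more than
``spread_threshold`` bp (default 4 kb) from the TSS into the gene body, in
the direction of transcription, without its downstream edge passing the TES.
Peaks are free to extend any distance upstream of the TSS; only the
gene-body direction is constrained.

The module also characterizes the unmethylated-CpG (uCpG) landscape under
spreading domains: which uCpG intervals lie under the peak, the edge-to-edge
gaps between consecutive ones, and whether the domain edges are bookended by
a uCpG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak, build_peak_trees

DEFAULT_SPREAD_THRESHOLD = 4000
DEFAULT_BOOKEND_TOL = 1000


@dataclass
class SpreadingCall:
    """One (peak, isoform) pair with its spreading verdict.

    ``spreading_length`` is the distance in bp from the TSS to the peak's
    downstream-in-transcription edge (0 for non-targets): ``peak.end - tss``
    on plus strand, ``tss - peak.start`` on minus strand.
    """

    peak: Peak
    gene: GeneModel
    is_target: bool
    is_spreading: bool = False
    spreading_length: int = 0
    exceeds_tes: bool = False


@dataclass
class UcpgLandscape:
    """uCpG intervals under a spreading domain and their spacing."""

    call: SpreadingCall
    ucpg_under: list[GenomicInterval]
    gaps: list[int]
    max_gap: int
    bookended_start: bool
    bookended_end: bool


def assign_gene_targets(peaks: Sequence[Peak], genes: Sequence[GeneModel]) -> list[SpreadingCall]:
    """Emit one SpreadingCall per (peak, isoform) pair whose TSS lies in the peak.

    A peak may target several isoforms and a gene may be hit by several
    peaks; every target pair is emitted.
    """
    trees = build_peak_trees(peaks)
    calls: list[SpreadingCall] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        hits = sorted(tree.at(gene.tss), key=lambda iv: iv.data)
        for iv in hits:
            calls.append(SpreadingCall(peak=peaks[iv.data], gene=gene, is_target=True))
    return calls


def classify_spreading(
    call: SpreadingCall, spread_threshold: int = DEFAULT_SPREAD_THRESHOLD
) -> SpreadingCall:
    """Populate is_spreading per the gene-body extension rule.

    "Over ``spread_threshold``" is strict (> threshold); "without going
    beyond the TES" means the last covered base in the direction of
    transcription is <= TES (plus strand) / the first covered base is >= TES
    (minus strand).
    """
    peak, gene = call.peak, call.gene
    if not call.is_target:
        call.is_spreading = False
        call.spreading_length = 0
        call.exceeds_tes = False
        return call
    if gene.strand == "+":
        call.spreading_length = peak.end - gene.tss
        call.exceeds_tes = peak.end - 1 > gene.tes
    else:
        call.spreading_length = gene.tss - peak.start
        call.exceeds_tes = peak.start < gene.tes
    call.is_spreading = (
        call.spreading_length > spread_threshold and not call.exceeds_tes
    )
    return call


def classify_all(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    spread_threshold: int = DEFAULT_SPREAD_THRESHOLD,
) -> list[SpreadingCall]:
    return [classify_spreading(c, spread_threshold) for c in assign_gene_targets(peaks, genes)]


def keep_isoform_pairs(calls: Sequence[SpreadingCall]) -> list[SpreadingCall]:
    """Collapse isoforms of one gene with identical TSS and TES to one pair.

    Isoforms with distinct TSS coordinates are kept as separate pairs, so a
    peak spreading at two isoforms yields two calls but one unique gene.
    """
    seen: set[tuple] = set()
    kept: list[SpreadingCall] = []
    for c in calls:
        key = (id(c.peak), c.gene.gene_id, c.gene.tss, c.gene.tes)
        if key in seen:
            continue
        seen.add(key)
        kept.append(c)
    return kept


def spreading_summary(calls: Sequence[SpreadingCall]) -> dict:
    """Counts at isoform-pair and unique-gene level, plus fraction spreading."""
    kept = keep_isoform_pairs(calls)
    spreading = [c for c in kept if c.is_spreading]
    n_pairs = len(spreading)
    n_genes = len({c.gene.gene_id for c in spreading})
    n_target_pairs = len(kept)
    n_target_genes = len({c.gene.gene_id for c in kept})
    return {
        "n_target_pairs": n_target_pairs,
        "n_target_genes": n_target_genes,
        "n_spreading_pairs": n_pairs,
        "n_spreading_genes": n_genes,
        "fraction_spreading_pairs": (n_pairs / n_target_pairs) if n_target_pairs else 0.0,
    }


def ucpg_landscape(
    call: SpreadingCall,
    ucpg_regions: Sequence[GenomicInterval],
    bookend_tol: int = DEFAULT_BOOKEND_TOL,
) -> UcpgLandscape:
    """uCpG intervals under a spreading peak, their gaps, and edge bookending.

    Gaps are edge-to-edge distances between consecutive uCpG intervals,
    clipped at 0 for touching/overlapping regions. An edge is bookended when
    some uCpG interval comes within ``bookend_tol`` bp of it.
    """
    peak = call.peak
    under = sorted(
        (u for u in ucpg_regions if u.chrom == peak.chrom and u.start < peak.end and peak.start < u.end),
        key=lambda u: (u.start, u.end),
    )
    if not under:
        warnings.warn(
            f"spreading peak {peak.name} [{peak.start},{peak.end}) has no uCpG under it",
            stacklevel=2,
        )
    gaps = [max(0, nxt.start - prev.end) for prev, nxt in zip(under, under[1:])]
    max_gap = max(gaps) if gaps else 0

    def _edge_distance(edge_pos: int) -> int | None:
        best = None
        for u in under:
            d = max(u.start - edge_pos, edge_pos - (u.end - 1), 0)
            best = d if best is None else min(best, d)
        return best

    d_start = _edge_distance(peak.start)
    d_end = _edge_distance(peak.end - 1)
    return UcpgLandscape(
        call=call,
        ucpg_under=under,
        gaps=gaps,
        max_gap=max_gap,
        bookended_start=d_start is not None and d_start <= bookend_tol,
        bookended_end=d_end is not None and d_end <= bookend_tol,
    )


def split_by_cofactor(
    peaks: Sequence[Peak],
    cofactor_track: CoverageTrack,
    quantile: float = 0.5,
) -> tuple[list[Peak], list[Peak], np.ndarray]:
    """Partition peaks at a quantile of per-peak cofactor signal (default median).

    Returns (high, low, signals): ``high`` holds peaks with signal strictly
    above the split point, ``low`` the rest. Per-peak signal is the summed
    normalized cofactor signal over the peak.
    """
    from .signals import normalize_track, peak_signal

    track = cofactor_track if cofactor_track.normalized else normalize_track(cofactor_track)
    signals = np.array([peak_signal(track, p.interval) for p in peaks])
    if len(signals) == 0:
        return [], [], signals
    threshold = float(np.quantile(signals, quantile))
    high = [p for p, s in zip(peaks, signals) if s > threshold]
    low = [p for p, s in zip(peaks, signals) if s <= threshold]
    if not high:
        warnings.warn("cofactor split produced an empty high set (all-equal signals?)", stacklevel=2)
    return high, low, signals


def calls_to_table(calls: Sequence[SpreadingCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.peak.chrom,
                "start": c.peak.start,
                "end": c.peak.end,
                "peak": c.peak.name,
                "gene_id": c.gene.gene_id,
                "isoform_id": c.gene.isoform_id,
                "strand": c.gene.strand,
                "tss": c.gene.tss,
                "tes": c.gene.tes,
                "spreading_length": c.spreading_length,
                "exceeds_tes": c.exceeds_tes,
                "is_spreading": c.is_spreading,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "peak",
            "gene_id",
            "isoform_id",
            "strand",
            "tss",
            "tes",
            "spreading_length",
            "exceeds_tes",
            "is_spreading",
        ],
    )
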