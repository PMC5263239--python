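"""Synthetic genomes, tracks, count matrices and viability tables.

Every generator is deterministic under its seed and records ground truth
sufficient to compute the expected output of every downstream module:
per-isoform spreading labels with planted domain extents, realized uCpG
gap draws, planted enhancer regimes, per-group differential-response
probabilities and affected-gene identities, and the median-effect
parameters plus interaction multiplier behind each viability table.

The default genome emulates the study-scale geometry at desk scale: one
10 Mb chromosome, 300 genes, ~5% spreading, spreading domains of 4.5-9.5 kb
punctuated by uCpG islands 1-2 kb apart, bookending both domain edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak
from .synergy import DoseResponseModel


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 300
    isoform_rate: float = 0.15
    plus_strand_prob: float = 0.5
    fraction_spreading: float = 0.05
    spreading_length_range: tuple[int, int] = (4500, 9500)
    gene_length_range: tuple[int, int] = (12_000, 25_000)
    intergenic_gap_range: tuple[int, int] = (2_000, 8_000)
    ucpg_gap_range: tuple[int, int] = (1_000, 2_000)
    ucpg_gap_cap: int = 7_000
    ucpg_width_range: tuple[int, int] = (200, 400)
    peak_upstream: int = 300
    nonspreading_extent_range: tuple[int, int] = (500, 3_500)
    fraction_no_peak: float = 0.3
    isoform_tss_offset_range: tuple[int, int] = (200, 1_200)
    n_enhancers: int = 60
    enhancer_super_fraction: float = 0.1
    adversarial: bool = False
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted structure of one synthetic genome."""

    spec: SyntheticGenomeSpec
    genes: list[GeneModel]
    peaks: list[Peak]
    ucpg: list[GenomicInterval]
    isoform_labels: pd.DataFrame  # isoform_id, gene_id, has_peak, is_target, is_spreading, ...
    planted_gaps: dict[str, list[int]]  # peak name -> realized uCpG gaps under the domain
    enhancers: list[Peak]
    enhancer_amplitudes: np.ndarray
    enhancer_is_super: np.ndarray
    h3k4me3_peaks: list[Peak]
    cofactor_class: dict[str, str]  # peak name -> "high" | "low"

    @property
    def n_spreading_isoforms(self) -> int:
        return int(self.isoform_labels["is_spreading"].sum())

    @property
    def n_spreading_genes(self) -> int:
        lab = self.isoform_labels
        return lab.loc[lab["is_spreading"], "gene_id"].nunique()


def _literal_spreading_label(
    peak_start: int, peak_end: int, strand: str, tss: int, tes: int, threshold: int = 4000
) -> tuple[bool, bool, int, bool]:
    """Literal re-reading of the spreading rule, kept independent of the
    classifier module so round-trip tests compare two implementations."""
    is_target = peak_start <= tss < peak_end
    if not is_target:
        return False, False, 0, False
    if strand == "+":
        length = peak_end - tss
        exceeds = peak_end - 1 > tes
    else:
        length = tss - peak_start
        exceeds = peak_start < tes
    return True, (length > threshold and not exceeds), length, exceeds


def _ucpg_chain(
    tss: int,
    domain_start: int,
    domain_end: int,
    strand: str,
    rng: np.random.Generator,
    gap_range: tuple[int, int],
    width_range: tuple[int, int],
) -> tuple[list[tuple[int, int]], list[int]]:
    """Chain of uCpG islands from the promoter to the domain's downstream
    edge, bookending both edges; returns (islands, realized gaps)."""
    g_lo, g_hi = gap_range
    w_lo, w_hi = width_range
    w0 = int(rng.integers(w_lo, w_hi + 1))
    islands = [(tss - w0 // 2, tss + w0 - w0 // 2)]
    if strand == "+":
        prev_end = islands[0][1]
        while True:
            g = int(rng.integers(g_lo, g_hi + 1))
            w = int(rng.integers(w_lo, w_hi + 1))
            if prev_end + g + w > domain_end - 1200:
                break
            islands.append((prev_end + g, prev_end + g + w))
            prev_end = prev_end + g + w
        wf = int(rng.integers(w_lo, w_hi + 1))
        islands.append((domain_end - wf, domain_end))
    else:
        prev_start = islands[0][0]
        while True:
            g = int(rng.integers(g_lo, g_hi + 1))
            w = int(rng.integers(w_lo, w_hi + 1))
            if prev_start - g - w < domain_start + 1200:
                break
            islands.append((prev_start - g - w, prev_start - g))
            prev_start = prev_start - g - w
        wf = int(rng.integers(w_lo, w_hi + 1))
        islands.append((domain_start, domain_start + wf))
    islands = sorted(islands)
    gaps = [max(0, nxt[0] - prev[1]) for prev, nxt in zip(islands, islands[1:])]
    return islands, gaps


def simulate_genome(spec: SyntheticGenomeSpec) -> GroundTruth:
    """Plant non-overlapping genes, fusion-protein peaks and uCpG islands.

    Spreading genes get a peak extending a drawn length into the gene body
    with a chained uCpG landscape bookending both domain edges;
    non-spreading target genes get a promoter-restricted peak and a promoter
    uCpG only. Planted geometry respects the classification rule with >= 1
    bp margin except in adversarial mode, which appends exact boundary
    configurations (length exactly at threshold, peak edge exactly at TES).
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[GeneModel] = []
    peaks: list[Peak] = []
    ucpg: list[GenomicInterval] = []
    label_rows: list[dict] = []
    planted_gaps: dict[str, list[int]] = {}
    cofactor_class: dict[str, str] = {}
    h3k4me3_peaks: list[Peak] = []

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    per_chrom = -(-spec.n_genes // spec.n_chromosomes)
    gene_counter = 0

    for chrom in chrom_names:
        cursor = int(rng.integers(*spec.intergenic_gap_range)) + 2000
        for _ in range(per_chrom):
            if gene_counter >= spec.n_genes:
                break
            length = int(rng.integers(*spec.gene_length_range))
            if cursor + length + 3000 > spec.chrom_length:
                raise ValueError(
                    f"genes do not fit on {chrom} ({spec.chrom_length} bp): reduce n_genes "
                    f"below ~{spec.chrom_length // (spec.gene_length_range[1] + spec.intergenic_gap_range[1])} "
                    "per chromosome or shorten genes"
                )
            strand = "+" if rng.random() < spec.plus_strand_prob else "-"
            gene_id = f"G{gene_counter:04d}"
            gs, ge = cursor, cursor + length
            iv = GenomicInterval(chrom, gs, ge, strand)
            gene = GeneModel(gene_id=gene_id, isoform_id=f"{gene_id}.1", interval=iv)
            isoforms = [gene]
            if rng.random() < spec.isoform_rate:
                off = int(
                    rng.integers(
                        spec.isoform_tss_offset_range[0],
                        max(spec.isoform_tss_offset_range[0] + 2, spec.isoform_tss_offset_range[1]),
                    )
                )
                if strand == "+":
                    iv2 = GenomicInterval(chrom, gs + off, ge, strand)
                else:
                    iv2 = GenomicInterval(chrom, gs, ge - off, strand)
                isoforms.append(GeneModel(gene_id=gene_id, isoform_id=f"{gene_id}.2", interval=iv2))
            genes.extend(isoforms)

            u = rng.random()
            is_spreading_gene = u < spec.fraction_spreading
            has_peak = is_spreading_gene or u < 1 - spec.fraction_no_peak
            peak = None
            if is_spreading_gene:
                l_hi = min(spec.spreading_length_range[1], length - 1000)
                spread_len = int(rng.integers(spec.spreading_length_range[0], l_hi + 1))
                # a second isoform's TSS must stay > threshold + margin from the edge
                if len(isoforms) > 1:
                    off = abs(isoforms[1].tss - gene.tss)
                    spread_len = max(spread_len, off + 4101)
                if gene.strand == "+":
                    peak = Peak(
                        GenomicInterval(chrom, gene.tss - spec.peak_upstream, gene.tss + spread_len),
                        name=f"peak_{gene_id}",
                    )
                    islands, gaps = _ucpg_chain(
                        gene.tss, peak.start, peak.end, "+", rng,
                        spec.ucpg_gap_range, spec.ucpg_width_range,
                    )
                else:
                    peak = Peak(
                        GenomicInterval(chrom, gene.tss - spread_len, gene.tss + spec.peak_upstream + 1),
                        name=f"peak_{gene_id}",
                    )
                    islands, gaps = _ucpg_chain(
                        gene.tss, peak.start, peak.end, "-", rng,
                        spec.ucpg_gap_range, spec.ucpg_width_range,
                    )
                ucpg.extend(GenomicInterval(chrom, a, b) for a, b in islands)
                planted_gaps[peak.name] = gaps
                cofactor_class[peak.name] = "high"
                h3k4me3_width = int(rng.integers(6000, 10_001))
            elif has_peak:
                extent = int(rng.integers(*spec.nonspreading_extent_range))
                if gene.strand == "+":
                    peak = Peak(
                        GenomicInterval(chrom, gene.tss - spec.peak_upstream, gene.tss + extent),
                        name=f"peak_{gene_id}",
                    )
                else:
                    peak = Peak(
                        GenomicInterval(chrom, gene.tss - extent, gene.tss + spec.peak_upstream + 1),
                        name=f"peak_{gene_id}",
                    )
                w0 = int(rng.integers(*spec.ucpg_width_range))
                ucpg.append(GenomicInterval(chrom, gene.tss - w0 // 2, gene.tss + w0 - w0 // 2))
                cofactor_class[peak.name] = "high" if rng.random() < 0.5 else "low"
                h3k4me3_width = int(rng.integers(500, 3_001))
            if peak is not None:
                peaks.append(peak)
                h3k4me3_peaks.append(
                    Peak(
                        GenomicInterval(
                            chrom,
                            max(0, gene.tss - h3k4me3_width // 2),
                            gene.tss + h3k4me3_width - h3k4me3_width // 2,
                        ),
                        name=f"k4_{gene_id}",
                    )
                )
            for iso in isoforms:
                if peak is None:
                    label_rows.append(
                        {
                            "isoform_id": iso.isoform_id,
                            "gene_id": gene_id,
                            "has_peak": False,
                            "is_target": False,
                            "is_spreading": False,
                            "spreading_length": 0,
                            "exceeds_tes": False,
                        }
                    )
                else:
                    tgt, spr, ln, exc = _literal_spreading_label(
                        peak.start, peak.end, iso.strand, iso.tss, iso.tes
                    )
                    label_rows.append(
                        {
                            "isoform_id": iso.isoform_id,
                            "gene_id": gene_id,
                            "has_peak": True,
                            "is_target": tgt,
                            "is_spreading": spr,
                            "spreading_length": ln,
                            "exceeds_tes": exc,
                        }
                    )
            cursor = ge + int(rng.integers(*spec.intergenic_gap_range))
            gene_counter += 1

    if spec.adversarial:
        genes, peaks, label_rows = _plant_adversarial(
            spec, chrom_names[0], genes, peaks, label_rows
        )

    # intergenic enhancer peaks with a two-regime amplitude distribution
    enhancers: list[Peak] = []
    amp: list[float] = []
    chrom = chrom_names[0]
    occupied_end = max((g.interval.end for g in genes if g.chrom == chrom), default=0)
    region_lo = occupied_end + 20_000
    room = spec.chrom_length - region_lo - 20_000
    step = max(room // max(spec.n_enhancers, 1), 5_000)
    n_super = int(round(spec.n_enhancers * spec.enhancer_super_fraction))
    for i in range(spec.n_enhancers):
        start = region_lo + i * step
        width = int(rng.integers(1_000, 3_001))
        enhancers.append(Peak(GenomicInterval(chrom, start, start + width), name=f"enh_{i:03d}"))
        if i < spec.n_enhancers - n_super:
            amp.append(float(rng.uniform(1.0, 3.0)))
        else:
            amp.append(float(rng.uniform(15.0, 25.0)))
    amp_arr = np.array(amp)
    is_super = np.zeros(spec.n_enhancers, dtype=bool)
    if n_super:
        is_super[np.argsort(amp_arr)[-n_super:]] = True

    labels = pd.DataFrame(
        label_rows,
        columns=[
            "isoform_id",
            "gene_id",
            "has_peak",
            "is_target",
            "is_spreading",
            "spreading_length",
            "exceeds_tes",
        ],
    )
    return GroundTruth(
        spec=spec,
        genes=genes,
        peaks=peaks,
        ucpg=sorted(ucpg, key=lambda u: (u.chrom, u.start)),
        isoform_labels=labels,
        planted_gaps=planted_gaps,
        enhancers=enhancers,
        enhancer_amplitudes=amp_arr,
        enhancer_is_super=is_super,
        h3k4me3_peaks=h3k4me3_peaks,
        cofactor_class=cofactor_class,
    )


def _plant_adversarial(spec, chrom, genes, peaks, label_rows):
    """Boundary configurations that pin the strict-inequality decisions:
    spreading length exactly at the threshold (not spreading), one bp over
    (spreading), peak edge exactly at the TES (spreading) and one bp past
    it (not spreading)."""
    base = max(g.interval.end for g in genes) + 50_000
    cases = [
        ("ADV_LEN_EQ", 4000, 20_000, False),   # length == threshold: not over
        ("ADV_LEN_GT", 4001, 20_000, True),    # one bp over: spreading
        ("ADV_TES_EQ", 6000, 6000, True),      # last base exactly at TES
        ("ADV_TES_GT", 6000, 5999, False),     # one bp beyond TES
    ]
    out_genes, out_peaks, out_rows = list(genes), list(peaks), list(label_rows)
    cursor = base
    for name, spread_len, gene_len, expected in cases:
        iv = GenomicInterval(chrom, cursor, cursor + gene_len, "+")
        gene = GeneModel(gene_id=name, isoform_id=f"{name}.1", interval=iv)
        peak = Peak(
            GenomicInterval(chrom, gene.tss - spec.peak_upstream, gene.tss + spread_len),
            name=f"peak_{name}",
        )
        tgt, spr, ln, exc = _literal_spreading_label(
            peak.start, peak.end, "+", gene.tss, gene.tes
        )
        assert spr == expected, "adversarial geometry mislabeled"
        out_genes.append(gene)
        out_peaks.append(peak)
        out_rows.append(
            {
                "isoform_id": gene.isoform_id,
                "gene_id": name,
                "has_peak": True,
                "is_target": tgt,
                "is_spreading": spr,
                "spreading_length": ln,
                "exceeds_tes": exc,
            }
        )
        cursor += gene_len + 30_000
    return out_genes, out_peaks, out_rows


# ---------------------------------------------------------------------------
# Coverage tracks


def _paint(arr: np.ndarray, start: int, end: int, value: float, bin_size: int) -> None:
    lo = max(0, start // bin_size)
    hi = min(len(arr), -(-end // bin_size))
    if hi > lo:
        arr[lo:hi] += value


def simulate_tracks(
    truth: GroundTruth,
    bin_size: int = 50,
    noise: bool = True,
    seed: int | None = None,
) -> dict[str, CoverageTrack]:
    """Fusion-protein, H3K79me2, H3K36me3, cofactor and enhancer-mark tracks.

    Spreading genes carry a fusion/cofactor plateau over the planted domain,
    elevated H3K79me2 over the same span and a depleted gene-body H3K36me3;
    non-spreading targets carry a promoter-restricted fusion peak and a
    normal 3'-weighted H3K36me3 ramp. Values are expected read counts per
    bin; with ``noise`` each bin is Poisson-sampled.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 7 if seed is None else seed)
    chroms = sorted({g.chrom for g in truth.genes} | {e.chrom for e in truth.enhancers})
    n_bins = {c: -(-spec.chrom_length // bin_size) for c in chroms}

    def blank() -> dict[str, np.ndarray]:
        return {c: np.full(n_bins[c], 0.2) for c in chroms}

    fusion, k79, k36, cof, k27ac = blank(), blank(), blank(), blank(), blank()

    gene_by_peak = {}
    for row in truth.isoform_labels.itertuples():
        gene_by_peak.setdefault(f"peak_{row.gene_id}", row.gene_id)
    primary = {g.isoform_id: g for g in truth.genes}

    spreading_genes = set(
        truth.isoform_labels.loc[truth.isoform_labels["is_spreading"], "gene_id"]
    )
    for peak in truth.peaks:
        gene_id = gene_by_peak.get(peak.name, peak.name.removeprefix("peak_"))
        gene = primary.get(f"{gene_id}.1")
        if gene is None:
            continue
        arr_f = fusion[peak.chrom]
        spreading = gene_id in spreading_genes
        _paint(arr_f, peak.start, peak.end, 8.0, bin_size)
        cof_amp = 20.0 if truth.cofactor_class.get(peak.name) == "high" else 2.0
        _paint(cof[peak.chrom], peak.start, peak.end, cof_amp, bin_size)
        tss, tes = gene.tss, gene.tes
        if gene.strand == "+":
            k79_span = (tss - 1000, peak.end if spreading else tss + 3000)
            body = (min(tss + 2000, tes), tes)
        else:
            k79_span = (peak.start if spreading else tss - 3000, tss + 1000)
            body = (tes, max(tss - 2000, tes))
        _paint(k79[peak.chrom], *k79_span, 6.0 if spreading else 2.0, bin_size)
        if spreading:
            _paint(k36[peak.chrom], min(body), max(body), 0.5, bin_size)
        else:
            lo, hi = min(body), max(body)
            nb = max(1, (hi - lo) // bin_size)
            ramp = np.linspace(1.0, 4.0, nb)
            if gene.strand == "-":
                ramp = ramp[::-1]
            lo_b = max(0, lo // bin_size)
            k36[peak.chrom][lo_b : lo_b + nb] += ramp[: len(k36[peak.chrom]) - lo_b]
    for enh, a in zip(truth.enhancers, truth.enhancer_amplitudes):
        _paint(k27ac[enh.chrom], enh.start, enh.end, a, bin_size)

    tracks = {}
    for name, data in [
        ("fusion", fusion),
        ("h3k79me2", k79),
        ("h3k36me3", k36),
        ("cofactor", cof),
        ("h3k27ac", k27ac),
    ]:
        if noise:
            data = {c: rng.poisson(arr).astype(float) for c, arr in data.items()}
        total = float(sum(arr.sum() for arr in data.values()))
        tracks[name] = CoverageTrack(data=data, bin_size=bin_size, total_reads=total)
    return tracks


# ---------------------------------------------------------------------------
# Count matrices

DEFAULT_DOWN_PROBS = {"spreading": 0.5, "nonspreading": 0.16, "background": 0.23}


def simulate_count_matrix(
    group_sizes: Mapping[str, int],
    down_probs: Mapping[str, float] = DEFAULT_DOWN_PROBS,
    n_reps: int = 4,
    nb_dispersion: float = 0.1,
    mean_log: float = np.log(300.0),
    mean_sigma: float = 1.0,
    down_lfc_range: tuple[float, float] = (1.5, 3.0),
    up_prob: float = 0.05,
    up_lfc_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """Negative-binomial control/treated counts with planted group effects.

    Each gene of group g is downregulated in the treated condition with
    probability ``down_probs[g]`` (log2 fold change drawn from
    ``down_lfc_range``, i.e. 3- to 8-fold down by default) or upregulated
    with probability ``up_prob``. Returns (counts, gene groups, per-gene
    truth with planted log2 fold changes).
    """
    rng = np.random.default_rng(seed)
    gene_ids, groups, rows = [], {}, []
    lfcs = []
    for gname, size in group_sizes.items():
        p_down = down_probs.get(gname, 0.0)
        ids = [f"{gname}_{i:05d}" for i in range(size)]
        groups[gname] = set(ids)
        gene_ids.extend(ids)
        u = rng.random(size)
        down = u < p_down
        up = (u >= p_down) & (u < p_down + up_prob)
        lfc = np.zeros(size)
        lfc[down] = -rng.uniform(*down_lfc_range, size=int(down.sum()))
        lfc[up] = rng.uniform(*up_lfc_range, size=int(up.sum()))
        lfcs.append(lfc)
        rows.extend({"gene_id": g, "group": gname} for g in ids)
    lfc = np.concatenate(lfcs) if lfcs else np.zeros(0)
    n_genes = len(gene_ids)
    base = rng.lognormal(mean_log, mean_sigma, size=n_genes)

    def draw(mu: np.ndarray) -> np.ndarray:
        if nb_dispersion <= 1e-12:
            return rng.poisson(mu)
        n = 1.0 / nb_dispersion
        return rng.negative_binomial(n, n / (n + mu))

    cols = {}
    for r in range(n_reps):
        cols[f"ctrl_{r + 1}"] = draw(base)
    treated_mu = base * 2.0**lfc
    for r in range(n_reps):
        cols[f"trt_{r + 1}"] = draw(treated_mu)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(rows).set_index("gene_id")
    truth["planted_log2fc"] = lfc
    truth["base_mean"] = base
    return counts, groups, truth


def simulate_counts(
    truth: GroundTruth,
    n_reps: int = 4,
    nb_dispersion: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """Count matrix keyed to a synthetic genome's gene groups.

    Groups: spreading targets, non-spreading targets, background (genes
    without a fusion peak, standing in for other expressed genes).
    """
    lab = truth.isoform_labels
    per_gene = lab.groupby("gene_id").agg(
        is_spreading=("is_spreading", "any"), is_target=("is_target", "any")
    )
    spreading = set(per_gene.index[per_gene["is_spreading"]])
    nonspread = set(per_gene.index[per_gene["is_target"] & ~per_gene["is_spreading"]])
    background = set(per_gene.index) - spreading - nonspread
    sizes = {"spreading": len(spreading), "nonspreading": len(nonspread), "background": len(background)}
    counts, _, gene_truth = simulate_count_matrix(
        sizes, n_reps=n_reps, nb_dispersion=nb_dispersion, seed=seed, **kwargs
    )
    # map synthetic ids onto the genome's gene ids, preserving group identity
    mapping = {}
    for gname, members in [
        ("spreading", sorted(spreading)),
        ("nonspreading", sorted(nonspread)),
        ("background", sorted(background)),
    ]:
        for i, gid in enumerate(members):
            mapping[f"{gname}_{i:05d}"] = gid
    counts.index = [mapping[g] for g in counts.index]
    counts.index.name = "gene_id"
    gene_truth.index = [mapping[g] for g in gene_truth.index]
    gene_truth.index.name = "gene_id"
    groups = {"spreading": spreading, "nonspreading": nonspread, "background": background}
    return counts, groups, gene_truth


# ---------------------------------------------------------------------------
# Dose-response viability tables

DEFAULT_DOSES_A = (320.0, 160.0, 80.0, 40.0, 20.0, 10.0, 5.0)


def loewe_combo_fa(
    model_a: DoseResponseModel,
    model_b: DoseResponseModel,
    d1: float,
    d2: float,
    interaction: float = 1.0,
) -> float:
    """Affected fraction of the combination (d1, d2) on a Loewe surface.

    Solves d1/Dx1(fa) + d2/Dx2(fa) = interaction for fa; interaction < 1
    plants synergy (the measured CI at that dose equals ``interaction``).
    """
    if interaction <= 0:
        raise ValueError("interaction multiplier must be positive")

    def f(fa: float) -> float:
        return d1 / model_a.dose_for_fa(fa) + d2 / model_b.dose_for_fa(fa) - interaction

    return float(brentq(f, 1e-12, 1 - 1e-12))


def simulate_viability(
    drug_params: Mapping[str, tuple[float, float]],
    doses_a: Sequence[float] = DEFAULT_DOSES_A,
    ratio: float = 10.0,
    interaction: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-agent + constant-ratio combination viability table.

    ``drug_params`` maps two drug names to (Dm, m). Drug B doses are
    ``ratio`` times drug A's. Viability = 1 - fa plus Gaussian noise,
    clipped at 0. With interaction = 1 the combination series is exactly
    Loewe-additive; an interaction multiplier s plants CI = s at every dose.
    """
    if len(drug_params) != 2:
        raise ValueError("exactly two drugs required")
    (name_a, (dm_a, m_a)), (name_b, (dm_b, m_b)) = list(drug_params.items())
    model_a = DoseResponseModel(dm=dm_a, m=m_a, r_squared=1.0, n_points=0)
    model_b = DoseResponseModel(dm=dm_b, m=m_b, r_squared=1.0, n_points=0)
    rng = np.random.default_rng(seed)
    rows = [{"dose_a": 0.0, "dose_b": 0.0, "viability": 1.0}]
    for d in doses_a:
        rows.append({"dose_a": float(d), "dose_b": 0.0, "viability": 1 - model_a.fa(d)})
        rows.append({"dose_a": 0.0, "dose_b": float(d) * ratio, "viability": 1 - model_b.fa(d * ratio)})
    for d in doses_a:
        fa = loewe_combo_fa(model_a, model_b, float(d), float(d) * ratio, interaction)
        rows.append({"dose_a": float(d), "dose_b": float(d) * ratio, "viability": 1 - fa})
    df = pd.DataFrame(rows, columns=["dose_a", "dose_b", "viability"])
    if noise_sd > 0:
        noise = rng.normal(0, noise_sd, size=len(df))
        noise[0] = 0.0  # keep the vehicle anchor clean
        df["viability"] = np.clip(df["viability"] + noise, 0.0, None)
    return df


# ---------------------------------------------------------------------------
# Serialization


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "spec": asdict(truth.spec),
        "n_spreading_isoforms": truth.n_spreading_isoforms,
        "n_spreading_genes": truth.n_spreading_genes,
        "planted_gaps": truth.planted_gaps,
        "cofactor_class": truth.cofactor_class,
        "enhancer_amplitudes": truth.enhancer_amplitudes.tolist(),
        "enhancer_is_super": truth.enhancer_is_super.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
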