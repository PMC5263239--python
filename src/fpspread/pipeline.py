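"""End-to-end orchestration: simulate or load inputs, run every stage,
write reproducible tab-delimited reports plus a machine-readable manifest.

Given one config (file or dataclass) the pipeline runs spreading ->
signal -> domains -> expression -> synergy and emits the summary tables a
study of fusion-protein spreading reports: target and spreading counts at
isoform and unique-gene level, uCpG landscape statistics, Venn sectors,
composite profiles, super-enhancer/broad-domain partitions, group response
proportions with Fisher and Mann-Whitney statistics, and combination-index
tables. Two runs with the same config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as fio
from .core import Peak, overlap_venn
from .domains import (
    assign_region_targets,
    broad_domains,
    call_super_enhancers,
    stitch_enhancers,
    three_way_partition,
)
from .expression import call_response, group_response_proportions, group_shift_test
from .signals import composite_profile, matrix_to_table, peak_signal_correlation, region_matrix
from .simulate import (
    SyntheticGenomeSpec,
    simulate_counts,
    simulate_genome,
    simulate_tracks,
    simulate_viability,
)
from .spreading import calls_to_table, classify_all, spreading_summary, ucpg_landscape
from .synergy import combo_experiment_report


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    simulate: bool = True
    # input paths; ignored (regenerated) when simulate is true
    peaks_bed: str | None = None
    genes_gtf: str | None = None
    ucpg_bed: str | None = None
    enhancer_bed: str | None = None
    h3k4me3_bed: str | None = None
    fusion_bedgraph: str | None = None
    cofactor_bedgraph: str | None = None
    h3k79me2_bedgraph: str | None = None
    h3k27ac_bedgraph: str | None = None
    counts_tsv: str | None = None
    viability_tsv: str | None = None
    # stage parameters
    bin_size: int = 50
    spread_threshold: int = 4000
    bookend_tol: int = 1000
    stitch_distance: int = 12500
    tss_exclusion: int = 2500
    broad_quantile: float = 0.05
    enhancer_target_distance: int = 50000
    alpha: float = 0.05
    window: int = 5000
    n_bins: int = 100
    n_genes: int = 300

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into config.output_dir.

    Returns the summary dictionary that is also written as summary.tsv.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs_dir = out / "inputs"

    if config.simulate:
        inputs_dir.mkdir(exist_ok=True)
        spec = SyntheticGenomeSpec(seed=config.seed, n_genes=config.n_genes)
        truth = simulate_genome(spec)
        tracks = simulate_tracks(truth, bin_size=config.bin_size)
        counts, groups, _ = simulate_counts(truth, seed=config.seed + 1)
        via_additive = simulate_viability(
            {"drug_a": (50.0, 1.5), "drug_b": (600.0, 2.0)}, interaction=1.0, seed=config.seed + 2
        )
        via_synergy = simulate_viability(
            {"drug_a": (50.0, 1.5), "drug_b": (600.0, 2.0)}, interaction=0.5, seed=config.seed + 3
        )
        genes, peaks, ucpg = truth.genes, truth.peaks, truth.ucpg
        enhancer_peaks, h3k4me3_peaks = truth.enhancers, truth.h3k4me3_peaks
        fio.write_gtf(genes, inputs_dir / "genes.gtf")
        fio.write_bed(peaks, inputs_dir / "peaks.bed")
        fio.write_bed([Peak(u) for u in ucpg], inputs_dir / "ucpg.bed")
        fio.write_bed(enhancer_peaks, inputs_dir / "enhancers.bed")
        fio.write_bed(h3k4me3_peaks, inputs_dir / "h3k4me3.bed")
        for name, track in tracks.items():
            fio.write_bedgraph(track, inputs_dir / f"{name}.bedgraph")
        fio.write_table(counts.reset_index(), inputs_dir / "counts.tsv")
        fio.write_table(via_additive, inputs_dir / "viability_additive.tsv")
        fio.write_table(via_synergy, inputs_dir / "viability_synergy.tsv")
        viability_tables = {"additive": via_additive, "synergy": via_synergy}
    else:
        required = [config.peaks_bed, config.genes_gtf, config.ucpg_bed]
        if any(p is None or not Path(p).exists() for p in required):
            raise FileNotFoundError("peaks_bed, genes_gtf and ucpg_bed are required inputs")
        peaks = fio.read_bed(config.peaks_bed)
        genes = fio.read_gene_models(config.genes_gtf)
        ucpg = fio.read_intervals_bed(config.ucpg_bed)
        tracks = {}
        for name, path in [
            ("fusion", config.fusion_bedgraph),
            ("cofactor", config.cofactor_bedgraph),
            ("h3k79me2", config.h3k79me2_bedgraph),
            ("h3k27ac", config.h3k27ac_bedgraph),
        ]:
            if path is not None:
                tracks[name] = fio.read_bedgraph(path, bin_size=config.bin_size)
        enhancer_peaks = fio.read_bed(config.enhancer_bed) if config.enhancer_bed else []
        h3k4me3_peaks = fio.read_bed(config.h3k4me3_bed) if config.h3k4me3_bed else []
        counts = fio.read_counts(config.counts_tsv) if config.counts_tsv else None
        groups = None
        viability_tables = (
            {"combo": pd.read_csv(config.viability_tsv, sep="\t")} if config.viability_tsv else {}
        )

    summary: dict = {}

    # --- spreading stage -------------------------------------------------
    calls = classify_all(peaks, genes, spread_threshold=config.spread_threshold)
    fio.write_table(calls_to_table(calls), out / "spreading_calls.tsv")
    sp_summary = spreading_summary(calls)
    summary.update({f"spreading_{k}": v for k, v in sp_summary.items()})

    land_rows = []
    for call in calls:
        if not call.is_spreading:
            continue
        land = ucpg_landscape(call, ucpg, bookend_tol=config.bookend_tol)
        land_rows.append(
            {
                "peak": call.peak.name,
                "isoform_id": call.gene.isoform_id,
                "n_ucpg": len(land.ucpg_under),
                "max_gap": land.max_gap,
                "bookended_start": land.bookended_start,
                "bookended_end": land.bookended_end,
            }
        )
    land_df = pd.DataFrame(
        land_rows,
        columns=["peak", "isoform_id", "n_ucpg", "max_gap", "bookended_start", "bookended_end"],
    )
    fio.write_table(land_df, out / "ucpg_landscapes.tsv")
    if len(land_df):
        summary["ucpg_max_gap_bp"] = int(land_df["max_gap"].max())
        summary["ucpg_bookended_fraction"] = float(
            (land_df["bookended_start"] & land_df["bookended_end"]).mean()
        )

    sectors, _ = overlap_venn({"peaks": peaks, "ucpg": [Peak(u) for u in ucpg]})
    venn_rows = [
        {"from_set": name, "sector": sec, "count": cnt}
        for name, counter in sorted(sectors.items())
        for sec, cnt in sorted(counter.items())
    ]
    fio.write_table(pd.DataFrame(venn_rows, columns=["from_set", "sector", "count"]), out / "venn_peaks_ucpg.tsv")

    # --- signal stage ----------------------------------------------------
    if "h3k79me2" in tracks:
        spreading_iso = {c.gene.isoform_id for c in calls if c.is_spreading}
        target_iso = {c.gene.isoform_id for c in calls}
        groups_genes = {
            "spreading": [g for g in genes if g.isoform_id in spreading_iso],
            "nonspreading": [g for g in genes if g.isoform_id in target_iso - spreading_iso],
            "nontarget": [g for g in genes if g.isoform_id not in target_iso],
        }
        profile = composite_profile(
            tracks["h3k79me2"], groups_genes, window=config.window, n_bins=config.n_bins
        )
        fio.write_table(profile, out / "composite_h3k79me2.tsv")
    if "fusion" in tracks:
        sp_calls = [c for c in calls if c.is_spreading]
        if sp_calls:
            mat = region_matrix(
                tracks["fusion"],
                [c.gene for c in sp_calls],
                window=config.window,
                n_bins=config.n_bins,
                anchor="tss",
                order_key=[c.spreading_length for c in sp_calls],
            )
            fio.write_table(
                matrix_to_table(mat, ids=[c.gene.isoform_id for c in sp_calls]),
                out / "spreading_matrix_fusion.tsv",
            )
    if "fusion" in tracks and "cofactor" in tracks and len(peaks) >= 3:
        summary["fusion_cofactor_r2"] = peak_signal_correlation(
            tracks["fusion"], tracks["cofactor"], peaks
        )

    # --- domains stage ---------------------------------------------------
    spreading_gene_ids = {c.gene.gene_id for c in calls if c.is_spreading}
    if enhancer_peaks and "h3k27ac" in tracks:
        stitched = stitch_enhancers(
            enhancer_peaks,
            stitch_distance=config.stitch_distance,
            tss_exclusion=config.tss_exclusion,
            genes=genes,
        )
        stitched = call_super_enhancers(stitched, tracks["h3k27ac"])
        se_rows = [
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "n_constituents": len(e.constituents),
                "signal": e.signal,
                "rank": e.rank,
                "is_super": e.is_super,
            }
            for e in stitched
        ]
        fio.write_table(
            pd.DataFrame(
                se_rows,
                columns=["chrom", "start", "end", "n_constituents", "signal", "rank", "is_super"],
            ),
            out / "stitched_enhancers.tsv",
        )
        se_genes = assign_region_targets(
            [e.interval for e in stitched if e.is_super], genes, config.enhancer_target_distance
        )
        summary["n_super_enhancers"] = sum(e.is_super for e in stitched)
    else:
        se_genes = set()
    if h3k4me3_peaks:
        broad = broad_domains(h3k4me3_peaks, quantile=config.broad_quantile)
        broad_genes = assign_region_targets(
            [p.interval for p in broad.selected], genes, config.enhancer_target_distance
        )
        summary["n_broad_domains"] = len(broad.selected)
    else:
        broad_genes = set()
    sectors3, part_table, frac = three_way_partition(spreading_gene_ids, se_genes, broad_genes)
    fio.write_table(part_table, out / "three_way_partition.tsv")
    fio.write_table(
        pd.DataFrame(sorted(sectors3.items()), columns=["sector", "count"]),
        out / "three_way_sectors.tsv",
    )
    summary["fraction_spreading_in_broad"] = frac

    # --- expression stage ------------------------------------------------
    if counts is not None:
        ctrl = [c for c in counts.columns if c.startswith("ctrl")]
        trt = [c for c in counts.columns if c.startswith("trt")]
        response = call_response(counts, ctrl, trt, alpha=config.alpha)
        fio.write_table(response.reset_index(), out / "expression_response.tsv")
        if groups:
            props, fisher = group_response_proportions(response, groups)
            fio.write_table(props, out / "group_proportions.tsv")
            fio.write_table(fisher, out / "group_fisher.tsv")
            for row in props.itertuples():
                summary[f"frac_down_{row.group}"] = row.frac_down
            down = response[response["status"] == "down"]
            a = down.loc[down.index.intersection(sorted(groups.get("spreading", set()))), "log2_fold_change"]
            b = down.loc[
                down.index.intersection(sorted(groups.get("nonspreading", set()))), "log2_fold_change"
            ]
            if len(a) and len(b):
                shift = group_shift_test(a, b)
                summary["downshift_mw_p"] = shift["pvalue"]

    # --- synergy stage ---------------------------------------------------
    for name, table in viability_tables.items():
        ci_table, ci_summary = combo_experiment_report(table)
        fio.write_table(ci_table, out / f"ci_table_{name}.tsv")
        summary[f"mean_ci_{name}"] = ci_summary["mean_ci"]

    # --- manifest & summary ----------------------------------------------
    manifest = {
        "parameters": dataclasses.asdict(config),
        "input_checksums": {
            p.name: _sha256(p) for p in sorted(inputs_dir.glob("*")) if config.simulate
        }
        if config.simulate
        else {},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    summary_df = pd.DataFrame(
        [{"key": k, "value": _fmt(v)} for k, v in sorted(summary.items())], columns=["key", "value"]
    )
    fio.write_table(summary_df, out / "summary.tsv")
    return summary


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.8g}"
    return str(v)
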