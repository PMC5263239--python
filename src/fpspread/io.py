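"""Readers and writers for BED, BED12, GTF, bedGraph and tab-delimited tables.

All readers emit 0-based half-open coordinates; the GTF reader performs the
1-based -> 0-based shift. Malformed input fails with the offending line
number rather than silently skipping records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GeneModel, GenomicInterval, Peak


class ParseError(ValueError):
    pass


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}, line {lineno}: {msg}")


def read_bed(path) -> list[Peak]:
    """Read BED3/BED6 into Peaks, preserving input order.

    Strand defaults to '.' and score to None when the columns are absent or
    the BED placeholder '.'.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"expected >= 3 tab-separated fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    _fail(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            peaks.append(Peak(iv, name=name, score=score))
    return peaks


def write_bed(peaks: Sequence[Peak], path, extra_columns: pd.DataFrame | None = None) -> None:
    """Write Peaks as BED6 (+ optional extra columns aligned by row)."""
    rows = []
    for p in peaks:
        score = "." if p.score is None else f"{p.score:.6g}"
        rows.append([p.chrom, p.start, p.end, p.name, score, p.interval.strand])
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            cols = [str(x) for x in row]
            if extra_columns is not None:
                cols += [str(x) for x in extra_columns.iloc[i].tolist()]
            fh.write("\t".join(cols) + "\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    return [p.interval for p in read_bed(path)]


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path) -> list[GeneModel]:
    """Read transcript isoforms from GTF or BED12 (chosen by extension).

    Each transcript record becomes one GeneModel; isoforms sharing a gene_id
    are retained separately. Records without an explicit +/- strand are
    rejected because spreading classification is direction-dependent.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _read_bed12_genes(path)
    return _read_gtf_genes(path)


def _read_gtf_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                _fail(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
            if fields[2] != "transcript":
                continue
            chrom = fields[0]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            strand = fields[6]
            if strand not in {"+", "-"}:
                _fail(path, lineno, f"transcript without +/- strand: {strand!r}")
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            if not gene_id or not tx_id:
                _fail(path, lineno, "transcript record missing gene_id/transcript_id")
            try:
                # GTF is 1-based inclusive; shift to 0-based half-open.
                iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            genes.append(GeneModel(gene_id=gene_id, isoform_id=tx_id, interval=iv))
    return genes


def _read_bed12_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                _fail(path, lineno, "BED gene models need >= 6 columns (strand required)")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            if strand not in {"+", "-"}:
                _fail(path, lineno, f"gene record without +/- strand: {strand!r}")
            gene_id = name.split("|")[0] if "|" in name else name
            iv = GenomicInterval(chrom, start, end, strand)
            genes.append(GeneModel(gene_id=gene_id, isoform_id=name, interval=iv))
    return genes


def write_gtf(genes: Sequence[GeneModel], path, source: str = "fpspread") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.isoform_id}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "transcript",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_bedgraph(path, bin_size: int, total_reads: float | None = None) -> CoverageTrack:
    """Read a fixed-bin bedGraph into a CoverageTrack.

    Records must align to the ``bin_size`` grid (the format this package
    writes). ``total_reads`` defaults to the sum of all bin values, i.e. the
    track is assumed to hold raw per-bin read counts.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    maxima: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "bedGraph needs 4 columns")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
            if start % bin_size or end % bin_size:
                _fail(path, lineno, f"record [{start},{end}) not aligned to bin_size {bin_size}")
            bins = per_chrom.setdefault(chrom, {})
            for b in range(start // bin_size, end // bin_size):
                bins[b] = value
            maxima[chrom] = max(maxima.get(chrom, 0), end // bin_size)
    data = {}
    for chrom, bins in per_chrom.items():
        arr = np.zeros(maxima[chrom])
        for b, v in bins.items():
            arr[b] = v
        data[chrom] = arr
    if total_reads is None:
        total_reads = float(sum(arr.sum() for arr in data.values()))
    return CoverageTrack(data=data, bin_size=bin_size, total_reads=total_reads)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a CoverageTrack as bedGraph, run-length merging equal bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            run_start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[run_start]:
                    v = arr[run_start]
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{run_start * track.bin_size}\t{i * track.bin_size}\t{v:.10g}\n"
                        )
                    run_start = i


def read_counts(path) -> pd.DataFrame:
    """Read a tab-delimited count matrix: gene_id column + one column per sample."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
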