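"""Plain-text readers and writers: BED6 promoters, bedMethyl/bedGraph-style
per-site records, Bismark-coverage-style bisulfite tables, event tables and
expression tables as TSV. Coordinates are 0-based, half-open."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import PromoterRecord


class ParseError(ValueError):
    pass


def write_promoters_bed(promoters: list[PromoterRecord], path) -> None:
    """BED6 with name = promoterID|geneSymbol and thickStart-style window
    encoded by the interval itself; the TSS is recoverable from strand."""
    with open(path, "w") as fh:
        for p in promoters:
            lo, hi = p.genomic_bounds()
            fh.write(f"{p.chrom}\t{lo}\t{hi}\t{p.promoter_id}|{p.gene}\t0\t{p.strand}\n")


def read_promoters_bed(path, upstream: int = 1000, downstream: int = 500) -> list[PromoterRecord]:
    """Read promoters back; the TSS is reconstructed from the interval, the
    window sizes, and the strand."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {ln}: expected 6 BED fields, got {len(parts)}")
            chrom, lo, hi, name, _score, strand = parts[:6]
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError as e:
                raise ParseError(f"{path}: line {ln}: non-integer coordinate") from e
            if "|" not in name:
                raise ParseError(f"{path}: line {ln}: name lacks 'promoterID|gene' form")
            if strand not in "+-":
                raise ParseError(f"{path}: line {ln}: bad strand {strand!r}")
            pid, gene = name.split("|", 1)
            tss = lo_i + upstream if strand == "+" else hi_i - 1 - upstream
            out.append(PromoterRecord(pid, gene, chrom, tss, strand, upstream, downstream))
    return out


def write_bedmethyl(records: pd.DataFrame, path) -> None:
    """bedMethyl-style TSV: chrom, start, end, coverage, methylated,
    frequency in percent (half-open single-base intervals)."""
    df = records.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int),
            "end": df["pos"].astype(int) + 1,
            "coverage": df["coverage"].astype(int),
            "methylated": df["methylated"].astype(int),
            "frequency_percent": np.round(df["frequency"] * 100.0, 4),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_bedmethyl(path, platform: str = "nanopore") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),
            "strand": "+",
            "platform": platform,
            "coverage": df["coverage"].astype(int),
            "methylated": df["methylated"].astype(int),
        }
    )
    out["frequency"] = df["frequency_percent"] / 100.0
    return out


def write_bedgraph(records: pd.DataFrame, path) -> None:
    """bedGraph browser track of methylation frequency."""
    df = records.dropna(subset=["frequency"])
    with open(path, "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{int(r.pos)}\t{int(r.pos) + 1}\t{r.frequency:.4f}\n")


def write_bismark_cov(table: pd.DataFrame, path) -> None:
    """Bismark-coverage-style TSV: chrom, start, end, frequency%, methylated,
    unmethylated counts."""
    total = table["total_count"].astype(int)
    meth = table["methylated_count"].astype(int)
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["pos"].astype(int),
            "end": table["pos"].astype(int) + 1,
            "frequency_percent": np.round(100.0 * meth / total, 4),
            "methylated": meth,
            "unmethylated": total - meth,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bismark_cov(path, platform: str = "wgbs") -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "frequency_percent", "methylated", "unmethylated"],
    )
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(int),
            "strand": "+",
            "methylated_count": df["methylated"].astype(int),
            "total_count": (df["methylated"] + df["unmethylated"]).astype(int),
            "platform": platform,
        }
    )


def write_events(events: pd.DataFrame, path) -> None:
    """Event-level nanopore observations as (gzipped, if the path ends in
    .gz) TSV; the gzip mtime is pinned so reruns are byte-identical."""
    compression = (
        {"method": "gzip", "mtime": 0} if str(path).endswith(".gz") else "infer"
    )
    events.to_csv(path, sep="\t", index=False, float_format="%.6f", compression=compression)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
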