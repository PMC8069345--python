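"""Per-read 5mC calling from current events, and per-site frequencies.

For each CpG site on each read, the log-likelihood ratio (natural log)

    LLR = sum over events [ log N(x; mu_M, sd_M) - log N(x; mu_C, sd_C) ]

compares the methylated against the unmethylated 6-mer emission model,
treating the overlapping 6-mer events of one site as independent. Calls are
three-way at a confidence threshold T (default 2.5): methylated if
LLR >= +T, unmethylated if LLR <= -T, otherwise ambiguous. Ambiguous calls
are excluded from both the coverage and the methylated count when per-site
frequencies are aggregated, so frequencies are over confident calls only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .sixmer import SixMerModel

CALL_METH = "methylated"
CALL_UNMETH = "unmethylated"
CALL_AMBIG = "ambiguous"

DEFAULT_LLR_THRESHOLD = 2.5
DEFAULT_MIN_COVERAGE = 5

RECORD_COLUMNS = ["chrom", "pos", "strand", "platform", "coverage", "methylated", "frequency"]


def score_site_llr(events, model: SixMerModel) -> float:
    """LLR of one read-site from its ``(kmer_index, current)`` events."""
    events = list(events)
    if not events:
        raise ValueError("cannot score a site with no events")
    from .sixmer import methylated_variant

    llr = 0.0
    for kmer_index, current in events:
        kmer = model.kmers[kmer_index]
        mkmer = methylated_variant(kmer)
        if mkmer == kmer:
            continue  # no CpG in this 6-mer: identical models, zero contribution
        mu_c, sd_c = model.params(kmer)
        mu_m, sd_m = model.params(mkmer)
        llr += stats.norm.logpdf(current, mu_m, sd_m) - stats.norm.logpdf(current, mu_c, sd_c)
    return float(llr)


def call_site(llr: float, threshold: float = DEFAULT_LLR_THRESHOLD) -> str:
    """Three-way call; the threshold is inclusive on both sides."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if llr >= threshold:
        return CALL_METH
    if llr <= -threshold:
        return CALL_UNMETH
    return CALL_AMBIG


def call_reads(
    events: pd.DataFrame, model: SixMerModel, threshold: float = DEFAULT_LLR_THRESHOLD
) -> pd.DataFrame:
    """Vectorised per-read-site calls over a long event table.

    ``events`` has columns read_id, chrom, pos, kmer_index, current. Returns
    one row per (read_id, chrom, pos) with llr and call.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if events.empty:
        return pd.DataFrame(columns=["read_id", "chrom", "pos", "llr", "call"])
    mu_c, sd_c, mu_m, sd_m = model.param_arrays()
    k = events["kmer_index"].to_numpy()
    if k.min() < 0 or k.max() >= len(model.kmers):
        raise KeyError(f"event kmer_index out of range for this model (index {int(k.max())})")
    x = events["current"].to_numpy(dtype=float)
    contrib = (
        -0.5 * ((x - mu_m[k]) / sd_m[k]) ** 2
        - np.log(sd_m[k])
        + 0.5 * ((x - mu_c[k]) / sd_c[k]) ** 2
        + np.log(sd_c[k])
    )
    df = events[["read_id", "chrom", "pos"]].copy()
    df["contrib"] = contrib
    out = df.groupby(["read_id", "chrom", "pos"], as_index=False, sort=False)["contrib"].sum()
    out = out.rename(columns={"contrib": "llr"})
    out["call"] = np.select(
        [out["llr"] >= threshold, out["llr"] <= -threshold],
        [CALL_METH, CALL_UNMETH],
        default=CALL_AMBIG,
    )
    return out


def aggregate_nanopore_frequency(calls: pd.DataFrame, strand: str = "+") -> pd.DataFrame:
    """Per-site records from per-read calls.

    coverage counts confident (non-ambiguous) calls only; a site where every
    read was ambiguous is kept with coverage 0 and undefined frequency so
    promoter coverage accounting stays explicit.
    """
    if calls.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    tmp = calls[["chrom", "pos"]].copy()
    tmp["confident"] = (calls["call"] != CALL_AMBIG).astype(int)
    tmp["meth"] = (calls["call"] == CALL_METH).astype(int)
    agg = tmp.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    out = agg.rename(columns={"confident": "coverage", "meth": "methylated"})
    out["strand"] = strand
    out["platform"] = "nanopore"
    with np.errstate(invalid="ignore", divide="ignore"):
        out["frequency"] = np.where(
            out["coverage"] > 0, out["methylated"] / out["coverage"], np.nan
        )
    return out[RECORD_COLUMNS]


def bisulfite_frequency(
    table: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Per-site records from a bisulfite count table; sites covered by fewer
    than ``min_coverage`` reads are dropped (no call is made for them)."""
    if (table["methylated_count"] > table["total_count"]).any():
        raise ValueError("methylated_count exceeds total_count")
    keep = table[table["total_count"] >= min_coverage]
    out = pd.DataFrame(
        {
            "chrom": keep["chrom"].to_numpy(),
            "pos": keep["pos"].to_numpy(),
            "strand": keep.get("strand", pd.Series("+", index=keep.index)).to_numpy(),
            "platform": keep.get("platform", pd.Series("wgbs", index=keep.index)).to_numpy(),
            "coverage": keep["total_count"].to_numpy(),
            "methylated": keep["methylated_count"].to_numpy(),
        }
    )
    out["frequency"] = out["methylated"] / out["coverage"]
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def platform_spearman(
    a: pd.DataFrame, b: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> float:
    """Spearman rank correlation (average ranks on ties) of per-site
    frequencies across the sites present in both record sets after the
    coverage filter."""
    fa = a[a["coverage"] >= min_coverage][["chrom", "pos", "frequency"]]
    fb = b[b["coverage"] >= min_coverage][["chrom", "pos", "frequency"]]
    merged = fa.merge(fb, on=["chrom", "pos"], suffixes=("_a", "_b")).dropna()
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared sites after coverage filtering; need at least 3"
        )
    rho, _ = stats.spearmanr(merged["frequency_a"], merged["frequency_b"])
    return float(rho)
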