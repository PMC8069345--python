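"""Promoter-level methylation: profiles, k-means classes, gene sets.

CpG records are assigned to strand-aware promoter windows around each TSS,
sites with methylation frequency above 50% are marked hypermethylated, each
promoter is summarised as a binned vector of hypermethylated-site fractions,
and k-means with k=2 separates hyper- from hypomethylated promoters (the
cluster with the larger centroid mean is "hyper"). A gene counts as
hypermethylated when at least one of its promoters does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import PromoterRecord, oriented_offset

HYPER = "hyper"
HYPO = "hypo"

DEFAULT_FREQ_THRESHOLD = 0.5
DEFAULT_N_BINS = 20
DEFAULT_MIN_SITES = 3


def assign_sites_to_promoters(
    records: pd.DataFrame, promoters: list[PromoterRecord]
) -> dict[str, np.ndarray]:
    """Map promoter_id -> integer indices (into ``records``) of the CpG
    records inside the promoter window.

    A record at strand-oriented offset d from the TSS belongs to the window
    iff -upstream <= d < downstream (half-open). A site may belong to more
    than one promoter. Records on chromosomes absent from the annotation are
    skipped with a warning.
    """
    known_chroms = {p.chrom for p in promoters}
    rec_chroms = records["chrom"].to_numpy()
    unknown = set(rec_chroms) - known_chroms
    if unknown:
        warnings.warn(
            f"records on unknown chromosome(s) {sorted(unknown)} skipped", stacklevel=2
        )
    pos = records["pos"].to_numpy()
    idx = np.arange(len(records))
    out: dict[str, np.ndarray] = {}
    for p in promoters:
        d = oriented_offset(pos, p.tss, p.strand)
        mask = (rec_chroms == p.chrom) & (d >= -p.upstream) & (d < p.downstream)
        out[p.promoter_id] = idx[mask]
    return out


def select_hypermethylated_sites(
    records: pd.DataFrame, freq_threshold: float = DEFAULT_FREQ_THRESHOLD
) -> pd.DataFrame:
    """Sites with methylation frequency strictly greater than the threshold
    ("more than 50%" — a site at exactly 50% is excluded)."""
    return records[records["frequency"] > freq_threshold]


@dataclass
class PromoterProfile:
    promoter_id: str
    gene: str
    n_sites: int
    feature: np.ndarray | None  # per-bin hypermethylated-site fraction
    mean_frequency: float
    read_depth: float  # mean confident coverage over covered sites
    classifiable: bool


def build_profiles(
    mapping: dict[str, np.ndarray],
    records: pd.DataFrame,
    promoters: list[PromoterRecord],
    n_bins: int = DEFAULT_N_BINS,
    min_sites: int = DEFAULT_MIN_SITES,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> list[PromoterProfile]:
    """Binned hypermethylation profile per promoter.

    The window is split into ``n_bins`` equal bins of strand-oriented offset;
    feature[b] = hypermethylated / covered sites in bin b. Bins with no
    covered site are imputed with the promoter-wide hypermethylated fraction.
    Promoters with fewer than ``min_sites`` covered sites are flagged
    unclassifiable (feature None).
    """
    by_id = {p.promoter_id: p for p in promoters}
    pos = records["pos"].to_numpy()
    freq = records["frequency"].to_numpy(dtype=float)
    cov = records["coverage"].to_numpy(dtype=float)
    profiles = []
    for pid, rec_idx in mapping.items():
        p = by_id[pid]
        ri = rec_idx[(cov[rec_idx] > 0) & np.isfinite(freq[rec_idx])]
        n = len(ri)
        if n == 0:
            profiles.append(PromoterProfile(pid, p.gene, 0, None, np.nan, 0.0, False))
            continue
        d = np.asarray(oriented_offset(pos[ri], p.tss, p.strand), dtype=float)
        width = p.upstream + p.downstream
        bins = np.clip(((d + p.upstream) / width * n_bins).astype(int), 0, n_bins - 1)
        hyper = freq[ri] > freq_threshold
        overall = float(hyper.mean())
        feature = np.full(n_bins, overall)
        for b in range(n_bins):
            m = bins == b
            if m.any():
                feature[b] = hyper[m].mean()
        profiles.append(
            PromoterProfile(
                pid,
                p.gene,
                n,
                feature,
                float(np.mean(freq[ri])),
                float(np.mean(cov[ri])),
                n >= min_sites,
            )
        )
    return profiles


@dataclass
class PromoterClassification:
    labels: dict[str, str]  # promoter_id -> hyper | hypo (classifiable only)
    centroid_means: dict[str, float]
    degenerate: bool = False


def kmeans_classify(
    profiles: list[PromoterProfile],
    k: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
) -> PromoterClassification:
    """k=2 k-means over classifiable profiles (Euclidean, k-means++ seeding,
    best of ``n_restarts`` by within-cluster sum of squares; deterministic
    for a fixed seed). The cluster whose centroid has the larger mean is
    labelled hyper."""
    if k != 2:
        raise ValueError("exactly two clusters are supported")
    usable = [p for p in profiles if p.classifiable]
    if len(usable) < 2:
        raise ValueError("need at least 2 classifiable promoter profiles")
    X = np.vstack([p.feature for p in usable])
    if np.allclose(X, X[0]):
        warnings.warn(
            "all promoter profiles identical; labelling by mean vs 0.5", stacklevel=2
        )
        label = HYPER if X[0].mean() > 0.5 else HYPO
        return PromoterClassification(
            {p.promoter_id: label for p in usable},
            {label: float(X[0].mean())},
            degenerate=True,
        )
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(X)
    means = km.cluster_centers_.mean(axis=1)
    hyper_cluster = int(np.argmax(means))
    labels = {
        p.promoter_id: (HYPER if a == hyper_cluster else HYPO)
        for p, a in zip(usable, km.labels_)
    }
    return PromoterClassification(
        labels,
        {HYPER: float(means[hyper_cluster]), HYPO: float(means[1 - hyper_cluster])},
    )


def collapse_to_genes(
    classification: PromoterClassification, promoters: list[PromoterRecord]
) -> tuple[set[str], int]:
    """(hypermethylated gene set, hypermethylated promoter count): a gene is
    hypermethylated iff at least one of its promoters is labelled hyper."""
    by_id = {p.promoter_id: p for p in promoters}
    hyper_proms = [pid for pid, lab in classification.labels.items() if lab == HYPER]
    genes = {by_id[pid].gene for pid in hyper_proms}
    return genes, len(hyper_proms)


def tss_metaplot(
    records: pd.DataFrame,
    promoters: list[PromoterRecord],
    span: int = 2000,
    n_bins: int = 80,
) -> pd.DataFrame:
    """Mean methylation frequency by strand-oriented distance to the TSS.

    Sites within [-span, +span) of any TSS contribute to the bin of their
    offset (a site near two TSSs contributes to both). Returns bin_center /
    mean_frequency / n_sites; empty bins have NaN mean.
    """
    edges = np.linspace(-span, span, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    pos = records["pos"].to_numpy()
    freq = records["frequency"].to_numpy(dtype=float)
    chroms = records["chrom"].to_numpy()
    ok = np.isfinite(freq)
    for p in promoters:
        d = np.asarray(oriented_offset(pos, p.tss, p.strand), dtype=float)
        mask = ok & (chroms == p.chrom) & (d >= -span) & (d < span)
        if not mask.any():
            continue
        b = np.clip(((d[mask] + span) / (2 * span) * n_bins).astype(int), 0, n_bins - 1)
        np.add.at(sums, b, freq[mask])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_center": centers, "mean_frequency": means, "n_sites": counts})
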