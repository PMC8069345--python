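"""Cross-platform integration of hypermethylated gene sets.

Nanopore reads 5mC directly; bisulfite (WGBS/EPIC) reads the sum of 5mC and
5hmC. Genes hypermethylated by WGBS but not by nanopore are therefore either
under-covered by nanopore or putatively hydroxymethylated: a WGBS-only gene
whose best-covered promoter has at least ``min_reads`` nanopore reads yet a
low nanopore 5mC frequency is flagged putative-5hmC. Genes failing the depth
test are reported as insufficiently covered, not as non-5hmC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genome import PromoterRecord
from .promoters import PromoterProfile

DEFAULT_MIN_READS = 5
DEFAULT_LOW_FREQ = 0.1

REASON_FLAGGED = "putative_5hmC"
REASON_LOW_COVERAGE = "insufficient_coverage"
REASON_METHYLATED = "5mC_detected"


def normalize_symbol(gene: str) -> str:
    return gene.strip().upper()


def normalize_set(genes: Iterable[str]) -> set[str]:
    return {normalize_symbol(g) for g in genes}


@dataclass
class GeneSetComparison:
    nanopore: set[str]
    wgbs: set[str]
    shared: set[str] = field(init=False)
    nanopore_only: set[str] = field(init=False)
    wgbs_only: set[str] = field(init=False)
    overlap_percent: int | None = field(init=False)

    def __post_init__(self) -> None:
        self.shared = self.nanopore & self.wgbs
        self.nanopore_only = self.nanopore - self.wgbs
        self.wgbs_only = self.wgbs - self.nanopore
        # partition identities hold by construction; keep them checked
        assert len(self.nanopore) == len(self.shared) + len(self.nanopore_only)
        assert len(self.wgbs) == len(self.shared) + len(self.wgbs_only)
        if self.nanopore:
            self.overlap_percent = round(100 * len(self.shared) / len(self.nanopore))
        else:
            self.overlap_percent = None

    @property
    def overlap_defined(self) -> bool:
        return self.overlap_percent is not None


def compare_gene_sets(nanopore: Iterable[str], wgbs: Iterable[str]) -> GeneSetComparison:
    """Set algebra between the two platforms' hypermethylated gene sets;
    overlap_percent = 100 * |shared| / |nanopore|, rounded to the nearest
    integer percent (undefined for an empty nanopore set)."""
    return GeneSetComparison(normalize_set(nanopore), normalize_set(wgbs))


def confirm_with_epic(shared: Iterable[str], epic: Iterable[str]) -> set[str]:
    """Genes hypermethylated on both primary platforms that deep targeted
    bisulfite (EPIC) also calls hypermethylated."""
    return normalize_set(shared) & normalize_set(epic)


@dataclass(frozen=True)
class FiveHmcFlag:
    gene: str
    nanopore_read_depth: float
    nanopore_mean_frequency: float
    flagged: bool
    reason: str


def gene_promoter_stats(
    profiles: list[PromoterProfile], promoters: list[PromoterRecord]
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene (nanopore depth, mean 5mC frequency), each taken from the
    gene's maximally covered promoter: one adequately covered promoter
    suffices to interrogate the gene."""
    depths: dict[str, float] = {}
    freqs: dict[str, float] = {}
    for prof in profiles:
        g = normalize_symbol(prof.gene)
        if g not in depths or prof.read_depth > depths[g]:
            depths[g] = prof.read_depth
            freqs[g] = prof.mean_frequency
    return depths, freqs


def flag_putative_5hmc(
    wgbs_only: Iterable[str],
    depths: Mapping[str, float],
    frequencies: Mapping[str, float],
    min_reads: float = DEFAULT_MIN_READS,
    low_freq: float = DEFAULT_LOW_FREQ,
) -> list[FiveHmcFlag]:
    """Flag WGBS-only hypermethylated genes as putatively hydroxymethylated:
    flagged iff nanopore depth >= min_reads AND nanopore mean 5mC frequency
    <= low_freq."""
    out = []
    for gene in sorted(normalize_set(wgbs_only)):
        depth = float(depths.get(gene, 0.0))
        freq = float(frequencies.get(gene, float("nan")))
        if depth < min_reads:
            out.append(FiveHmcFlag(gene, depth, freq, False, REASON_LOW_COVERAGE))
        elif freq <= low_freq:
            out.append(FiveHmcFlag(gene, depth, freq, True, REASON_FLAGGED))
        else:
            out.append(FiveHmcFlag(gene, depth, freq, False, REASON_METHYLATED))
    return out


def membership_table(
    comparison: GeneSetComparison,
    epic: Iterable[str],
    flags: list[FiveHmcFlag],
) -> pd.DataFrame:
    """Three-way membership with partition and 5hmC flag, one row per gene."""
    epic_set = normalize_set(epic)
    flag_by_gene = {f.gene: f for f in flags}
    rows = []
    for gene in sorted(comparison.nanopore | comparison.wgbs | epic_set):
        if gene in comparison.shared:
            part = "shared"
        elif gene in comparison.nanopore_only:
            part = "nanopore_only"
        elif gene in comparison.wgbs_only:
            part = "wgbs_only"
        else:
            part = "epic_only"
        f = flag_by_gene.get(gene)
        rows.append(
            {
                "gene": gene,
                "nanopore": gene in comparison.nanopore,
                "wgbs": gene in comparison.wgbs,
                "epic": gene in epic_set,
                "partition": part,
                "hmc_flag": bool(f.flagged) if f else False,
                "reason": f.reason if f else "",
            }
        )
    return pd.DataFrame(rows)


def venn_counts(comparison: GeneSetComparison, confirmed: set[str]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("nanopore", len(comparison.nanopore)),
            ("wgbs", len(comparison.wgbs)),
            ("shared", len(comparison.shared)),
            ("nanopore_only", len(comparison.nanopore_only)),
            ("wgbs_only", len(comparison.wgbs_only)),
            ("epic_confirmed", len(confirmed)),
        ],
        columns=["partition", "n_genes"],
    )
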