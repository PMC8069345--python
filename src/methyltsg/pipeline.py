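"""End-to-end orchestration of simulate -> call -> cluster -> integrate ->
filter, with in-memory stage results the CLI serialises to TSV artifacts.

Seeding: each stage derives its own child seed from the pipeline seed via
``numpy.random.SeedSequence.spawn``-style offsets so stages are individually
reproducible and independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, integration, promoters, simulate
from .config import PipelineConfig
from .filters import CascadeResult, run_cascade
from .genome import ToyGenome, generate_toy_genome
from .promoters import PromoterClassification, PromoterProfile
from .simulate import (
    CLASS_HYPER5HMC,
    CLASS_HYPER5MC,
    MethylationLandscape,
    assign_landscape,
    simulate_bisulfite_counts,
    simulate_expression,
    simulate_nanopore_events,
)
from .sixmer import SixMerModel, make_synthetic_model

log = logging.getLogger("methyltsg")

PLATFORMS = ("nanopore", "wgbs", "epic")


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class SimulationBundle:
    genome: ToyGenome
    landscape: MethylationLandscape
    model: SixMerModel
    events: pd.DataFrame
    wgbs: pd.DataFrame
    epic: pd.DataFrame
    regeneration: pd.DataFrame
    cohort: pd.DataFrame
    planted_candidates: list[str]


def simulate_all(config: PipelineConfig, seed: int | None = None) -> SimulationBundle:
    """Generate genome, landscape, pore model, and all read-outs."""
    s = config.seed if seed is None else seed
    sim = config.simulator
    genome = generate_toy_genome(
        sim.n_chrom,
        sim.chrom_length,
        sim.n_genes,
        sim.cpg_density,
        seed=stage_seed(s, 0),
        island_factor=sim.island_factor,
        upstream=config.promoter.upstream,
        downstream=config.promoter.downstream,
    )
    landscape = assign_landscape(
        genome, sim.fractions, sim.p_in, sim.p_out, sim.p_background, seed=stage_seed(s, 1)
    )
    model = make_synthetic_model(sim.model_sd, sim.model_delta, seed=stage_seed(s, 2))
    events = simulate_nanopore_events(
        landscape,
        genome,
        model,
        sim.nanopore_coverage,
        seed=stage_seed(s, 3),
        n_events_per_site=sim.n_events_per_site,
    )
    wgbs, epic = simulate_bisulfite_counts(
        landscape,
        genome,
        sim.bisulfite_coverage,
        sim.conversion_error,
        sim.epic_fraction,
        seed=stage_seed(s, 4),
        epic_mean_coverage=sim.epic_coverage,
    )
    hyper_genes = sorted(landscape.genes_of_class(genome, CLASS_HYPER5MC))
    rng = np.random.default_rng(stage_seed(s, 5))
    n_pick = min(sim.n_planted_candidates, len(hyper_genes))
    planted = sorted(rng.choice(hyper_genes, size=n_pick, replace=False).tolist())
    regen, cohort = simulate_expression(
        genome,
        planted,
        sim.fc_ph4h,
        sim.fc_tumor,
        sim.recovery,
        sim.n_tumor,
        sim.n_normal,
        sim.noise_cv,
        seed=stage_seed(s, 6),
    )
    log.info(
        "simulated %d sites, %d promoters, %d planted candidates",
        genome.n_sites,
        len(genome.promoters),
        len(planted),
    )
    return SimulationBundle(
        genome, landscape, model, events, wgbs, epic, regen, cohort, planted
    )


def call_stage(bundle: SimulationBundle, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Per-site methylation records for all three platforms."""
    calls = calling.call_reads(bundle.events, bundle.model, config.caller.llr_threshold)
    nanopore = calling.aggregate_nanopore_frequency(calls)
    wgbs = calling.bisulfite_frequency(bundle.wgbs, config.caller.min_coverage)
    epic = calling.bisulfite_frequency(bundle.epic, config.caller.min_coverage)
    log.info(
        "called %d/%d/%d sites (nanopore/wgbs/epic)", len(nanopore), len(wgbs), len(epic)
    )
    return {"nanopore": nanopore, "wgbs": wgbs, "epic": epic}


@dataclass
class ClusterStageResult:
    profiles: dict[str, list[PromoterProfile]]
    classifications: dict[str, PromoterClassification]
    gene_sets: dict[str, set[str]]
    promoter_counts: dict[str, int]


def cluster_stage(
    records: dict[str, pd.DataFrame], genome: ToyGenome, config: PipelineConfig, seed: int = 0
) -> ClusterStageResult:
    """Promoter profiling + k-means hyper/hypo classification per platform."""
    pc = config.promoter
    profiles: dict[str, list[PromoterProfile]] = {}
    classifications: dict[str, PromoterClassification] = {}
    gene_sets: dict[str, set[str]] = {}
    promoter_counts: dict[str, int] = {}
    for platform, recs in records.items():
        mapping = promoters.assign_sites_to_promoters(recs, genome.promoters)
        profs = promoters.build_profiles(
            mapping, recs, genome.promoters, pc.n_bins, pc.min_sites, pc.freq_threshold
        )
        cls = promoters.kmeans_classify(
            profs, n_restarts=pc.n_restarts, seed=stage_seed(seed, 10)
        )
        genes, n_hyper = promoters.collapse_to_genes(cls, genome.promoters)
        profiles[platform] = profs
        classifications[platform] = cls
        gene_sets[platform] = {integration.normalize_symbol(g) for g in genes}
        promoter_counts[platform] = n_hyper
        log.info("%s: %d hyper promoters, %d hyper genes", platform, n_hyper, len(genes))
    return ClusterStageResult(profiles, classifications, gene_sets, promoter_counts)


@dataclass
class IntegrationResult:
    comparison: integration.GeneSetComparison
    confirmed: set[str]
    flags: list[integration.FiveHmcFlag]
    membership: pd.DataFrame
    venn: pd.DataFrame


def integrate_stage(
    cluster: ClusterStageResult, genome: ToyGenome, config: PipelineConfig
) -> IntegrationResult:
    comparison = integration.compare_gene_sets(
        cluster.gene_sets["nanopore"], cluster.gene_sets["wgbs"]
    )
    confirmed = integration.confirm_with_epic(comparison.shared, cluster.gene_sets["epic"])
    depths, freqs = integration.gene_promoter_stats(
        cluster.profiles["nanopore"], genome.promoters
    )
    flags = integration.flag_putative_5hmc(
        comparison.wgbs_only,
        depths,
        freqs,
        config.integration.min_reads,
        config.integration.low_freq,
    )
    membership = integration.membership_table(comparison, cluster.gene_sets["epic"], flags)
    venn = integration.venn_counts(comparison, confirmed)
    log.info(
        "overlap %s%%, %d confirmed, %d 5hmC-flagged",
        comparison.overlap_percent,
        len(confirmed),
        sum(f.flagged for f in flags),
    )
    return IntegrationResult(comparison, confirmed, flags, membership, venn)


def cohort_matrices(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the long cohort table into genes x samples tumor and normal
    matrices."""
    wide = cohort.pivot_table(index="gene", columns="sample", values="value")
    tcols = [c for c in wide.columns if str(c).startswith("tumor")]
    ncols = [c for c in wide.columns if str(c).startswith("normal")]
    return wide[tcols], wide[ncols]


def filter_stage(
    confirmed: set[str], bundle: SimulationBundle, config: PipelineConfig
) -> CascadeResult:
    tumor, normal = cohort_matrices(bundle.cohort)
    fc = config.filter
    return run_cascade(
        confirmed,
        bundle.regeneration,
        tumor,
        normal,
        fc.fc_threshold,
        fc.recovery_factor,
        fc.pseudocount,
        fc.alpha,
        fc.use_q,
        fc.known_tsgs,
    )


@dataclass
class PipelineResult:
    bundle: SimulationBundle
    records: dict[str, pd.DataFrame]
    cluster: ClusterStageResult
    integrated: IntegrationResult
    cascade: CascadeResult
    spearman: float
    metaplot: pd.DataFrame
    planted_recovered: set[str] = field(default_factory=set)


def run_all(config: PipelineConfig, seed: int | None = None) -> PipelineResult:
    """Full pipeline on one simulated replicate."""
    s = config.seed if seed is None else seed
    bundle = simulate_all(config, s)
    records = call_stage(bundle, config)
    cluster = cluster_stage(records, bundle.genome, config, seed=s)
    integrated = integrate_stage(cluster, bundle.genome, config)
    cascade = filter_stage(integrated.confirmed, bundle, config)
    rho = calling.platform_spearman(
        records["nanopore"], records["wgbs"], config.caller.min_coverage
    )
    meta = promoters.tss_metaplot(
        records["nanopore"],
        bundle.genome.promoters,
        config.promoter.metaplot_span,
        config.promoter.metaplot_bins,
    )
    planted = {integration.normalize_symbol(g) for g in bundle.planted_candidates}
    result = PipelineResult(
        bundle,
        records,
        cluster,
        integrated,
        cascade,
        rho,
        meta,
        planted_recovered=cascade.candidates & planted,
    )
    log.info("funnel: %s; spearman %.3f", cascade.funnel, rho)
    return result


def replicate_metrics(config: PipelineConfig, seeds: list[int]) -> dict:
    """Planted-candidate recovery over seeded replicates.

    Pools across replicates: sensitivity = recovered planted candidates /
    planted; per-stage false-admission = non-planted (or non-hyper5mC, for
    the confirmation stage) genes admitted by the stage / such genes entering
    it. Also checks funnel monotonicity on every replicate.
    """
    planted_total = recovered_total = 0
    admit = {"confirmed": [0, 0], "regeneration": [0, 0], "tumor": [0, 0]}
    monotone = True
    for s in seeds:
        res = run_all(config, seed=s)
        planted = {g.upper() for g in res.bundle.planted_candidates}
        true_hyper = {
            g.upper()
            for g in res.bundle.landscape.genes_of_class(res.bundle.genome, CLASS_HYPER5MC)
        }
        all_genes = {g.upper() for g in res.bundle.genome.gene_symbols}
        confirmed = res.integrated.confirmed
        tab = res.cascade.table
        regen_pass = set(tab.loc[tab["regeneration_pass"], "gene"])
        tumor_pass = set(tab.loc[tab["tumor_pass"] & tab["regeneration_pass"], "gene"])
        planted_total += len(planted)
        recovered_total += len(res.cascade.candidates & planted)
        admit["confirmed"][0] += len(confirmed - true_hyper)
        admit["confirmed"][1] += len(all_genes - true_hyper)
        admit["regeneration"][0] += len(regen_pass - planted)
        admit["regeneration"][1] += len(confirmed - planted)
        admit["tumor"][0] += len(tumor_pass - planted)
        admit["tumor"][1] += len(regen_pass - planted) or 0
        counts = list(res.cascade.funnel.values())
        monotone &= all(a >= b for a, b in zip(counts, counts[1:]))
    rates = {
        stage: (num / den if den else 0.0) for stage, (num, den) in admit.items()
    }
    return {
        "sensitivity": recovered_total / planted_total if planted_total else float("nan"),
        "false_admission": rates,
        "funnel_monotone": monotone,
        "n_replicates": len(seeds),
        "n_planted": planted_total,
    }
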