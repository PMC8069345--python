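"""Pipeline configuration: one YAML file, per-stage blocks, all defaults
preloaded with the published analysis parameters (LLR threshold 2.5, minimum
coverage 5 reads, hypermethylation cut-off 50%, 5hmC rule >=5 reads at <=10%
frequency, twofold expression filters)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SimulatorConfig:
    n_chrom: int = 1
    chrom_length: int = 300_000
    n_genes: int = 40
    cpg_density: float = 0.005
    island_factor: float = 10.0
    fractions: tuple[float, float, float] = (0.25, 0.55, 0.20)
    p_in: float = 0.9
    p_out: float = 0.05
    p_background: float = 0.8
    model_sd: float = 2.0
    model_delta: float = 4.0
    n_events_per_site: int = 11
    nanopore_coverage: float = 15.0
    bisulfite_coverage: float = 30.0
    epic_coverage: float = 60.0
    conversion_error: float = 0.005
    epic_fraction: float = 0.3
    n_planted_candidates: int = 5
    fc_ph4h: float = 4.0
    fc_tumor: float = 4.0
    recovery: bool = True
    n_tumor: int = 371
    n_normal: int = 50
    noise_cv: float = 0.2


@dataclass
class CallerConfig:
    llr_threshold: float = 2.5
    min_coverage: int = 5


@dataclass
class PromoterConfig:
    upstream: int = 1000
    downstream: int = 500
    n_bins: int = 20
    min_sites: int = 3
    n_restarts: int = 10
    freq_threshold: float = 0.5
    metaplot_span: int = 2000
    metaplot_bins: int = 80


@dataclass
class IntegrationConfig:
    min_reads: float = 5.0
    low_freq: float = 0.1


@dataclass
class FilterConfig:
    fc_threshold: float = 2.0
    alpha: float = 1e-4
    recovery_factor: float = 2.0
    pseudocount: float = 0.1
    use_q: bool = False
    known_tsgs: list[str] = field(default_factory=lambda: ["AJAP1", "GATA5", "LRAT"])


@dataclass
class PipelineConfig:
    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulator"]["fractions"] = list(d["simulator"]["fractions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def block(klass, key):
            sub = dict(d.get(key, {}))
            if klass is SimulatorConfig and "fractions" in sub:
                sub["fractions"] = tuple(sub["fractions"])
            return klass(**sub)

        return cls(
            seed=int(d.get("seed", 0)),
            simulator=block(SimulatorConfig, "simulator"),
            caller=block(CallerConfig, "caller"),
            promoter=block(PromoterConfig, "promoter"),
            integration=block(IntegrationConfig, "integration"),
            filter=block(FilterConfig, "filter"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
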