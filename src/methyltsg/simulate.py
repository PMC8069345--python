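"""Simulators with recorded ground truth.

The landscape assigns each promoter one of three true classes — 5mC-
hypermethylated, hypomethylated, or 5hmC-hydroxymethylated — and each CpG
site a true state. Two read-out simulators sit on top:

* nanopore: per-read current events drawn from the 6-mer Gaussian model.
  5mC sites emit from the M-context distributions; unmethylated AND 5hmC
  sites emit from the C-context distributions, so the downstream 5mC caller
  sees hydroxymethylation as absence of 5mC.
* bisulfite (WGBS / EPIC): binomial methylated counts where both 5mC and
  5hmC read as methylated — bisulfite conversion cannot tell them apart.

This asymmetry between the two read-outs is what the putative-5hmC flagging
rule exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import PromoterRecord, ToyGenome, oriented_offset
from .sixmer import SixMerModel, methylated_variant

STATE_5MC = "5mC"
STATE_UNMETH = "unmeth"
STATE_5HMC = "5hmC"
SITE_STATES = (STATE_5MC, STATE_UNMETH, STATE_5HMC)

CLASS_HYPER5MC = "hyper5mC"
CLASS_HYPO = "hypo"
CLASS_HYPER5HMC = "hyper5hmC"
PROMOTER_CLASSES = (CLASS_HYPER5MC, CLASS_HYPO, CLASS_HYPER5HMC)

# per-site event window: 11 six-mers, the CpG cytosine at context index 7,
# so six of the eleven 6-mers contain the CpG and are informative
N_EVENTS_PER_SITE = 11
_CPG_CONTEXT_INDEX = 7


def largest_remainder(fractions, n: int) -> list[int]:
    """Apportion ``n`` items to ``fractions`` (summing to 1) so the counts sum
    to ``n`` exactly: floor quotas, then +1 by largest fractional remainder
    (ties broken by position)."""
    fractions = np.asarray(fractions, dtype=float)
    quotas = fractions * n
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    order = np.argsort(-remainders, kind="stable")
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


@dataclass
class MethylationLandscape:
    """Ground truth: per-CpG state and per-promoter class."""

    site_states: np.ndarray  # one of SITE_STATES per genome CpG, in site order
    promoter_classes: dict[str, str]
    site_promoter: np.ndarray  # promoter_id per site, "" outside promoters

    def promoter_class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in PROMOTER_CLASSES}
        for c in self.promoter_classes.values():
            out[c] += 1
        return out

    def genes_of_class(self, genome: ToyGenome, cls: str) -> set[str]:
        return {
            p.gene for p in genome.promoters if self.promoter_classes[p.promoter_id] == cls
        }

    def truth_table(self, genome: ToyGenome) -> pd.DataFrame:
        df = genome.cpg_sites.copy()
        df["state"] = self.site_states
        df["promoter_id"] = self.site_promoter
        return df


def _site_promoter_map(genome: ToyGenome) -> np.ndarray:
    """promoter_id per CpG site ('' where the site is in no promoter;
    first promoter wins on overlap)."""
    out = np.full(genome.n_sites, "", dtype=object)
    chroms = genome.cpg_sites["chrom"].to_numpy()
    pos = genome.cpg_sites["pos"].to_numpy()
    for p in genome.promoters:
        d = oriented_offset(pos, p.tss, p.strand)
        mask = (chroms == p.chrom) & (d >= -p.upstream) & (d < p.downstream) & (out == "")
        out[mask] = p.promoter_id
    return out


def assign_landscape(
    genome: ToyGenome,
    fractions: tuple[float, float, float] = (0.25, 0.55, 0.20),
    p_in: float = 0.9,
    p_out: float = 0.05,
    p_background: float = 0.8,
    seed: int = 0,
) -> MethylationLandscape:
    """Draw promoter classes and per-site states.

    ``fractions`` = (hyper5mC, hypo, hyper5hmC) promoter proportions; counts
    follow largest-remainder rounding so they are exact. Within a hyper5mC
    promoter each CpG is 5mC with probability ``p_in``; within a hypo
    promoter with probability ``p_out``; within a hyper5hmC promoter it is
    5hmC with probability ``p_in``. Sites outside promoters are 5mC with
    probability ``p_background`` (the typical methylated genomic baseline).
    """
    for name, v in [("p_in", p_in), ("p_out", p_out), ("p_background", p_background)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability, got {v}")
    fr = np.asarray(fractions, dtype=float)
    if len(fr) != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three non-negative values summing to 1")

    rng = np.random.default_rng(seed)
    n_prom = len(genome.promoters)
    counts = largest_remainder(fr, n_prom)
    labels = np.repeat(PROMOTER_CLASSES, counts)
    rng.shuffle(labels)
    promoter_classes = {
        p.promoter_id: labels[i] for i, p in enumerate(genome.promoters)
    }

    site_promoter = _site_promoter_map(genome)
    u = rng.random(genome.n_sites)
    states = np.full(genome.n_sites, STATE_UNMETH, dtype=object)
    for i, pid in enumerate(site_promoter):
        if pid == "":
            if u[i] < p_background:
                states[i] = STATE_5MC
        else:
            cls = promoter_classes[pid]
            if cls == CLASS_HYPER5MC:
                if u[i] < p_in:
                    states[i] = STATE_5MC
            elif cls == CLASS_HYPO:
                if u[i] < p_out:
                    states[i] = STATE_5MC
            else:  # hyper5hmC
                if u[i] < p_in:
                    states[i] = STATE_5HMC
    return MethylationLandscape(states, promoter_classes, site_promoter)


def _random_context(rng: np.random.Generator, length: int, cpg_at: int) -> str:
    """Random ACGT context with a single CG dinucleotide at ``cpg_at``."""
    bases = []
    prev = "A"
    i = 0
    while i < length:
        if i == cpg_at:
            bases.append("CG")
            prev = "G"
            i += 2
            continue
        b = "ACGT"[rng.integers(0, 4)]
        while (prev == "C" and b == "G") or (b == "C" and i + 1 == cpg_at):
            b = "ACT"[rng.integers(0, 3)]
        bases.append(b)
        prev = b
        i += 1
    return "".join(bases)[:length]


def site_context_kmers(rng: np.random.Generator, n_events: int = N_EVENTS_PER_SITE) -> list[str]:
    """The ``n_events`` overlapping 6-mers of a random site context."""
    cpg_at = min(_CPG_CONTEXT_INDEX, max(0, n_events - 1))
    ctx = _random_context(rng, n_events + 5, cpg_at)
    return [ctx[s : s + 6] for s in range(n_events)]


def simulate_nanopore_events(
    landscape: MethylationLandscape,
    genome: ToyGenome,
    model: SixMerModel,
    mean_coverage: float = 15.0,
    seed: int = 0,
    n_events_per_site: int = N_EVENTS_PER_SITE,
) -> pd.DataFrame:
    """Per-read current events for every CpG site.

    Read depth per site is Poisson(mean_coverage); each read contributes one
    current per overlapping 6-mer. Returns a long table with columns
    read_id, chrom, pos, kmer_index, current. Reads are independent per site
    (reads are not modelled as contiguous molecules).
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be non-negative")
    rng = np.random.default_rng(seed)
    n_sites = genome.n_sites
    cols = ["read_id", "chrom", "pos", "kmer_index", "current"]
    if n_sites == 0 or mean_coverage == 0:
        return pd.DataFrame(columns=cols)

    mu_c, sd_c, mu_m, sd_m = model.param_arrays()
    # per-site fixed sequence context
    kidx = np.empty((n_sites, n_events_per_site), dtype=np.int64)
    for i in range(n_sites):
        for j, k in enumerate(site_context_kmers(rng, n_events_per_site)):
            if k not in model.kmer_index:
                raise KeyError(f"6-mer {k!r} missing from the pore model")
            mk = methylated_variant(k)
            if mk != k and mk not in model:
                raise KeyError(f"6-mer {mk!r} missing from the pore model")
            kidx[i, j] = model.kmer_index[k]

    depth = rng.poisson(mean_coverage, size=n_sites)
    site_rep = np.repeat(np.arange(n_sites), depth)  # one row per read-site
    n_reads = len(site_rep)
    if n_reads == 0:
        return pd.DataFrame(columns=cols)

    meth = (landscape.site_states == STATE_5MC)[site_rep]
    kk = kidx[site_rep]  # (n_reads, n_events)
    mu = np.where(meth[:, None], mu_m[kk], mu_c[kk])
    sd = np.where(meth[:, None], sd_m[kk], sd_c[kk])
    currents = mu + sd * rng.standard_normal(mu.shape)

    chrom = genome.cpg_sites["chrom"].to_numpy()
    pos = genome.cpg_sites["pos"].to_numpy()
    df = pd.DataFrame(
        {
            "read_id": np.repeat(np.arange(n_reads), n_events_per_site),
            "chrom": np.repeat(chrom[site_rep], n_events_per_site),
            "pos": np.repeat(pos[site_rep], n_events_per_site),
            "kmer_index": kk.ravel(),
            "current": currents.ravel(),
        }
    )
    return df


def simulate_bisulfite_counts(
    landscape: MethylationLandscape,
    genome: ToyGenome,
    mean_coverage: float = 30.0,
    conversion_error: float = 0.005,
    epic_fraction: float = 0.3,
    seed: int = 0,
    epic_mean_coverage: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial methylated/total counts for WGBS (all sites) and EPIC (a
    random targeted subset of sites, fraction ``epic_fraction``).

    Both 5mC and 5hmC sites convert as methylated (probability
    1 - conversion_error); unmethylated sites as methylated with probability
    ``conversion_error``. Sites drawing zero coverage are omitted.
    """
    if not 0.0 <= conversion_error <= 0.05:
        raise ValueError("conversion_error must be in [0, 0.05]")
    if not 0.0 <= epic_fraction <= 1.0:
        raise ValueError("epic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    q = np.where(
        np.isin(landscape.site_states.astype(str), [STATE_5MC, STATE_5HMC]),
        1.0 - conversion_error,
        conversion_error,
    )
    targeted = rng.random(genome.n_sites) < epic_fraction

    def one(platform: str, cov: float, mask: np.ndarray) -> pd.DataFrame:
        total = rng.poisson(cov, size=genome.n_sites) * mask
        keep = total > 0
        meth = rng.binomial(total[keep], q[keep])
        sites = genome.cpg_sites.loc[keep]
        return pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy(),
                "pos": sites["pos"].to_numpy(),
                "strand": sites["strand"].to_numpy(),
                "methylated_count": meth,
                "total_count": total[keep],
                "platform": platform,
            }
        )

    wgbs = one("wgbs", mean_coverage, np.ones(genome.n_sites, dtype=bool))
    epic = one(
        "epic",
        mean_coverage if epic_mean_coverage is None else epic_mean_coverage,
        targeted,
    )
    return wgbs, epic


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 log-normal multiplicative noise with coefficient of variation
    ``cv`` (exactly 1 when cv == 0)."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def simulate_expression(
    genome: ToyGenome,
    planted_candidates: list[str],
    fc_ph4h: float = 4.0,
    fc_tumor: float = 4.0,
    recovery: bool = True,
    n_tumor: int = 371,
    n_normal: int = 50,
    noise_cv: float = 0.2,
    seed: int = 0,
    baseline_median: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression tables for the regeneration time course and the tumor cohort.

    Regeneration (mouse-style capitalised symbols): one TPM-like value per
    gene per condition (sham, ph4h, ph1wk). Planted candidates are divided by
    ``fc_ph4h`` at 4 h post-hepatectomy and return to the sham level at one
    week when ``recovery`` is true. Cohort: per-sample values, planted genes
    divided by ``fc_tumor`` in tumors. Noise is multiplicative log-normal.
    """
    if fc_ph4h <= 1 or fc_tumor <= 1:
        raise ValueError("fold changes denote downregulation divisors and must exceed 1")
    rng = np.random.default_rng(seed)
    genes = list(genome.gene_symbols)
    planted = {g.strip().upper() for g in planted_candidates}
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted candidates not in genome: {sorted(unknown)}")
    base = baseline_median * np.exp(rng.normal(0.0, 1.0, size=len(genes)))
    is_planted = np.array([g in planted for g in genes])

    regen_rows = []
    for cond in ("sham", "ph4h", "ph1wk"):
        vals = base.copy()
        if cond == "ph4h":
            vals = np.where(is_planted, vals / fc_ph4h, vals)
        elif cond == "ph1wk" and not recovery:
            vals = np.where(is_planted, vals / fc_ph4h, vals)
        vals = vals * _noise(rng, noise_cv, len(genes))
        for g, v in zip(genes, vals):
            regen_rows.append((g.capitalize(), cond, float(v)))
    regen = pd.DataFrame(regen_rows, columns=["gene", "condition", "value"])

    cohort_rows = []
    for cond, n in (("normal", n_normal), ("tumor", n_tumor)):
        centre = np.where(is_planted & (cond == "tumor"), base / fc_tumor, base)
        vals = centre[:, None] * _noise(rng, noise_cv, (len(genes), n))
        for gi, g in enumerate(genes):
            for s in range(n):
                cohort_rows.append((g, cond, f"{cond}_{s:03d}", float(vals[gi, s])))
    cohort = pd.DataFrame(cohort_rows, columns=["gene", "condition", "sample", "value"])
    return regen, cohort
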