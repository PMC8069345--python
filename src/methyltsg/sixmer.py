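"""Gaussian 6-mer current model over the five-base alphabet {A, C, G, T, M}.

Nanopore ionic current depends on the ~6 bases occupying the pore, so a
per-6-mer Gaussian emission model (mean and spread of the current level in pA)
captures the sequence dependence. 5-methylcytosine is written as ``M``; for
every 6-mer containing a CpG the model stores both the unmethylated variant
(with ``CG``) and the fully methylated variant (with ``MG``). 6-mers mixing a
methylated and an unmethylated CpG cytosine are excluded: a site is modelled
as all-or-nothing within one 6-mer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_ALPHABET = "ACGT"
METHYL_BASE = "M"


def methylated_variant(kmer: str) -> str:
    """Replace every CpG-context cytosine in ``kmer`` with M.

    A trailing C (possibly followed by G in the genome, outside the 6-mer) is
    left untouched: only C's whose G is visible inside the 6-mer are in CpG
    context here.
    """
    out = list(kmer)
    for i in range(len(kmer) - 1):
        if kmer[i] == "C" and kmer[i + 1] == "G":
            out[i] = METHYL_BASE
    return "".join(out)


def unmethylated_variant(kmer: str) -> str:
    """Replace every M with C."""
    return kmer.replace(METHYL_BASE, "C")


def _has_unmethylated_cpg(kmer: str) -> bool:
    return "CG" in kmer


@dataclass
class SixMerModel:
    """Map 6-mer -> (mean current, sd current), both in pA.

    ``kmers`` lists the canonical (ACGT-only) 6-mers; event records refer to
    entries of that list by integer index so event tables stay compact.
    """

    entries: dict[str, tuple[float, float]]
    kmers: list[str] = field(init=False)
    kmer_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for kmer, (mean, sd) in self.entries.items():
            if not np.isfinite(mean) or not np.isfinite(sd) or sd <= 0:
                raise ValueError(f"invalid Gaussian parameters for {kmer!r}: ({mean}, {sd})")
            if METHYL_BASE in kmer and _has_unmethylated_cpg(kmer):
                raise ValueError(
                    f"{kmer!r} mixes methylated and unmethylated CpG cytosines; "
                    "such 6-mers are excluded from the model"
                )
        for kmer in self.entries:
            if METHYL_BASE in kmer:
                if unmethylated_variant(kmer) not in self.entries:
                    raise ValueError(f"M-variant {kmer!r} lacks its C-variant")
            elif _has_unmethylated_cpg(kmer):
                if methylated_variant(kmer) not in self.entries:
                    raise ValueError(f"CpG 6-mer {kmer!r} lacks its M-variant")
        self.kmers = sorted(k for k in self.entries if METHYL_BASE not in k)
        self.kmer_index = {k: i for i, k in enumerate(self.kmers)}

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def params(self, kmer: str) -> tuple[float, float]:
        try:
            return self.entries[kmer]
        except KeyError:
            raise KeyError(f"6-mer {kmer!r} is not in the pore model") from None

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mu_C, sd_C, mu_M, sd_M) aligned with ``self.kmers``.

        For 6-mers without a CpG the M columns repeat the C columns, so the
        per-event log-likelihood ratio contribution is exactly zero there.
        """
        n = len(self.kmers)
        mu_c = np.empty(n)
        sd_c = np.empty(n)
        mu_m = np.empty(n)
        sd_m = np.empty(n)
        for i, k in enumerate(self.kmers):
            mu_c[i], sd_c[i] = self.entries[k]
            mk = methylated_variant(k)
            mu_m[i], sd_m[i] = self.entries[mk] if mk != k else (mu_c[i], sd_c[i])
        return mu_c, sd_c, mu_m, sd_m

    def to_tsv(self, path) -> None:
        rows = [(k, m, s) for k, (m, s) in sorted(self.entries.items())]
        pd.DataFrame(rows, columns=["kmer", "level_mean", "level_stdv"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "SixMerModel":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        entries = {
            str(r.kmer): (float(r.level_mean), float(r.level_stdv)) for r in df.itertuples()
        }
        return cls(entries)


def make_synthetic_model(
    sd: float = 2.0,
    delta: float = 4.0,
    mean_center: float = 100.0,
    mean_spread: float = 10.0,
    seed: int = 0,
) -> SixMerModel:
    """Build a full synthetic pore model over all 4096 canonical 6-mers.

    Every CpG-containing 6-mer gets an M-variant whose mean is shifted by
    ``delta`` pA (random sign per 6-mer); the default delta = 2*sd gives each
    informative event a two-standard-deviation separation between the
    methylated and unmethylated current distributions.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    entries: dict[str, tuple[float, float]] = {}
    for tup in itertools.product(CANONICAL_ALPHABET, repeat=6):
        kmer = "".join(tup)
        mean = float(rng.normal(mean_center, mean_spread))
        entries[kmer] = (mean, sd)
        mk = methylated_variant(kmer)
        if mk != kmer:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            entries[mk] = (mean + sign * delta, sd)
    return SixMerModel(entries)
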