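"""Toy genome: chromosomes, CpG sites, and promoter annotations.

A stand-in for a reference assembly plus a promoter database: a few
chromosomes, CpG sites at a background density with CpG-island enrichment
inside promoter windows, and one promoter window per gene around its TSS.
Coordinates are 0-based; promoter windows are half-open in strand-oriented
TSS offset (see :func:`oriented_offset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter window around a TSS: [-upstream, +downstream) in
    strand-oriented offset, upstream meaning 5' of the TSS on the annotated
    strand."""

    promoter_id: str
    gene: str
    chrom: str
    tss: int
    strand: str
    upstream: int = 1000
    downstream: int = 500

    def contains(self, pos: int) -> bool:
        d = oriented_offset(pos, self.tss, self.strand)
        return -self.upstream <= d < self.downstream

    def genomic_bounds(self) -> tuple[int, int]:
        """Half-open genomic interval [start, end) covered by the window."""
        if self.strand == "+":
            return self.tss - self.upstream, self.tss + self.downstream
        return self.tss - self.downstream + 1, self.tss + self.upstream + 1


def oriented_offset(pos, tss, strand):
    """Offset of ``pos`` from the TSS, positive in the direction of
    transcription (vectorises over ``pos``)."""
    pos = np.asarray(pos)
    return pos - tss if strand == "+" else tss - pos


@dataclass
class ToyGenome:
    chromosomes: list[tuple[str, int]]
    cpg_sites: pd.DataFrame  # columns: chrom, pos, strand
    promoters: list[PromoterRecord]
    gene_symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        pos = self.cpg_sites["pos"].to_numpy()
        if len(pos) and (pos < 0).any():
            raise ValueError("CpG position < 0")
        for chrom, grp in self.cpg_sites.groupby("chrom"):
            if chrom not in lengths:
                raise ValueError(f"CpG site on unknown chromosome {chrom!r}")
            if (grp["pos"].to_numpy() >= lengths[chrom]).any():
                raise ValueError(f"CpG position beyond end of {chrom}")
        for p in self.promoters:
            lo, hi = p.genomic_bounds()
            if p.chrom not in lengths or lo < 0 or hi > lengths[p.chrom]:
                raise ValueError(f"promoter {p.promoter_id} outside chromosome bounds")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("gene symbols must be unique")

    @property
    def n_sites(self) -> int:
        return len(self.cpg_sites)


def generate_toy_genome(
    n_chrom: int = 1,
    chrom_length: int = 100_000,
    n_genes: int = 10,
    cpg_density: float = 0.01,
    seed: int = 0,
    island_factor: float = 10.0,
    upstream: int = 1000,
    downstream: int = 500,
) -> ToyGenome:
    """Generate chromosomes with promoters and CpG sites.

    CpG sites fall at rate ``cpg_density`` per bp genome-wide plus an extra
    ``(island_factor - 1) * cpg_density`` inside promoter windows, mimicking
    CpG islands. Promoters are placed non-overlapping, one per gene, genes
    distributed round-robin over chromosomes; raises if the windows do not
    fit without overlap. Deterministic for a fixed seed.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if cpg_density < 0:
        raise ValueError("cpg_density must be non-negative")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)]
    margin = max(upstream, downstream) + 1
    window = upstream + downstream

    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    per_chrom: dict[str, list[int]] = {name: [] for name, _ in chromosomes}
    for i in range(n_genes):
        per_chrom[chromosomes[i % n_chrom][0]].append(i)

    promoters: list[PromoterRecord] = []
    for chrom, length in chromosomes:
        idx = per_chrom[chrom]
        if not idx:
            continue
        seg = length // len(idx)
        if seg < window + 2 * margin:
            raise ValueError(
                f"cannot place {len(idx)} non-overlapping promoter windows on "
                f"{chrom} ({length} bp)"
            )
        for j, gi in enumerate(idx):
            lo, hi = j * seg + margin, (j + 1) * seg - margin
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            promoters.append(
                PromoterRecord(f"P{gi:04d}", genes[gi], chrom, tss, strand, upstream, downstream)
            )

    chunks = []
    for chrom, length in chromosomes:
        n_bg = rng.poisson(cpg_density * length)
        positions = list(rng.integers(0, length, size=n_bg))
        for p in promoters:
            if p.chrom != chrom:
                continue
            lo, hi = p.genomic_bounds()
            n_extra = rng.poisson((island_factor - 1.0) * cpg_density * (hi - lo))
            positions.extend(rng.integers(lo, hi, size=n_extra))
        positions = sorted(set(int(x) for x in positions))
        # a CpG occupies two bases; drop positions adjacent to the previous one
        spaced: list[int] = []
        for p in positions:
            if not spaced or p > spaced[-1] + 1:
                spaced.append(p)
        chunks.append(pd.DataFrame({"chrom": chrom, "pos": spaced, "strand": "+"}))
    sites = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["chrom", "pos", "strand"])
    )
    return ToyGenome(chromosomes, sites, promoters, genes)


def write_fasta(genome: ToyGenome, path, seed: int = 0, width: int = 60) -> None:
    """Write a sequence realisation of the toy genome: CG dinucleotides at the
    recorded CpG sites, no CG elsewhere."""
    rng = np.random.default_rng(seed)
    by_chrom = {c: set(g["pos"]) for c, g in genome.cpg_sites.groupby("chrom")}
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes:
            cpg = by_chrom.get(chrom, set())
            seq = []
            prev = "A"
            i = 0
            while i < length:
                if i in cpg and i + 1 < length:
                    seq.append("CG")
                    prev = "G"
                    i += 2
                    continue
                base = "ACGT"[rng.integers(0, 4)]
                # avoid spurious CpGs: no G after C, no C before a recorded site
                while (prev == "C" and base == "G") or (base == "C" and (i + 1) in cpg):
                    base = "ACT"[rng.integers(0, 3)]
                seq.append(base)
                prev = base
                i += 1
            s = "".join(seq)[:length]
            fh.write(f">{chrom}\n")
            for j in range(0, len(s), width):
                fh.write(s[j : j + width] + "\n")
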