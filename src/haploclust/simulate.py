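"""Synthetic polyploid read simulator with a known haplotype truth set.

The generator emulates the virtual-polyploid validation design: k
haplotypes over a shared reference, heterozygous sites at a configurable
fraction of positions, and long reads sampled per haplotype at a target
coverage with substitution errors at heterozygous sites.  Reads are
produced directly in reduced space — ordered (position, base) calls at
the known heterozygous sites — because the phaser never consults any
other base; an optional random-scaffold FASTQ (synthetic sequence, only
to exercise the FASTQ writer) can be emitted alongside.

Allele sharing between haplotypes is controlled by ``p_shared``: with
that probability a site's two alleles split the haplotypes into two
random groups (the shared alleles that make polyploid phasing hard),
otherwise exactly one haplotype carries a private allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .variantio import BASES, ReducedRead, VariantPosition


@dataclass
class SimulationConfig:
    """Study conditions of a simulated polyploid.

    Defaults follow the hardest routinely reported benchmark regime: a
    tetraploid at 0.5% heterozygosity, 20X long-read coverage per
    haplotype, ~20 kb reads, and a 10% per-base substitution error at
    heterozygous sites (raw nanopore-scale noise; no error correction is
    ever applied downstream).
    """

    ploidy: int = 4
    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    heterozygosity: float = 0.005
    coverage_per_haplotype: float = 20.0
    read_length_mean: float = 20_000.0
    read_length_sd: float = 8_000.0
    per_base_error_rate: float = 0.10
    split_read_fraction: float = 0.0
    variant_call_miss_rate: float = 0.0
    p_shared: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        for name in (
            "heterozygosity",
            "per_base_error_rate",
            "split_read_fraction",
            "variant_call_miss_rate",
            "p_shared",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_chromosomes, self.chromosome_length) < 1:
            raise ValueError("chromosome count/length must be positive")
        if self.coverage_per_haplotype <= 0 or self.read_length_mean <= 0:
            raise ValueError("coverage and read length must be positive")

    def haplotype_names(self) -> list[str]:
        return [f"hap{i + 1}" for i in range(self.ploidy)]

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground-truth base of every haplotype at every heterozygous site."""

    haplotypes: dict[str, dict[tuple[str, int], str]]

    def names(self) -> list[str]:
        return sorted(self.haplotypes)

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def positions(self) -> set[VariantPosition]:
        out: set[VariantPosition] = set()
        for calls in self.haplotypes.values():
            for chrom, pos in calls:
                out.add(VariantPosition(chrom, pos))
        return out

    def base_of(self, haplotype: str, chrom: str, pos: int) -> str | None:
        return self.haplotypes[haplotype].get((chrom, pos))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for hap in self.names():
                for (chrom, pos), base in sorted(self.haplotypes[hap].items()):
                    fh.write(f"{hap}\t{chrom}\t{pos}\t{base}\n")

    @classmethod
    def read_tsv(cls, path) -> "TruthSet":
        haps: dict[str, dict[tuple[str, int], str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                hap, chrom, pos, base = line.split("\t")
                haps.setdefault(hap, {})[(chrom, int(pos))] = base
        return cls(haps)


def generate_truth(config: SimulationConfig) -> tuple[set[VariantPosition], TruthSet]:
    """Sample heterozygous sites and assign every haplotype a base.

    Sites are drawn uniformly without replacement at rate
    ``heterozygosity``; at each site at least two distinct bases occur
    across haplotypes (except for the degenerate ploidy-1 case, where a
    single base is assigned)."""
    rng = np.random.default_rng(config.seed)
    haps = config.haplotype_names()
    truth: dict[str, dict[tuple[str, int], str]] = {h: {} for h in haps}
    positions: set[VariantPosition] = set()
    k = config.ploidy
    for chrom in config.chromosome_names():
        n_sites = int(round(config.heterozygosity * config.chromosome_length))
        if n_sites < 1:
            continue
        sites = rng.choice(config.chromosome_length, size=n_sites, replace=False) + 1
        for pos in sorted(int(p) for p in sites):
            b1, b2 = rng.choice(4, size=2, replace=False)
            if k == 1:
                truth[haps[0]][(chrom, pos)] = BASES[b1]
            else:
                if k > 2 and rng.random() < config.p_shared:
                    group_size = int(rng.integers(1, k))
                else:
                    group_size = 1
                carriers = set(rng.choice(k, size=group_size, replace=False).tolist())
                for i, hap in enumerate(haps):
                    truth[hap][(chrom, pos)] = BASES[b2 if i in carriers else b1]
            positions.add(VariantPosition(chrom, pos))
    if not positions:
        import warnings

        warnings.warn("heterozygosity * chromosome_length < 1: empty truth set")
    return positions, TruthSet(truth)


def degrade_variant_calls(
    het_positions: Iterable[VariantPosition],
    miss_rate: float,
    seed: int = 0,
) -> set[VariantPosition]:
    """Randomly drop a fraction of sites, emulating variant-calling misses.

    Sites the caller never reported cannot be phased; downstream reduced
    reads built against the degraded set will not contain them."""
    ordered = sorted(het_positions)
    if miss_rate <= 0:
        return set(ordered)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(ordered)) >= miss_rate
    return {vp for vp, k in zip(ordered, keep) if k}


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    while True:
        ln = rng.normal(config.read_length_mean, config.read_length_sd)
        if ln >= 1:
            return int(ln)


def simulate_reads(
    truth: TruthSet,
    config: SimulationConfig,
    het_positions: Iterable[VariantPosition] | None = None,
) -> list[ReducedRead]:
    """Sample reduced long reads from every haplotype at the target coverage.

    Read starts are uniform, lengths are truncated-normal, and at each
    covered heterozygous site the haplotype's base is emitted, flipped to
    a uniformly random different base with probability
    ``per_base_error_rate``.  A ``split_read_fraction`` of reads is
    emitted as two same-chromosome segments separated by a displaced gap
    (emulating a structural variant between sample and reference).
    Reads carry their source haplotype as a hidden truth label and reads
    covering no heterozygous site are not emitted.
    """
    rng = np.random.default_rng(config.seed + 1)
    if het_positions is None:
        known = truth.positions()
    else:
        known = set(het_positions)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in config.chromosome_names():
        pos = sorted(vp.position for vp in known if vp.chromosome == chrom)
        by_chrom[chrom] = np.asarray(pos, dtype=np.int64)

    reads: list[ReducedRead] = []
    counter = 0
    length = config.chromosome_length
    for chrom in config.chromosome_names():
        sites = by_chrom[chrom]
        for hap in truth.names():
            # starts sampled over [1-(len-1), length] and clipped, so
            # coverage is uniform out to both chromosome ends; the read
            # count compensates for the clipped overhangs
            mean_len = min(config.read_length_mean, length)
            clip_factor = (length + mean_len - 1) / length
            target_bases = config.coverage_per_haplotype * length
            n_reads = max(1, int(round(target_bases / config.read_length_mean * clip_factor)))
            for _ in range(n_reads):
                ln = _draw_length(rng, config)
                ln = min(ln, length)
                is_split = rng.random() < config.split_read_fraction
                segments: list[tuple[int, int]] = []
                if is_split:
                    half = ln // 2
                    gap = int(rng.integers(1, 4) * config.read_length_mean)
                    total = ln + gap
                    if total < length and half >= 1:
                        start = int(rng.integers(1, length - total + 1))
                        segments = [
                            (start, start + half - 1),
                            (start + half + gap, start + ln + gap - 1),
                        ]
                    else:
                        is_split = False
                if not segments:
                    start0 = int(rng.integers(1 - (ln - 1), length + 1))
                    start = max(1, start0)
                    end = min(length, start0 + ln - 1)
                    if end < start:
                        continue
                    segments = [(start, end)]
                counter += 1
                base_id = f"sim{counter:06d}"
                for seg_no, (s, e) in enumerate(segments, 1):
                    lo = int(np.searchsorted(sites, s, side="left"))
                    hi = int(np.searchsorted(sites, e, side="right"))
                    seg_sites = sites[lo:hi]
                    if len(seg_sites) == 0:
                        continue
                    calls = []
                    errs = rng.random(len(seg_sites)) < config.per_base_error_rate
                    alts = rng.integers(1, 4, size=len(seg_sites))
                    for p, is_err, alt in zip(seg_sites.tolist(), errs.tolist(), alts.tolist()):
                        b = truth.base_of(hap, chrom, p)
                        if b is None:
                            continue
                        if is_err:
                            b = BASES[(BASES.index(b) + alt) % 4]
                        calls.append((p, b))
                    if not calls:
                        continue
                    rid = base_id if not is_split else f"{base_id}/seg{seg_no}"
                    reads.append(
                        ReducedRead(
                            read_id=rid,
                            chromosome=chrom,
                            calls=tuple(calls),
                            is_split_segment=is_split,
                            true_haplotype=hap,
                        )
                    )
    return reads


@dataclass
class SimulatedDataset:
    """A complete simulated study: truth, callable sites, reduced reads."""

    config: SimulationConfig
    truth: TruthSet
    het_positions: set[VariantPosition]
    reads: list[ReducedRead] = field(repr=False)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Truth generation, variant-call degradation and read sampling in the
    canonical order (reads never contain sites the caller missed)."""
    all_positions, truth = generate_truth(config)
    callable_sites = degrade_variant_calls(
        all_positions, config.variant_call_miss_rate, seed=config.seed + 2
    )
    reads = simulate_reads(truth, config, het_positions=callable_sites)
    return SimulatedDataset(config, truth, callable_sites, reads)


def synthetic_fastq_records(reads: Iterable[ReducedRead], seed: int = 0):
    """Random-scaffold FASTQ records for reduced reads (synthetic sequence;
    exists only so the per-haplotig FASTQ writer can be exercised)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    records = []
    for r in reads:
        ln = max(len(r.calls) * 10, 50)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=ln))
        rec = SeqRecord(Seq(seq), id=r.read_id, description="synthetic")
        rec.letter_annotations["phred_quality"] = [20] * ln
        records.append(rec)
    return records
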