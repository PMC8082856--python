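"""Truth-based accuracy/contiguity metrics and truth-free diagnostics.

With a known truth set every haplotig is assigned to the haplotype it
most closely represents, and per-haplotype SNPs are scored as true
positives (some assigned haplotig calls the correct base), false
positives (a consensus call disagreeing with the assigned haplotype) or
false negatives (truth SNPs never covered by any assigned haplotig).
All three rates share the denominator TP + FP + FN, so
accuracy + error + missing = 100 exactly.  Switch-error rate is
deliberately not reported: with phased blocks this accurate and
contiguous, raw proportions of correct/incorrect/missing calls are the
more direct statement of trustworthiness.

Without truth, two diagnostics reveal suspect clusters: windowed read
coverage per haplotig (a region phased into two haplotigs where one has
twice the depth of the other is a duplicated haplotype, not a failure)
and the in-cluster allele-frequency distribution (enrichment near 50%
marks chimeras of two equally covered haplotypes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .phaser import Cluster
from .simulate import TruthSet

__all__ = [
    "TruthSet",
    "MetricsReport",
    "assign_haplotigs",
    "compute_metrics",
    "coverage_profile",
    "allele_frequency_distribution",
    "AlleleFrequencyResult",
    "plot_haplotigs",
]

UNASSIGNED = "unknown"


@dataclass
class MetricsReport:
    """Accuracy/error/missing rates (percent, common denominator) plus
    contiguity: haplotigs per haplotype and per-(chromosome, haplotype)
    L90 — the minimal number of assigned haplotigs covering >= 90% of
    that haplotype's truth SNPs (None when 90% is unreachable)."""

    tp: int
    fp: int
    fn: int
    accuracy: float
    error: float
    missing: float
    n_haplotigs: int
    ploidy: int
    haplotigs_per_haplotype: float
    haplotigs_per_haplotype_by_chromosome: dict[str, float]
    l90: dict[tuple[str, str], int | None]
    assignment: dict[str, str]
    unassigned: list[str] = field(default_factory=list)

    @property
    def mean_chromosome_haplotigs_per_haplotype(self) -> float:
        values = list(self.haplotigs_per_haplotype_by_chromosome.values())
        return float(np.mean(values)) if values else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "error": self.error,
            "missing": self.missing,
            "n_haplotigs": self.n_haplotigs,
            "ploidy": self.ploidy,
            "haplotigs_per_haplotype": self.haplotigs_per_haplotype,
            "haplotigs_per_haplotype_by_chromosome": self.haplotigs_per_haplotype_by_chromosome,
            "l90": {f"{c}:{h}": v for (c, h), v in self.l90.items()},
            "assignment": self.assignment,
            "unassigned": self.unassigned,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key in ("tp", "fp", "fn", "accuracy", "error", "missing",
                        "n_haplotigs", "ploidy", "haplotigs_per_haplotype"):
                fh.write(f"{key}\t{getattr(self, key)}\n")
            for chrom, v in sorted(self.haplotigs_per_haplotype_by_chromosome.items()):
                fh.write(f"haplotigs_per_haplotype[{chrom}]\t{v}\n")
            for (chrom, hap), v in sorted(self.l90.items()):
                fh.write(f"L90[{chrom},{hap}]\t{v}\n")


def _rates(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    denom = tp + fp + fn
    if denom == 0:
        return 0.0, 0.0, 100.0
    return 100.0 * tp / denom, 100.0 * fp / denom, 100.0 * fn / denom


def assign_haplotigs(
    haplotigs: Sequence[Cluster], truth: TruthSet
) -> dict[str, str]:
    """Assign each haplotig to the haplotype it most closely represents.

    The haplotype maximizing the count of matching consensus calls wins;
    ties break by match fraction, then lexicographic haplotype name.
    Haplotigs with no truth-overlapping call are assigned ``unknown``
    and excluded from TP/FP accounting.
    """
    assignment: dict[str, str] = {}
    for h in haplotigs:
        best: tuple[int, float, str] | None = None
        for hap in truth.names():
            calls = truth.haplotypes[hap]
            matches = 0
            overlap = 0
            for pos, bases in h.consensus.items():
                b = calls.get((h.chromosome, pos))
                if b is None:
                    continue
                overlap += 1
                if b in bases:
                    matches += 1
            if overlap == 0:
                continue
            # tie-break: more matches, then higher match fraction, then
            # earlier name (negated comparisons via max on tuple)
            cand = (matches, matches / overlap, hap)
            if best is None:
                best = cand
            else:
                if (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1]) and cand[2] < best[2]
                ):
                    best = cand
        assignment[h.cluster_id] = best[2] if best is not None else UNASSIGNED
    return assignment


def compute_metrics(
    haplotigs: Sequence[Cluster],
    assignment: Mapping[str, str],
    truth: TruthSet,
) -> MetricsReport:
    """Score assigned haplotigs against the truth set.

    Per truth-haplotype SNP: TP when some assigned haplotig calls the
    correct base; FP counts each haplotig consensus position whose base
    set misses the assigned haplotype's truth base (tied bases count the
    position once, erroneous only if no tied base matches); FN counts
    truth SNPs covered by no assigned haplotig of their haplotype.
    """
    correct: dict[str, set[tuple[str, int]]] = {h: set() for h in truth.names()}
    covered: dict[str, set[tuple[str, int]]] = {h: set() for h in truth.names()}
    fp = 0
    unassigned: list[str] = []
    for h in haplotigs:
        hap = assignment.get(h.cluster_id, UNASSIGNED)
        if hap == UNASSIGNED:
            unassigned.append(h.cluster_id)
            continue
        calls = truth.haplotypes[hap]
        for pos, bases in h.consensus.items():
            b = calls.get((h.chromosome, pos))
            if b is None:
                continue
            covered[hap].add((h.chromosome, pos))
            if b in bases:
                correct[hap].add((h.chromosome, pos))
            else:
                fp += 1
    tp = sum(len(v) for v in correct.values())
    fn = sum(
        1
        for hap in truth.names()
        for key in truth.haplotypes[hap]
        if key not in covered[hap]
    )
    accuracy, error, missing = _rates(tp, fp, fn)

    ploidy = truth.ploidy
    chroms = sorted({c.chromosome for c in haplotigs} | {cp[0] for h in truth.haplotypes.values() for cp in h})
    by_chrom = {
        chrom: sum(1 for c in haplotigs if c.chromosome == chrom) / ploidy
        for chrom in chroms
    }

    l90: dict[tuple[str, str], int | None] = {}
    for chrom in chroms:
        for hap in truth.names():
            universe = {cp for cp in truth.haplotypes[hap] if cp[0] == chrom}
            if not universe:
                continue
            tig_cover = []
            for c in haplotigs:
                if c.chromosome != chrom or assignment.get(c.cluster_id) != hap:
                    continue
                cov = {(chrom, p) for p in c.consensus if (chrom, p) in universe}
                if cov:
                    tig_cover.append(cov)
            l90[(chrom, hap)] = _l90(universe, tig_cover)

    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        error=error,
        missing=missing,
        n_haplotigs=len(haplotigs),
        ploidy=ploidy,
        haplotigs_per_haplotype=len(haplotigs) / ploidy,
        haplotigs_per_haplotype_by_chromosome=by_chrom,
        l90=l90,
        assignment=dict(assignment),
        unassigned=sorted(unassigned),
    )


def _l90(universe: set, tig_cover: list[set]) -> int | None:
    """Greedy minimal haplotig count covering >= 90% of the universe."""
    need = math.ceil(0.9 * len(universe))
    covered: set = set()
    remaining = list(tig_cover)
    n = 0
    while len(covered) < need and remaining:
        remaining.sort(key=lambda s: -len(s - covered))
        best = remaining.pop(0)
        gain = best - covered
        if not gain:
            break
        covered |= gain
        n += 1
    return n if len(covered) >= need else None


def coverage_profile(
    clusters: Sequence[Cluster],
    window: int = 5000,
    chromosome_length: int | None = None,
    coverage_fraction: float | None = None,
) -> dict[str, np.ndarray]:
    """Windowed mean read depth per haplotig along its chromosome.

    Each member read contributes its spanned bases (between its first
    and last het call) to every overlapped window.  When
    ``coverage_fraction`` is given (e.g. 0.9), only the largest
    haplotigs jointly accounting for that fraction of all coverage are
    profiled, which mirrors how the plots are read in practice.
    """
    if not clusters:
        return {}
    chosen = list(clusters)
    if coverage_fraction is not None:
        ranked = sorted(clusters, key=lambda c: -c.total_coverage)
        total = sum(c.total_coverage for c in ranked)
        acc = 0
        chosen = []
        for c in ranked:
            chosen.append(c)
            acc += c.total_coverage
            if acc >= coverage_fraction * total:
                break
    if chromosome_length is None:
        chromosome_length = max(c.span[1] for c in chosen)
    n_windows = max(1, math.ceil(chromosome_length / window))
    out: dict[str, np.ndarray] = {}
    for c in chosen:
        depth = np.zeros(n_windows)
        for r in c.members:
            lo, hi = r.span
            w0 = (lo - 1) // window
            w1 = min((hi - 1) // window, n_windows - 1)
            for w in range(w0, w1 + 1):
                ws = w * window + 1
                we = min((w + 1) * window, chromosome_length)
                ov = min(hi, we) - max(lo, ws) + 1
                if ov > 0:
                    depth[w] += ov / (we - ws + 1)
        out[c.cluster_id] = depth
    return out


@dataclass
class AlleleFrequencyResult:
    """Per-position major allele frequencies of a cluster and a chimera
    flag raised when they are enriched near 0.5."""

    cluster_id: str
    major_frequencies: np.ndarray
    histogram: np.ndarray
    bin_edges: np.ndarray
    fraction_near_half: float
    flagged: bool


def allele_frequency_distribution(
    cluster: Cluster,
    min_depth: int = 20,
    near_half_max_major: float = 0.7,
    flag_fraction: float = 0.1,
) -> AlleleFrequencyResult:
    """Distribution of in-cluster major allele frequencies.

    Only positions covered by at least ``min_depth`` member reads
    qualify.  A pure cluster keeps major frequencies near 1.0 (sequencing
    errors are scattered minorities); a chimera of two equally covered
    haplotypes piles up near 0.5.  The cluster is flagged when more than
    ``flag_fraction`` of qualifying positions have a major frequency at
    or below ``near_half_max_major``.
    """
    counts: dict[int, dict[str, int]] = {}
    for r in cluster.members:
        for pos, base in r.calls:
            d = counts.setdefault(pos, {})
            d[base] = d.get(base, 0) + 1
    freqs = []
    for pos, t in counts.items():
        depth = sum(t.values())
        if depth < min_depth:
            continue
        freqs.append(max(t.values()) / depth)
    major = np.asarray(sorted(freqs))
    hist, edges = np.histogram(major, bins=20, range=(0.0, 1.0))
    if len(major):
        frac = float(np.mean(major <= near_half_max_major))
    else:
        frac = 0.0
    return AlleleFrequencyResult(
        cluster_id=cluster.cluster_id,
        major_frequencies=major,
        histogram=hist,
        bin_edges=edges,
        fraction_near_half=frac,
        flagged=bool(len(major)) and frac >= flag_fraction,
    )


def plot_haplotigs(
    clusters: Sequence[Cluster],
    out_path,
    assignment: Mapping[str, str] | None = None,
) -> None:
    """One subplot per chromosome; each haplotig a horizontal bar over its
    span, colored by assigned haplotype when a truth assignment exists."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({c.chromosome for c in clusters})
    if not chroms:
        return
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 2 + 1.2 * len(chroms)), squeeze=False)
    palette = plt.get_cmap("tab10")
    hap_names = sorted({assignment[c.cluster_id] for c in clusters}) if assignment else []
    color_of = {h: palette(i % 10) for i, h in enumerate(hap_names)}
    for ax, chrom in zip(axes[:, 0], chroms):
        tigs = [c for c in clusters if c.chromosome == chrom]
        tigs.sort(key=lambda c: c.span[0])
        for row, c in enumerate(tigs):
            lo, hi = c.span
            color = color_of.get(assignment.get(c.cluster_id)) if assignment else "steelblue"
            ax.plot([lo, hi], [row, row], lw=4, color=color or "grey")
        ax.set_title(chrom, fontsize=9)
        ax.set_ylabel("haplotig")
        ax.set_ylim(-1, max(1, len(tigs)))
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
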