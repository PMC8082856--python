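"""Automated cleaning of raw phasing results.

Raw clustering output tends to include short, lowly supported haplotigs
and to phase a region into fewer copies than the genome carries when two
copies are locally identical.  Cleaning addresses this in three ordered
steps: (1) discordance-gated merging — pairs of overlapping clusters are
merged, lowest hypothetical merged discordance first, while that
discordance stays below the pre-computed mean discordance of the raw
clusters; (2) removal of the clusters that jointly account for the
smallest fraction (default 1%) of total coverage; (3) gap filling —
regions covered by fewer haplotigs than the chromosome's rounded mean
haplotig multiplicity borrow a balanced random half of the reads of the
most-covered cluster there, on the presumption that the gap is a
haplotype present in more than one copy.

Discordance is the fraction of member base calls disagreeing with the
cluster consensus (the summed minor allele frequencies), so all tallies
here are read counts, not context weights.
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass
from typing import Sequence

from .phaser import Cluster, _argmax_bases
from .variantio import ReducedRead


@dataclass
class CleanOptions:
    gap_fill: bool = True
    filter_fraction: float = 0.01
    threshold_mode: str = "pooled"
    seed: int = 0


def _count_tallies(members: Sequence[ReducedRead]) -> dict[int, dict[str, int]]:
    t: dict[int, dict[str, int]] = {}
    for r in members:
        for pos, base in r.calls:
            d = t.setdefault(pos, {})
            d[base] = d.get(base, 0) + 1
    return t


def _cluster_from_members(cluster_id: str, chromosome: str, members: Sequence[ReducedRead]) -> Cluster:
    tallies = _count_tallies(members)
    consensus = {p: _argmax_bases(t) for p, t in tallies.items()}
    ordered = tuple(sorted(members, key=lambda r: r.read_id))
    weights = {r.read_id: tuple([1] * len(r.calls)) for r in ordered}
    return Cluster(cluster_id, chromosome, ordered, weights, tallies, consensus)


def _discordance_of_counts(
    counts: dict[int, dict[str, int]], consensus: dict[int, frozenset[str]]
) -> float:
    total = 0
    agree = 0
    for pos, t in counts.items():
        cons = consensus[pos]
        for base, n in t.items():
            total += n
            if base in cons:
                agree += n
    if total == 0:
        return 0.0
    return (total - agree) / total


def discordance(cluster: Cluster) -> float:
    """Fraction of member base calls that disagree with the cluster
    consensus; a call matching any tied consensus base is concordant.
    Zero for single-read clusters."""
    counts = _count_tallies(cluster.members)
    return _discordance_of_counts(counts, cluster.consensus)


def _merged_discordance(c1: Cluster, c2: Cluster) -> float:
    counts = _count_tallies(c1.members + c2.members)
    consensus = {p: _argmax_bases(t) for p, t in counts.items()}
    return _discordance_of_counts(counts, consensus)


def _pooled_discordance(clusters: Sequence[Cluster]) -> float:
    total = 0
    disagree = 0.0
    for c in clusters:
        cov = c.total_coverage
        total += cov
        disagree += discordance(c) * cov
    return disagree / total if total else 0.0


def merge_by_discordance(clusters: Sequence[Cluster], threshold_mode: str = "pooled") -> list[Cluster]:
    """Step 1: merge overlapping same-chromosome cluster pairs, lowest
    hypothetical merged discordance first, while below the mean raw
    discordance.

    The threshold is fixed before any merge.  In the default ``pooled``
    mode it is the call-weighted mean discordance of the raw clusters
    (total disagreeing calls over total calls) — the dataset's noise
    floor, which a same-haplotype merge matches and a cross-haplotype
    merge exceeds.  ``cluster_mean`` instead averages per-cluster
    discordances unweighted; tiny perfectly concordant clusters then pull
    the threshold below the noise floor and can block every merge on
    uniformly noisy data.  Merged clusters use read-count tallies (each
    read one vote) and their consensus is recomputed.  Never increases
    the number of clusters.
    """
    if not clusters:
        return []
    if threshold_mode == "pooled":
        threshold = _pooled_discordance(clusters)
    elif threshold_mode == "cluster_mean":
        threshold = sum(discordance(c) for c in clusters) / len(clusters)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    alive: dict[int, Cluster] = dict(enumerate(clusters))
    heap: list[tuple[float, int, int]] = []
    cache: dict[tuple[int, int], float] = {}

    def consider(a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        ca, cb = alive[a], alive[b]
        if ca.chromosome != cb.chromosome:
            return
        if not (set(ca.tallies) & set(cb.tallies)):
            return
        d = _merged_discordance(ca, cb)
        if d < threshold:
            cache[(a, b)] = d
            heapq.heappush(heap, (d, a, b))

    ids = list(alive)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            consider(a, b)

    next_id = len(clusters)
    merge_no = 0
    while heap:
        d, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        ca, cb = alive.pop(a), alive.pop(b)
        merge_no += 1
        merged = _cluster_from_members(
            f"{ca.chromosome}_m{merge_no:04d}", ca.chromosome, ca.members + cb.members
        )
        alive[next_id] = merged
        for other in list(alive):
            if other != next_id:
                consider(other, next_id)
        next_id += 1
    out = list(alive.values())
    out.sort(key=lambda c: (c.chromosome, c.span[0], c.cluster_id))
    return out


def filter_low_coverage(clusters: Sequence[Cluster], fraction: float = 0.01) -> list[Cluster]:
    """Step 2: drop clusters from the smallest up while the cumulative
    removed coverage stays within ``fraction`` of total coverage.  At
    least one cluster is always retained.  Coverage of a cluster is the
    summed het-position count of its member reads."""
    if not clusters:
        return []
    ranked = sorted(clusters, key=lambda c: (c.total_coverage, c.cluster_id))
    total = sum(c.total_coverage for c in ranked)
    budget = fraction * total
    removed = 0.0
    out = list(ranked)
    while len(out) > 1 and removed + out[0].total_coverage <= budget:
        removed += out[0].total_coverage
        out.pop(0)
    out.sort(key=lambda c: (c.chromosome, c.span[0], c.cluster_id))
    return out


def _multiplicity(clusters: Sequence[Cluster], universe: Sequence[int]) -> list[int]:
    spans = [c.span for c in clusters]
    return [sum(1 for lo, hi in spans if lo <= p <= hi) for p in universe]


#: Deficit regions spanning fewer het positions than this are treated as
#: haplotig span-placement raggedness, not as a missing haplotype copy.
MIN_GAP_POSITIONS = 10


def fill_gaps(
    clusters: Sequence[Cluster],
    chromosome: str | None = None,
    seed: int = 0,
    min_region_positions: int = MIN_GAP_POSITIONS,
    min_region_bp: float | None = None,
) -> list[Cluster]:
    """Step 3: duplicate-haplotype gap filling.

    Per chromosome, each haplotig counts as 1X of haplotig coverage over
    the het positions inside its span; the chromosome's expected
    multiplicity n is the rounded mean, fixed before any split.  Every
    maximal run of at least ``min_region_positions`` het positions
    covered by fewer than n haplotigs is filled by splitting the reads
    that the region's most-covered cluster has there into two balanced
    random halves (seeded), one of which becomes a new haplotig —
    presuming the gap is a large region where a haplotype is present in
    more than one genomic copy.  A region only qualifies when it spans at
    least ``min_region_bp`` bases (default: the median member-read span —
    a deficit too short to hold a single read cannot evidence a missing
    haplotype and is span-placement raggedness, typical at chromosome
    ends).  Unfillable regions and regions whose best donor has fewer
    than two reads are left alone.  The read multiset is conserved.
    """
    by_chrom: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)
    out: list[Cluster] = []
    for chrom in sorted(by_chrom):
        if chromosome is not None and chrom != chromosome:
            out.extend(by_chrom[chrom])
            continue
        out.extend(
            _fill_gaps_chrom(by_chrom[chrom], chrom, seed, min_region_positions, min_region_bp)
        )
    out.sort(key=lambda c: (c.chromosome, c.span[0], c.cluster_id))
    return out


def _median_read_span(clusters: Sequence[Cluster]) -> float:
    spans = sorted(r.span[1] - r.span[0] + 1 for c in clusters for r in c.members)
    if not spans:
        return 0.0
    mid = len(spans) // 2
    return float(spans[mid]) if len(spans) % 2 else (spans[mid - 1] + spans[mid]) / 2.0


def _fill_gaps_chrom(
    clusters: list[Cluster],
    chrom: str,
    seed: int,
    min_region_positions: int,
    min_region_bp: float | None,
) -> list[Cluster]:
    rng = random.Random(f"{seed}:fill:{chrom}")
    work = list(clusters)
    universe = sorted({p for c in work for p in c.tallies})
    if not universe:
        return work
    # the chromosome's expected haplotig multiplicity, fixed before any
    # split (splits add haplotigs and must not inflate their own target)
    mult = _multiplicity(work, universe)
    n = int(sum(mult) / len(mult) + 0.5)
    if min_region_bp is None:
        min_region_bp = _median_read_span(work)
    fill_no = 0
    unresolvable: set[tuple[int, int]] = set()
    while True:
        mult = _multiplicity(work, universe)
        # maximal runs of consecutive universe positions below n
        region: tuple[int, int] | None = None
        start = None
        run_len = 0
        for p, m in zip(universe, mult):
            if m < n:
                if start is None:
                    start = p
                    run_len = 0
                end = p
                run_len += 1
            else:
                if (
                    start is not None
                    and run_len >= min_region_positions
                    and end - start + 1 >= min_region_bp
                    and (start, end) not in unresolvable
                ):
                    region = (start, end)
                    break
                start = None
        if (
            region is None
            and start is not None
            and run_len >= min_region_positions
            and end - start + 1 >= min_region_bp
            and (start, end) not in unresolvable
        ):
            region = (start, end)
        if region is None:
            return work
        lo, hi = region
        # donor: cluster with the most member-read calls inside the region
        def region_reads(c: Cluster) -> list[ReducedRead]:
            return [r for r in c.members if any(lo <= p <= hi for p, _ in r.calls)]

        def region_cov(c: Cluster) -> int:
            return sum(
                1 for r in c.members for p, _ in r.calls if lo <= p <= hi
            )

        donor = max(work, key=lambda c: (region_cov(c), c.cluster_id))
        movable = region_reads(donor)
        if len(movable) < 2 or region_cov(donor) == 0:
            unresolvable.add(region)
            continue
        movable = sorted(movable, key=lambda r: r.read_id)
        rng.shuffle(movable)
        half = len(movable) // 2
        leaving = set(r.read_id for r in movable[:half])
        stay = [r for r in donor.members if r.read_id not in leaving]
        go = [r for r in donor.members if r.read_id in leaving]
        fill_no += 1
        work = [c for c in work if c is not donor]
        work.append(_cluster_from_members(donor.cluster_id, chrom, stay))
        work.append(_cluster_from_members(f"{donor.cluster_id}_fill{fill_no}", chrom, go))


def clean(clusters: Sequence[Cluster], options: CleanOptions | None = None) -> list[Cluster]:
    """The full cleaning pass: merge, filter, and (optionally) fill gaps.

    Gap filling can be disabled (``options.gap_fill = False``) for very
    fragmented raw results, where splitting donors is more likely to
    manufacture haplotigs than to recover duplicated haplotypes.
    """
    options = options if options is not None else CleanOptions()
    if not clusters:
        return []
    out = merge_by_discordance(clusters, options.threshold_mode)
    out = filter_low_coverage(out, options.filter_fraction)
    if options.gap_fill:
        out = fill_gaps(out, seed=options.seed)
    return out
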