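"""The iterative, ploidy-agnostic read-clustering engine.

Every reduced read starts as a singleton cluster.  At each step the most
similar allowed pair of clusters is merged — similarity is the fraction
of shared heterozygous positions at which the two consensus sequences
agree — and the merged cluster's consensus is recomputed by letting every
member read vote with its pre-calculated context-coverage weight.  A
merge is vetoed when it would change the clusters' identities too much
(see :func:`identity_change`); when no allowed pair remains, the
surviving clusters are the haplotigs.  No ploidy is supplied or inferred
anywhere: the number of clusters per region emerges from the data.

The module exposes the individual rules (:func:`similarity`,
:func:`pair_allowed`, :func:`identity_change`, :func:`merge_clusters`,
:func:`select_best_pair`) on dict-based :class:`Cluster` objects, and a
fast array-backed engine behind :func:`run_phasing` whose incremental
candidate caching is contractually identical to re-scoring every pair
from scratch at every step.
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .context import ContextCoverageTable, read_weights
from .variantio import BASES, ReducedRead

_BASE_CODE = {b: i for i, b in enumerate(BASES)}

IDENTITY_MODES = ("per_cluster", "summed")


@dataclass
class PhaseParams:
    """Tunable thresholds of the clustering engine.

    min_similarity (S) and min_overlap_fraction (O) gate which pairs may
    merge at all; max_id_change (ID) is the identity-maintenance veto;
    min_cluster_reads (L) filters the final clusters.  Two clusters must
    share at least ``min_overlap_count`` heterozygous positions to be
    compared, and the O rule is ignored above
    ``overlap_ignore_threshold`` shared positions.
    """

    min_similarity: float = 0.01
    min_overlap_fraction: float = 0.1
    min_cluster_reads: int = 0
    max_id_change: float = 0.05
    min_overlap_count: int = 10
    overlap_ignore_threshold: int = 100
    rng_seed: int = 0
    identity_mode: str = "per_cluster"

    def __post_init__(self) -> None:
        for name in ("min_similarity", "min_overlap_fraction", "max_id_change"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_cluster_reads", "min_overlap_count", "overlap_ignore_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.identity_mode not in IDENTITY_MODES:
            raise ValueError(f"identity_mode must be one of {IDENTITY_MODES}")


@dataclass
class Cluster:
    """A set of reads with weighted per-position vote tallies.

    ``consensus[p]`` is always the argmax set of ``tallies[p]`` (ties
    keep every tied base).  All members lie on one chromosome.
    """

    cluster_id: str
    chromosome: str
    members: tuple[ReducedRead, ...]
    member_weights: dict[str, tuple[int, ...]]
    tallies: dict[int, dict[str, int]]
    consensus: dict[int, frozenset[str]]

    @property
    def member_read_ids(self) -> frozenset[str]:
        return frozenset(r.read_id for r in self.members)

    @property
    def n_reads(self) -> int:
        return len(self.members)

    @property
    def covered_positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.consensus))

    @property
    def span(self) -> tuple[int, int]:
        pos = self.covered_positions
        return pos[0], pos[-1]

    @property
    def total_coverage(self) -> int:
        """Sum over member reads of het positions covered."""
        return sum(len(r.calls) for r in self.members)

    @classmethod
    def from_reads(
        cls,
        cluster_id: str,
        reads: Sequence[ReducedRead],
        table: ContextCoverageTable | None = None,
    ) -> "Cluster":
        """Build a cluster by letting ``reads`` vote position by position.

        Weights come from the context table (or from precomputed
        ``read.weights``); without a table every call votes with weight
        1 — the read-count tallies used by the cleaning stage.
        """
        if not reads:
            raise ValueError("cluster must contain at least one read")
        chroms = {r.chromosome for r in reads}
        if len(chroms) > 1:
            raise ValueError(f"cluster members span chromosomes {sorted(chroms)}")
        weights_map: dict[str, tuple[int, ...]] = {}
        tallies: dict[int, dict[str, int]] = {}
        for r in reads:
            if table is not None or r.weights is not None:
                w = read_weights(r, table) if r.weights is None else r.weights
            else:
                w = tuple([1] * len(r.calls))
            weights_map[r.read_id] = w
            for (pos, base), wt in zip(r.calls, w):
                tallies.setdefault(pos, {})[base] = tallies.get(pos, {}).get(base, 0) + wt
        consensus = {p: _argmax_bases(t) for p, t in tallies.items()}
        members = tuple(sorted(reads, key=lambda r: r.read_id))
        return cls(cluster_id, chroms.pop(), members, weights_map, tallies, consensus)

    def to_haplotig_record(self):
        from .variantio import HaplotigRecord

        rows = []
        for pos in sorted(self.consensus):
            for base in sorted(self.consensus[pos]):
                rows.append((pos, base))
        return HaplotigRecord(
            haplotig_id=self.cluster_id,
            chromosome=self.chromosome,
            consensus_calls=tuple(rows),
            member_read_ids=tuple(sorted(self.member_read_ids)),
        )


def _argmax_bases(tally: Mapping[str, int]) -> frozenset[str]:
    top = max(tally.values())
    return frozenset(b for b, v in tally.items() if v == top)


def _as_consensus(x: "Cluster | ReducedRead") -> tuple[str, dict[int, frozenset[str]]]:
    if isinstance(x, ReducedRead):
        return x.chromosome, {p: frozenset((b,)) for p, b in x.calls}
    return x.chromosome, x.consensus


def _n_covered(x: "Cluster | ReducedRead") -> int:
    if isinstance(x, ReducedRead):
        return len(x.calls)
    return len(x.consensus)


# ---------------------------------------------------------------------------
# Pairwise rules
# ---------------------------------------------------------------------------

def similarity(a, b) -> tuple[float, int] | None:
    """Similarity of two call sequences (reads or cluster consensuses).

    Returns (S, n_shared_positions) with S = shared variants / shared
    positions; a shared position counts as a shared variant when the base
    sets intersect (relevant for tied consensus positions).  Returns None
    — the no-overlap signal — for different chromosomes or disjoint
    position sets.
    """
    chrom_a, cons_a = _as_consensus(a)
    chrom_b, cons_b = _as_consensus(b)
    if chrom_a != chrom_b:
        return None
    if len(cons_b) < len(cons_a):
        cons_a, cons_b = cons_b, cons_a
    shared = 0
    match = 0
    for pos, bases in cons_a.items():
        other = cons_b.get(pos)
        if other is not None:
            shared += 1
            if bases & other:
                match += 1
    if shared == 0:
        return None
    return match / shared, shared


def pair_allowed(a, b, params: PhaseParams) -> bool:
    """Whether two call sequences overlap enough to be compared for merging.

    Requires ``min_overlap_count`` shared heterozygous positions, similarity
    at least S, and — unless the shared count exceeds the ignore threshold —
    a shared fraction of at least O of the positions covered by the smaller
    sequence ("smaller" = fewer covered het positions, not shorter).
    """
    sim = similarity(a, b)
    if sim is None:
        return False
    s, n_shared = sim
    return _allowed(s, n_shared, _n_covered(a), _n_covered(b), params)


def _allowed(s: float, n_shared: int, size_a: int, size_b: int, params: PhaseParams) -> bool:
    if n_shared < params.min_overlap_count:
        return False
    if s < params.min_similarity:
        return False
    if n_shared > params.overlap_ignore_threshold:
        return True
    smaller = min(size_a, size_b)
    return n_shared / smaller >= params.min_overlap_fraction


def ordered_candidate_pairs(
    candidates: Iterable[tuple[tuple, float, int]],
    rng: random.Random,
) -> list[tuple]:
    """The best-first tie-break ordering of the top-scoring candidates.

    ``candidates`` yields (pair_key, S, n_shared).  The pairs with the
    highest S win; ties go to the larger shared-position count; pairs
    still tied are ordered uniformly at random (seeded rng), after a
    deterministic sort so the shuffle is reproducible.  Returns the
    shuffled top tier only.
    """
    best: tuple[float, int] | None = None
    tier: list[tuple] = []
    for key, s, n in candidates:
        score = (s, n)
        if best is None or score > best:
            best = score
            tier = [key]
        elif score == best:
            tier.append(key)
    tier.sort()
    if len(tier) > 1:
        rng.shuffle(tier)
    return tier


def select_best_pair(
    candidates: Iterable[tuple[tuple, float, int]],
    rng: random.Random,
):
    """Pick the merge candidate: max S, then max shared positions, then a
    uniformly random (seeded) choice.  Returns None on an empty candidate
    set — the termination signal."""
    tier = ordered_candidate_pairs(candidates, rng)
    return tier[0] if tier else None


def identity_change(c1: Cluster, c2: Cluster, mode: str = "per_cluster") -> float | None:
    """How much merging would erode the two clusters' identities.

    Over the common region (positions covered by both), a cluster's
    consensus base loses the other cluster's votes wherever those votes
    back a different base — counted even if the base stays consensus
    after the merge; votes that reinforce a consensus base (positive
    changes) contribute nothing.  In ``per_cluster`` mode each cluster's
    lost votes are normalized by its own votes in the common region and
    the smaller of the two changes is returned, so a merge is vetoed only
    when it perturbs *both* clusters — a handful of noisy reads cannot be
    kept out of a deep cluster, but two well-supported distinct
    haplotypes can never swallow each other.  In ``summed`` mode the
    pooled lost votes are divided by the pooled common-region votes.
    Returns None (no-overlap signal) when the clusters share no position.
    """
    if mode not in IDENTITY_MODES:
        raise ValueError(f"mode must be one of {IDENTITY_MODES}")
    common = set(c1.tallies) & set(c2.tallies)
    if not common:
        return None
    lost1 = lost2 = own1 = own2 = 0
    for pos in common:
        t1 = c1.tallies[pos]
        t2 = c2.tallies[pos]
        cons1 = c1.consensus[pos]
        cons2 = c2.consensus[pos]
        own1 += sum(t1.values())
        own2 += sum(t2.values())
        lost1 += sum(w for b, w in t2.items() if b not in cons1)
        lost2 += sum(w for b, w in t1.items() if b not in cons2)
    if mode == "summed":
        return (lost1 + lost2) / (own1 + own2)
    return min(lost1 / own1, lost2 / own2)


def merge_clusters(c1: Cluster, c2: Cluster, cluster_id: str | None = None) -> Cluster:
    """Union of two clusters: members pooled, vote tallies summed, and the
    consensus recomputed as the per-position argmax set (ties keep all
    tied bases)."""
    if c1.chromosome != c2.chromosome:
        raise ValueError("cannot merge clusters across chromosomes")
    tallies: dict[int, dict[str, int]] = {}
    for src in (c1.tallies, c2.tallies):
        for pos, t in src.items():
            dst = tallies.setdefault(pos, {})
            for base, w in t.items():
                dst[base] = dst.get(base, 0) + w
    consensus = {p: _argmax_bases(t) for p, t in tallies.items()}
    members = tuple(sorted(c1.members + c2.members, key=lambda r: r.read_id))
    weights = {**c1.member_weights, **c2.member_weights}
    cid = cluster_id if cluster_id is not None else f"{c1.cluster_id}+{c2.cluster_id}"
    return Cluster(cid, c1.chromosome, members, weights, tallies, consensus)


# ---------------------------------------------------------------------------
# Array-backed engine
# ---------------------------------------------------------------------------

class _EC:
    """Engine-internal cluster: consensus bitmask + weighted tallies over
    the chromosome's het-position index."""

    __slots__ = ("cid", "rows", "mask", "tally", "imin", "imax", "ncov")

    def __init__(self, cid, rows, mask, tally, imin, imax, ncov):
        self.cid = cid
        self.rows = rows
        self.mask = mask
        self.tally = tally
        self.imin = imin
        self.imax = imax
        self.ncov = ncov


def _score(a: _EC, b: _EC) -> tuple[float, int] | None:
    lo = max(a.imin, b.imin)
    hi = min(a.imax, b.imax)
    if lo > hi:
        return None
    am = a.mask[lo : hi + 1]
    bm = b.mask[lo : hi + 1]
    n_match = int(np.count_nonzero(am & bm))
    n_shared = int(np.count_nonzero((am != 0) & (bm != 0)))
    if n_shared == 0:
        return None
    return n_match / n_shared, n_shared


def _identity(a: _EC, b: _EC, mode: str) -> float | None:
    lo = max(a.imin, b.imin)
    hi = min(a.imax, b.imax)
    if lo > hi:
        return None
    am = a.mask[lo : hi + 1]
    bm = b.mask[lo : hi + 1]
    common = (am != 0) & (bm != 0)
    if not common.any():
        return None
    ta = a.tally[lo : hi + 1]
    tb = b.tally[lo : hi + 1]
    own1 = int(ta[common].sum())
    own2 = int(tb[common].sum())
    lost1 = lost2 = 0
    for code in range(4):
        bit = np.uint8(1 << code)
        lost1 += int(tb[common & ((am & bit) == 0), code].sum())
        lost2 += int(ta[common & ((bm & bit) == 0), code].sum())
    if mode == "summed":
        return (lost1 + lost2) / (own1 + own2)
    return min(lost1 / own1, lost2 / own2)


def _consensus_mask(tally: np.ndarray) -> np.ndarray:
    top = tally.max(axis=1)
    mask = np.zeros(tally.shape[0], dtype=np.uint8)
    covered = top > 0
    for code in range(4):
        mask |= (((tally[:, code] == top) & covered) << code).astype(np.uint8)
    return mask


def _phase_chromosome(
    chrom: str,
    reads: list[ReducedRead],
    table: ContextCoverageTable | None,
    params: PhaseParams,
    rng: random.Random,
    merge_log: list | None,
) -> list[Cluster]:
    universe = sorted({p for r in reads for p, _ in r.calls})
    pos_index = {p: i for i, p in enumerate(universe)}
    npos = len(universe)

    weight_of: list[tuple[int, ...]] = []
    clusters: dict[int, _EC] = {}
    for cid, r in enumerate(reads):
        w = read_weights(r, table) if table is not None or r.weights is not None else tuple([1] * len(r.calls))
        weight_of.append(w)
        idx = np.fromiter((pos_index[p] for p, _ in r.calls), dtype=np.int64, count=len(r.calls))
        codes = np.fromiter((_BASE_CODE[b] for _, b in r.calls), dtype=np.int64, count=len(r.calls))
        mask = np.zeros(npos, dtype=np.uint8)
        mask[idx] = np.uint8(1) << codes.astype(np.uint8)
        tally = np.zeros((npos, 4), dtype=np.int64)
        tally[idx, codes] = np.asarray(w, dtype=np.int64)
        clusters[cid] = _EC(cid, [cid], mask, tally, int(idx[0]), int(idx[-1]), len(idx))

    heap: list[tuple[float, int, int, int]] = []
    scores: dict[tuple[int, int], tuple[float, int]] = {}
    forbidden: set[tuple[int, int]] = set()

    def consider(a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        ca, cb = clusters[a], clusters[b]
        sc = _score(ca, cb)
        if sc is None:
            return
        s, n_shared = sc
        if _allowed(s, n_shared, ca.ncov, cb.ncov, params):
            scores[(a, b)] = (s, n_shared)
            heapq.heappush(heap, (-s, -n_shared, a, b))

    # initial candidates: sweep over span-overlapping pairs
    order = sorted(clusters, key=lambda c: (clusters[c].imin, c))
    for i, a in enumerate(order):
        amax = clusters[a].imax
        for b in order[i + 1 :]:
            if clusters[b].imin > amax:
                break
            consider(a, b)

    next_id = len(reads)
    step = 0
    while heap:
        key0 = (heap[0][0], heap[0][1])
        tier: list[tuple[int, int]] = []
        while heap and (heap[0][0], heap[0][1]) == key0:
            _, _, a, b = heapq.heappop(heap)
            if a in clusters and b in clusters and (a, b) not in forbidden:
                tier.append((a, b))
        if not tier:
            continue
        tier.sort()
        if len(tier) > 1:
            rng.shuffle(tier)
        merged_at = None
        for k, (a, b) in enumerate(tier):
            ic = _identity(clusters[a], clusters[b], params.identity_mode)
            if ic is None or ic > params.max_id_change:
                forbidden.add((a, b))
                continue
            ca, cb = clusters.pop(a), clusters.pop(b)
            tally = ca.tally + cb.tally
            mask = _consensus_mask(tally)
            nc = _EC(
                next_id,
                ca.rows + cb.rows,
                mask,
                tally,
                min(ca.imin, cb.imin),
                max(ca.imax, cb.imax),
                int(np.count_nonzero(mask)),
            )
            clusters[next_id] = nc
            if merge_log is not None:
                s, n_shared = scores[(a, b)]
                merge_log.append(
                    {
                        "chromosome": chrom,
                        "step": step,
                        "pair": (a, b),
                        "similarity": s,
                        "n_shared": n_shared,
                        "identity_change": ic,
                        "new_cluster": next_id,
                    }
                )
            step += 1
            merged_at = k
            for other in list(clusters):
                if other != next_id:
                    consider(other, next_id)
            next_id += 1
            break
        if merged_at is not None:
            for pair in tier[merged_at + 1 :]:
                a, b = pair
                if a in clusters and b in clusters:
                    s, n_shared = scores[pair]
                    heapq.heappush(heap, (-s, -n_shared, a, b))

    out = []
    for cid in sorted(clusters):
        ec = clusters[cid]
        member_reads = [reads[i] for i in ec.rows]
        weights_map = {reads[i].read_id: weight_of[i] for i in ec.rows}
        tallies: dict[int, dict[str, int]] = {}
        rows_idx, codes_idx = np.nonzero(ec.tally)
        for ri, ci in zip(rows_idx.tolist(), codes_idx.tolist()):
            tallies.setdefault(universe[ri], {})[BASES[ci]] = int(ec.tally[ri, ci])
        consensus: dict[int, frozenset[str]] = {}
        for i in np.nonzero(ec.mask)[0].tolist():
            m = int(ec.mask[i])
            consensus[universe[i]] = frozenset(BASES[c] for c in range(4) if m & (1 << c))
        out.append(
            Cluster(
                cluster_id=f"{chrom}_c{cid:05d}",
                chromosome=chrom,
                members=tuple(sorted(member_reads, key=lambda r: r.read_id)),
                member_weights=weights_map,
                tallies=tallies,
                consensus=consensus,
            )
        )
    out.sort(key=lambda c: (c.span[0], c.cluster_id))
    return out


def run_phasing(
    reads: Sequence[ReducedRead],
    context_table: ContextCoverageTable | None,
    params: PhaseParams | None = None,
    merge_log: list | None = None,
) -> list[Cluster]:
    """Cluster reduced reads into haplotigs, chromosome by chromosome.

    Greedy loop: every read starts as a singleton cluster; the best
    allowed pair whose identity change passes the ID veto is merged until
    no allowed pair remains.  Reads from different reference chromosomes
    are never combined.  Clusters with fewer than ``min_cluster_reads``
    members are dropped from the output (the L parameter); with L = 0 the
    result is a partition of the input reads.

    The random seed only breaks exact score ties, so identical inputs and
    seed give identical cluster membership and consensus.  Pass a list as
    ``merge_log`` to receive one record per merge for audit.
    """
    params = params if params is not None else PhaseParams()
    if not reads:
        return []
    by_chrom: dict[str, list[ReducedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chromosome, []).append(r)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        creads = sorted(by_chrom[chrom], key=lambda r: (r.calls[0][0], r.read_id))
        rng = random.Random(f"{params.rng_seed}:{chrom}")
        clusters.extend(
            _phase_chromosome(chrom, creads, context_table, params, rng, merge_log)
        )
    min_reads = max(1, params.min_cluster_reads)
    return [c for c in clusters if c.n_reads >= min_reads]
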