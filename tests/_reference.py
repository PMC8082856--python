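"""Independent brute-force oracles used only by the test suite.

The phasing oracle re-scores every cluster pair from scratch at every
step using plain dict arithmetic (no caching, no arrays), following the
same selection protocol as the engine: best (similarity, shared) tier,
deterministic sort, seeded shuffle, identity gate, merge.  Agreement of
final partitions proves the engine's incremental candidate cache is
equivalent to full recomputation.
"""

from __future__ import annotations

import random

from haploclust.context import read_weights


def _consensus(tally):
    out = {}
    for pos, t in tally.items():
        top = max(t.values())
        out[pos] = frozenset(b for b, v in t.items() if v == top)
    return out


class _RefCluster:
    def __init__(self, cid, reads, weights):
        self.cid = cid
        self.reads = list(reads)
        tally = {}
        for r, w in zip(reads, weights):
            for (pos, base), wt in zip(r.calls, w):
                tally.setdefault(pos, {}).setdefault(base, 0)
                tally[pos][base] += wt
        self.tally = tally
        self.weights = list(weights)
        self.cons = _consensus(tally)


def _similarity(a: _RefCluster, b: _RefCluster):
    shared = 0
    match = 0
    small, big = (a, b) if len(a.cons) <= len(b.cons) else (b, a)
    for pos, bases in small.cons.items():
        other = big.cons.get(pos)
        if other is not None:
            shared += 1
            if bases & other:
                match += 1
    if shared == 0:
        return None
    return match / shared, shared


def _allowed(s, n_shared, size_a, size_b, params):
    if n_shared < params.min_overlap_count:
        return False
    if s < params.min_similarity:
        return False
    if n_shared > params.overlap_ignore_threshold:
        return True
    return n_shared / min(size_a, size_b) >= params.min_overlap_fraction


def _identity(a: _RefCluster, b: _RefCluster, mode):
    common = set(a.tally) & set(b.tally)
    if not common:
        return None
    lost_a = lost_b = own_a = own_b = 0
    for pos in common:
        own_a += sum(a.tally[pos].values())
        own_b += sum(b.tally[pos].values())
        lost_a += sum(w for base, w in b.tally[pos].items() if base not in a.cons[pos])
        lost_b += sum(w for base, w in a.tally[pos].items() if base not in b.cons[pos])
    if mode == "summed":
        return (lost_a + lost_b) / (own_a + own_b)
    return min(lost_a / own_a, lost_b / own_b)


def reference_phase(reads, table, params):
    """Exhaustive re-scoring clustering; returns the partition as a set of
    frozensets of read ids."""
    partitions = []
    by_chrom = {}
    for r in reads:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in sorted(by_chrom):
        creads = sorted(by_chrom[chrom], key=lambda r: (r.calls[0][0], r.read_id))
        rng = random.Random(f"{params.rng_seed}:{chrom}")
        clusters = {
            i: _RefCluster(i, [r], [read_weights(r, table)])
            for i, r in enumerate(creads)
        }
        next_id = len(creads)
        forbidden = set()
        while True:
            # score every alive pair from scratch
            scored = {}
            ids = sorted(clusters)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    if (a, b) in forbidden:
                        continue
                    sim = _similarity(clusters[a], clusters[b])
                    if sim is None:
                        continue
                    s, n = sim
                    if _allowed(s, n, len(clusters[a].cons), len(clusters[b].cons), params):
                        scored[(a, b)] = (s, n)
            merged = False
            while scored:
                best = max(scored.values())
                tier = sorted(p for p, sc in scored.items() if sc == best)
                if len(tier) > 1:
                    rng.shuffle(tier)
                for a, b in tier:
                    ic = _identity(clusters[a], clusters[b], params.identity_mode)
                    if ic is None or ic > params.max_id_change:
                        forbidden.add((a, b))
                        continue
                    ca = clusters.pop(a)
                    cb = clusters.pop(b)
                    clusters[next_id] = _RefCluster(
                        next_id, ca.reads + cb.reads, ca.weights + cb.weights
                    )
                    next_id += 1
                    merged = True
                    break
                if merged:
                    break
                for p in tier:
                    scored.pop(p, None)
            if not merged:
                break
        for c in clusters.values():
            partitions.append(frozenset(r.read_id for r in c.reads))
    return set(partitions)


def brute_force_subset_filter(reads):
    """Quadratic reference for subset-read removal (keeps one
    representative among identical reads, ordered deterministically)."""
    order = sorted(reads, key=lambda r: (-len(r.calls), r.read_id))
    kept = []
    for r in order:
        rset = r.call_set()
        if any(
            q.chromosome == r.chromosome and rset <= q.call_set() for q in kept
        ):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.chromosome, r.calls[0][0], r.read_id))
    return kept
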