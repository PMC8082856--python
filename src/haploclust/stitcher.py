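"""Second-pass stitching of haplotigs with split-read segments.

Reads whose alignment breaks into distant segments usually signal a
structural variant between the sample and the reference.  Trusted
blindly they create chimeric haplotigs, so only their most trustworthy
calls are used: the heterozygous SNPs at the edges of the first-pass
clusters, where a structural variant is expected to have interrupted a
haplotig.  Each split segment is restricted to those edge SNPs and the
clustering is re-run with the restricted segments included.  Merging
across reference chromosomes remains forbidden, so split reads can only
improve the contiguity of haplotigs on the same chromosome.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .context import ContextCoverageTable, read_weights
from .phaser import Cluster, PhaseParams, run_phasing
from .variantio import ReducedRead, VariantPosition

DEFAULT_EDGE_SIZE = 10


def auto_edge_size(clusters: Sequence[Cluster], params: PhaseParams | None = None) -> int:
    """Edge extent sized so that stitching merges can pass the O rule.

    A restricted split read shares at most ``edge_size`` positions with a
    haplotig, and once absorbed into one block it offers the other block
    exactly that many shared positions; the minimum-overlap rule then
    requires edge_size >= O times the smaller block's covered positions.
    Sizing the edge at O times the *largest* first-pass cluster (with the
    minimal-overlap count as a floor) guarantees the closure merge is
    never rejected for insufficient overlap, whatever the merge order.
    """
    params = params if params is not None else PhaseParams()
    if not clusters:
        return DEFAULT_EDGE_SIZE
    biggest = max(len(c.consensus) for c in clusters)
    import math

    return max(DEFAULT_EDGE_SIZE, params.min_overlap_count,
               math.ceil(params.min_overlap_fraction * biggest))


def find_edge_snps(clusters: Sequence[Cluster], edge_size: int = DEFAULT_EDGE_SIZE) -> set[VariantPosition]:
    """The first and last ``edge_size`` covered het positions of every
    first-pass cluster (all positions of clusters covering fewer)."""
    out: set[VariantPosition] = set()
    for c in clusters:
        pos = c.covered_positions
        edge = set(pos[:edge_size]) | set(pos[-edge_size:])
        out.update(VariantPosition(c.chromosome, p) for p in edge)
    return out


def _source_id(read_id: str) -> str:
    """Segments of one underlying read share the id before any "/seg"
    suffix (the convention used by alignment reduction and simulation)."""
    return read_id.split("/seg")[0]


def restrict_split_reads(
    split_reads: Iterable[ReducedRead],
    edge_snps: set[VariantPosition],
    context_table: ContextCoverageTable | None = None,
) -> list[ReducedRead]:
    """Reduce each split read to its calls at cluster-edge SNPs.

    Same-chromosome segments of one underlying read are rejoined into a
    single reduced read first — the whole point of a split read is that
    one molecule links SNPs on both sides of a structural-variant
    breakpoint; kept apart, its segments could never stitch two
    haplotigs.  Reads left with fewer than two edge calls are dropped (a
    single call cannot link anything).  When a context table is given,
    each surviving call keeps the vote weight it had in its full
    segment, so the second pass does not need a rebuilt table.
    """
    keys = {(vp.chromosome, vp.position) for vp in edge_snps}
    groups: dict[tuple[str, str], list[ReducedRead]] = {}
    for r in split_reads:
        if not r.is_split_segment:
            raise ValueError(f"read {r.read_id} is not a split segment")
        groups.setdefault((_source_id(r.read_id), r.chromosome), []).append(r)

    out: list[ReducedRead] = []
    for (source, chrom), segments in sorted(groups.items()):
        calls: dict[int, str] = {}
        weights: dict[int, int] = {}
        have_weights = True
        labels = {s.true_haplotype for s in segments}
        for s in sorted(segments, key=lambda x: x.calls[0][0]):
            w = read_weights(s, context_table) if context_table is not None else s.weights
            if w is None:
                have_weights = False
            for i, (pos, base) in enumerate(s.calls):
                if (chrom, pos) not in keys:
                    continue
                if pos in calls and calls[pos] != base:
                    # segments disagreeing at one site: untrustworthy, drop it
                    calls.pop(pos)
                    weights.pop(pos, None)
                    continue
                calls[pos] = base
                if w is not None:
                    weights[pos] = w[i]
        if len(calls) < 2:
            continue
        ordered = tuple(sorted(calls.items()))
        out.append(
            ReducedRead(
                read_id=f"{source}/stitch",
                chromosome=chrom,
                calls=ordered,
                is_split_segment=True,
                true_haplotype=labels.pop() if len(labels) == 1 else None,
                weights=tuple(weights[p] for p, _ in ordered) if have_weights else None,
            )
        )
    return out


def rerun_with_split(
    first_pass_reads: Sequence[ReducedRead],
    restricted_split_reads: Sequence[ReducedRead],
    context_table: ContextCoverageTable | None,
    params: PhaseParams | None = None,
    merge_log: list | None = None,
) -> list[Cluster]:
    """Re-run the clustering with the restricted split segments included.

    Cross-chromosome merging is still impossible — segments mapping to
    different chromosomes can never join one cluster — so stitching only
    raises same-chromosome contiguity."""
    return run_phasing(
        list(first_pass_reads) + list(restricted_split_reads),
        context_table,
        params,
        merge_log=merge_log,
    )


def phase_with_stitching(
    reads: Sequence[ReducedRead],
    context_table: ContextCoverageTable | None,
    params: PhaseParams | None = None,
    edge_size: int | None = None,
    use_split_reads: bool = True,
    merge_log: list | None = None,
) -> tuple[list[Cluster], list[Cluster]]:
    """First pass on non-split reads, then the stitching pass.

    Returns (first_pass_clusters, final_clusters).  ``edge_size=None``
    sizes the edge regions automatically from the first-pass clusters
    (see :func:`auto_edge_size`).  With no split segments in the input
    (or stitching disabled) the final clusters are the first pass
    unchanged.
    """
    full_reads = [r for r in reads if not r.is_split_segment]
    split_reads = [r for r in reads if r.is_split_segment]
    first = run_phasing(full_reads, context_table, params, merge_log=merge_log)
    if not use_split_reads or not split_reads:
        return first, first
    if edge_size is None:
        edge_size = auto_edge_size(first, params)
    edges = find_edge_snps(first, edge_size)
    restricted = restrict_split_reads(split_reads, edges, context_table)
    if not restricted:
        return first, first
    final = rerun_with_split(full_reads, restricted, context_table, params, merge_log=merge_log)
    return first, final
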