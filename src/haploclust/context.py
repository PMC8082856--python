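"""Dataset-wide context coverage: the vote weights of the consensus step.

Long reads are error-prone and no error correction is applied (correcting
would flatten or mis-assign genuine heterozygosity), so the engine instead
weights each base call by how often the whole dataset has seen that call
in the same local context.  The context of a call is its two nearest
upstream and two nearest downstream heterozygous calls *within the same
read*, bases included: a sequencing error that turns a well-supported SNP
into a base that is well-supported on another haplotype still lands in a
context that the other haplotype's reads do not share, so it keeps a low
weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .variantio import ReducedRead

#: Placeholder flank used when a call has fewer than two neighbours on a side.
EDGE: tuple[int, str] = (-1, "*")

ContextKey = tuple[str, int, str, tuple[tuple[int, str], ...]]


class ContextLookupError(KeyError):
    """A (call, context) key was queried that the table was not built over."""


@dataclass
class ContextCoverageTable:
    """Counts of each (SNP call, flanking context) over the whole dataset."""

    counts: dict[ContextKey, int]

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, key: ContextKey) -> int | None:
        return self.counts.get(key)


def _context_of(calls: Sequence[tuple[int, str]], i: int) -> tuple[tuple[int, str], ...]:
    up2 = calls[i - 2] if i >= 2 else EDGE
    up1 = calls[i - 1] if i >= 1 else EDGE
    dn1 = calls[i + 1] if i + 1 < len(calls) else EDGE
    dn2 = calls[i + 2] if i + 2 < len(calls) else EDGE
    return (up2, up1, dn1, dn2)


def context_key(read: ReducedRead, i: int) -> ContextKey:
    """The table key of the ``i``-th call of ``read``."""
    pos, base = read.calls[i]
    return (read.chromosome, pos, base, _context_of(read.calls, i))


def build_context_table(reads: Iterable[ReducedRead]) -> ContextCoverageTable:
    """Count every (call, in-read flanking context) over ``reads``.

    For each (chromosome, position) the counts over all keys sum to the
    number of read calls at that position; read order does not matter.
    """
    counts: dict[ContextKey, int] = {}
    for read in reads:
        calls = read.calls
        chrom = read.chromosome
        for i, (pos, base) in enumerate(calls):
            key = (chrom, pos, base, _context_of(calls, i))
            counts[key] = counts.get(key, 0) + 1
    return ContextCoverageTable(counts)


def vote_weight(read: ReducedRead, position: int, table: ContextCoverageTable) -> int:
    """Context-coverage vote weight of ``read``'s call at ``position``.

    By construction >= 1 for any read the table was built over; a missing
    key means the table and dataset do not match.
    """
    for i, (pos, _) in enumerate(read.calls):
        if pos == position:
            key = context_key(read, i)
            count = table.counts.get(key)
            if count is None:
                raise ContextLookupError(
                    f"read {read.read_id} call at {read.chromosome}:{position} "
                    f"has no entry in the context table (table/dataset mismatch)"
                )
            return count
    raise ValueError(f"read {read.read_id} has no call at position {position}")


def read_weights(read: ReducedRead, table: ContextCoverageTable) -> tuple[int, ...]:
    """Vote weights for every call of ``read``, in call order."""
    if read.weights is not None:
        return read.weights
    weights = []
    for i in range(len(read.calls)):
        key = context_key(read, i)
        count = table.counts.get(key)
        if count is None:
            pos = read.calls[i][0]
            raise ContextLookupError(
                f"read {read.read_id} call at {read.chromosome}:{pos} "
                f"has no entry in the context table (table/dataset mismatch)"
            )
        weights.append(count)
    return tuple(weights)


def write_context_tsv(table: ContextCoverageTable, path: str | Path) -> None:
    """Debug dump: chromosome, position, base, context string, count."""
    def fmt(flank: tuple[int, str]) -> str:
        return "*" if flank == EDGE else f"{flank[0]}:{flank[1]}"

    rows = sorted(table.counts.items())
    with open(path, "w") as fh:
        for (chrom, pos, base, ctx), count in rows:
            ctx_s = "|".join(fmt(f) for f in ctx)
            fh.write(f"{chrom}\t{pos}\t{base}\t{ctx_s}\t{count}\n")
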