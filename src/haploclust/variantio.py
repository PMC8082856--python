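"""Input/output for every external format the phaser touches.

Heterozygous positions come from a VCF produced by short-read variant
calling (or a plain TSV).  Long-read alignments are reduced to sparse
per-read base calls at those positions ("reduced reads"), the only
representation the clustering engine ever sees.  Phased clusters go back
out as per-haplotig consensus TSVs and FASTQ files.

Coordinates are 1-based throughout, following VCF convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


@dataclass(frozen=True, order=True)
class VariantPosition:
    """A single heterozygous SNP site on the reference (1-based)."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ReducedRead:
    """A long read (or split-read segment) reduced to its base calls at
    known heterozygous positions.

    ``calls`` is sorted strictly ascending by position and contains only
    A/C/G/T calls; ambiguous bases are treated as no-call upstream.
    ``weights``, when present, carries per-call context-coverage vote
    weights (derived data: excluded from equality/round-trip).
    ``true_haplotype`` is a hidden simulator label used only by the
    evaluation layer.
    """

    read_id: str
    chromosome: str
    calls: tuple[tuple[int, str], ...]
    is_split_segment: bool = False
    true_haplotype: str | None = None
    weights: tuple[int, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError(f"read {self.read_id}: calls must be non-empty")
        positions = [p for p, _ in self.calls]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"read {self.read_id}: calls must be strictly ascending by position"
            )
        for _, base in self.calls:
            if base not in _BASE_SET:
                raise ValueError(f"read {self.read_id}: invalid base {base!r}")
        if self.weights is not None and len(self.weights) != len(self.calls):
            raise ValueError(f"read {self.read_id}: weights/calls length mismatch")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.calls)

    @property
    def span(self) -> tuple[int, int]:
        return self.calls[0][0], self.calls[-1][0]

    def call_set(self) -> frozenset[tuple[int, str]]:
        return frozenset(self.calls)


@dataclass(frozen=True)
class HaplotigRecord:
    """A phased block: consensus calls plus the reads that support it.

    ``consensus_calls`` may contain several rows for one position when
    bases are tied in the weighted vote.
    """

    haplotig_id: str
    chromosome: str
    consensus_calls: tuple[tuple[int, str], ...]
    member_read_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.consensus_calls]
        if any(b < a for a, b in zip(positions, positions[1:])):
            raise ValueError("consensus rows must be sorted by position")


# ---------------------------------------------------------------------------
# Heterozygous positions
# ---------------------------------------------------------------------------

def _is_snp_record(rec: "pysam.VariantRecord") -> bool:
    if rec.ref is None or len(rec.ref) != 1 or rec.ref.upper() not in _BASE_SET:
        return False
    alts = rec.alts or ()
    # keep the record if at least one alt allele is a plain SNP
    return any(a is not None and len(a) == 1 and a.upper() in _BASE_SET for a in alts)


def parse_het_positions(vcf_path: str | Path, mode: str = "het_genotype") -> set[VariantPosition]:
    """Extract heterozygous SNP positions from a VCF 4.x file.

    Two selection modes are supported.  ``af_1`` keeps records whose INFO
    AF equals 1.00, the rule used when truth haplotypes are built by
    pooling homozygous strains (every pooled variant is then "fixed" in
    its source strain).  ``het_genotype`` keeps records where any sample
    genotype is heterozygous (0/1, 0/1/1, ...), the conventional rule for
    a real polyploid sample.  INDEL records are always skipped: phased
    blocks are built from SNPs only.
    """
    if mode not in ("af_1", "het_genotype"):
        raise ValueError(f"unknown mode {mode!r}")
    out: set[VariantPosition] = set()
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vcf:
        rec_no = 0
        try:
            for rec in vcf:
                rec_no += 1
                if not _is_snp_record(rec):
                    continue
                keep = False
                if mode == "af_1":
                    af = rec.info.get("AF")
                    if af is not None:
                        values = af if isinstance(af, tuple) else (af,)
                        keep = any(v is not None and abs(float(v) - 1.0) < 1e-9 for v in values)
                else:
                    for sample in rec.samples.values():
                        gt = sample.get("GT")
                        if gt is None:
                            continue
                        alleles = [a for a in gt if a is not None]
                        if len(set(alleles)) > 1:
                            keep = True
                            break
                if keep:
                    out.add(VariantPosition(rec.chrom, rec.pos))
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"malformed VCF record near data record {rec_no + 1} in {vcf_path}: {exc}"
            ) from exc
    if not out:
        logger.warning("no heterozygous SNP positions found in %s (mode=%s)", vcf_path, mode)
    return out


def read_het_positions_tsv(path: str | Path) -> set[VariantPosition]:
    """Read a two-column (chromosome, position) TSV of heterozygous sites."""
    out: set[VariantPosition] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            out.add(VariantPosition(parts[0], int(parts[1])))
    return out


def write_het_positions_tsv(positions: Iterable[VariantPosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for vp in sorted(positions):
            fh.write(f"{vp.chromosome}\t{vp.position}\n")


# ---------------------------------------------------------------------------
# Alignment reduction
# ---------------------------------------------------------------------------

def reduce_alignments(
    alignment_path: str | Path,
    het_positions: Iterable[VariantPosition],
) -> list[ReducedRead]:
    """Reduce SAM/BAM alignments to per-read calls at heterozygous sites.

    Secondary and unmapped alignments are excluded (flag bits 256 and 4,
    i.e. ``samtools view -F 260`` semantics); supplementary alignments
    and primaries carrying an SA tag are retained as split-read segments,
    each segment becoming its own :class:`ReducedRead`.  A read's call at
    a site is its aligned base there; deleted or clipped sites are simply
    absent.  Reads with zero calls are dropped.
    """
    by_chrom: dict[str, set[int]] = {}
    for vp in het_positions:
        by_chrom.setdefault(vp.chromosome, set()).add(vp.position)

    reads: list[ReducedRead] = []
    seg_counter: dict[str, int] = {}
    n_skipped_noseq = 0
    n_skipped_chrom = 0

    save = pysam.set_verbosity(0)
    try:
        af = pysam.AlignmentFile(str(alignment_path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary:
                continue
            chrom = aln.reference_name
            if chrom not in by_chrom:
                n_skipped_chrom += 1
                continue
            seq = aln.query_sequence
            if not seq:
                n_skipped_noseq += 1
                continue
            wanted = by_chrom[chrom]
            calls: list[tuple[int, str]] = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                if pos1 in wanted:
                    base = seq[qpos].upper()
                    if base in _BASE_SET:
                        calls.append((pos1, base))
            if not calls:
                continue
            calls.sort()
            is_split = aln.is_supplementary or aln.has_tag("SA")
            name = aln.query_name
            n_prev = seg_counter.get(name, 0)
            seg_counter[name] = n_prev + 1
            read_id = name if n_prev == 0 else f"{name}/seg{n_prev + 1}"
            reads.append(
                ReducedRead(
                    read_id=read_id,
                    chromosome=chrom,
                    calls=tuple(calls),
                    is_split_segment=is_split,
                )
            )
    if n_skipped_noseq:
        logger.warning("%d alignments skipped (no usable sequence)", n_skipped_noseq)
    if n_skipped_chrom:
        logger.warning(
            "%d alignments skipped (chromosome absent from heterozygous-position set)",
            n_skipped_chrom,
        )
    return reads


def remove_subset_reads(reads: Sequence[ReducedRead]) -> list[ReducedRead]:
    """Drop reads whose calls are a subset of another retained read's calls.

    Among mutually identical reads exactly one representative survives.
    Output is deterministically ordered by (chromosome, first position,
    read_id).  Idempotent.
    """
    by_chrom: dict[str, list[ReducedRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chromosome, []).append(r)

    kept: list[ReducedRead] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda r: (-len(r.calls), r.read_id))
        call_index: dict[tuple[int, str], list[int]] = {}
        retained: list[ReducedRead] = []
        retained_sets: list[frozenset[tuple[int, str]]] = []
        for r in group:
            rset = r.call_set()
            # candidate supersets must contain every call; intersect via the
            # sparsest call's posting list
            postings = [call_index.get(c) for c in r.calls]
            if all(p is not None for p in postings):
                smallest = min(postings, key=len)  # type: ignore[arg-type]
                if any(rset <= retained_sets[i] for i in smallest):  # type: ignore[union-attr]
                    continue
            idx = len(retained)
            retained.append(r)
            retained_sets.append(rset)
            for c in r.calls:
                call_index.setdefault(c, []).append(idx)
        kept.extend(retained)
    kept.sort(key=lambda r: (r.chromosome, r.calls[0][0], r.read_id))
    return kept


# ---------------------------------------------------------------------------
# Reduced-read interchange TSV
# ---------------------------------------------------------------------------
# Columns: read_id, chromosome, comma-separated pos:base tokens, split flag
# (0/1), truth haplotype label or ".".  The phaser is fully testable from
# this format without any alignment parser.

def write_reduced_reads_tsv(reads: Iterable[ReducedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            tokens = ",".join(f"{p}:{b}" for p, b in r.calls)
            label = r.true_haplotype if r.true_haplotype is not None else "."
            fh.write(f"{r.read_id}\t{r.chromosome}\t{tokens}\t{int(r.is_split_segment)}\t{label}\n")


def read_reduced_reads_tsv(path: str | Path) -> list[ReducedRead]:
    reads: list[ReducedRead] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 columns")
            read_id, chrom, tokens = parts[0], parts[1], parts[2]
            is_split = bool(int(parts[3])) if len(parts) > 3 else False
            label = None
            if len(parts) > 4 and parts[4] != ".":
                label = parts[4]
            calls = []
            for tok in tokens.split(","):
                pos_s, base = tok.split(":")
                calls.append((int(pos_s), base))
            reads.append(
                ReducedRead(
                    read_id=read_id,
                    chromosome=chrom,
                    calls=tuple(calls),
                    is_split_segment=is_split,
                    true_haplotype=label,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Haplotig outputs
# ---------------------------------------------------------------------------

def write_haplotig_outputs(
    haplotigs: Sequence[HaplotigRecord],
    raw_fastq_index: Mapping[str, object] | None,
    out_dir: str | Path,
) -> dict[str, dict[str, str]]:
    """Write per-haplotig consensus TSVs (and FASTQs when raw reads are
    available) plus a manifest.

    The TSV has three columns (chromosome, position, consensus base),
    sorted by position, with tied bases on separate lines.  The FASTQ
    index maps read_id to a Bio.SeqRecord; absent read ids are skipped
    from FASTQ output with a warning.  Returns the manifest mapping
    haplotig_id -> {"tsv": path, "fastq": path?} (also written as
    ``manifest.tsv``, with paths relative to ``out_dir`` so a run
    directory is relocatable and reruns are byte-comparable).
    """
    from Bio import SeqIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for h in haplotigs:
        entry: dict[str, str] = {}
        tsv_path = out / f"{h.haplotig_id}.tsv"
        with open(tsv_path, "w") as fh:
            for pos, base in sorted(h.consensus_calls):
                fh.write(f"{h.chromosome}\t{pos}\t{base}\n")
        entry["tsv"] = tsv_path.name
        if raw_fastq_index is not None:
            fq_path = out / f"{h.haplotig_id}.fastq"
            records = []
            missing = 0
            for rid in h.member_read_ids:
                rec = raw_fastq_index.get(rid)
                if rec is None:
                    missing += 1
                    continue
                records.append(rec)
            if missing:
                warnings.warn(
                    f"haplotig {h.haplotig_id}: {missing} member read(s) absent "
                    f"from FASTQ index, skipped in FASTQ output"
                )
            SeqIO.write(records, str(fq_path), "fastq")
            entry["fastq"] = fq_path.name
        manifest[h.haplotig_id] = entry
    with open(out / "manifest.tsv", "w") as fh:
        for hid in sorted(manifest):
            for kind, p in sorted(manifest[hid].items()):
                fh.write(f"{hid}\t{kind}\t{p}\n")
    return manifest


def write_membership_tsv(haplotigs: Sequence[HaplotigRecord], path: str | Path) -> None:
    """Two-column haplotig_id -> read_id table (one row per member)."""
    with open(path, "w") as fh:
        for h in haplotigs:
            for rid in h.member_read_ids:
                fh.write(f"{h.haplotig_id}\t{rid}\n")


def read_membership_tsv(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            hid, rid = line.split("\t")
            out.setdefault(hid, []).append(rid)
    return out
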