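"""End-to-end orchestration: reduce -> context -> phase -> stitch -> clean
-> outputs, with a fully resolved config written next to every run."""

from __future__ import annotations

import dataclasses
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import variantio
from .cleaner import CleanOptions, clean
from .context import build_context_table
from .evaluate import assign_haplotigs, compute_metrics, plot_haplotigs
from .phaser import PhaseParams
from .simulate import TruthSet
from .stitcher import phase_with_stitching

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Merged parameter record for a pipeline run (YAML-serializable)."""

    out_dir: str = "haploclust_out"
    reduced_reads: str | None = None
    alignment: str | None = None
    het_vcf: str | None = None
    het_tsv: str | None = None
    het_mode: str = "het_genotype"
    truth_tsv: str | None = None
    fastq: str | None = None
    chromosome: str | None = None
    max_het_fraction: float | None = None
    use_split_reads: bool = True
    edge_size: int | None = None  # None: sized from the first-pass clusters
    run_clean: bool = True
    gap_fill: bool = True
    filter_fraction: float = 0.01
    seed: int = 0
    phase: PhaseParams = field(default_factory=PhaseParams)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        phase = PhaseParams(**d.pop("phase", {}))
        return cls(phase=phase, **d)


def _load_inputs(config: RunConfig):
    if config.reduced_reads:
        reads = variantio.read_reduced_reads_tsv(config.reduced_reads)
    elif config.alignment:
        if config.het_vcf:
            het = variantio.parse_het_positions(config.het_vcf, config.het_mode)
        elif config.het_tsv:
            het = variantio.read_het_positions_tsv(config.het_tsv)
        else:
            raise ValueError("an alignment input needs --het-vcf or --het-tsv")
        reads = variantio.reduce_alignments(config.alignment, het)
    else:
        raise ValueError("missing input: provide reduced reads or an alignment")
    if config.chromosome:
        reads = [r for r in reads if r.chromosome == config.chromosome]
    if config.max_het_fraction is not None:
        # down-sample het positions (the potato strategy: keep a random
        # fraction of sites to bound runtime; all SNPs remain in the reads)
        rng = random.Random(f"{config.seed}:downsample")
        all_pos = sorted({(r.chromosome, p) for r in reads for p, _ in r.calls})
        keep = {cp for cp in all_pos if rng.random() < config.max_het_fraction}
        slim = []
        for r in reads:
            calls = tuple(c for c in r.calls if (r.chromosome, c[0]) in keep)
            if calls:
                slim.append(dataclasses.replace(r, calls=calls, weights=None))
        reads = slim
    return reads


def run_pipeline(config: RunConfig) -> dict:
    """Run the post-alignment pipeline and write all outputs.

    Returns the manifest (also written as ``manifest.json``).  Identical
    config + seed give byte-identical TSV outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    reads = _load_inputs(config)
    reads = variantio.remove_subset_reads(reads)
    table = build_context_table(reads)

    merge_log: list = []
    first, clusters = phase_with_stitching(
        reads,
        table,
        config.phase,
        edge_size=config.edge_size,
        use_split_reads=config.use_split_reads,
        merge_log=merge_log,
    )
    stage = {"raw": clusters}
    if config.run_clean:
        stage["cleaned"] = clean(
            clusters,
            CleanOptions(
                gap_fill=config.gap_fill,
                filter_fraction=config.filter_fraction,
                seed=config.seed,
            ),
        )

    manifest: dict = {"config": str(out / "config.yaml"), "stages": {}}
    fastq_index = None
    if config.fastq:
        from Bio import SeqIO

        fastq_index = SeqIO.index(config.fastq, "fastq")
    truth = TruthSet.read_tsv(config.truth_tsv) if config.truth_tsv else None

    for name, cl in stage.items():
        stage_dir = out / name
        records = [c.to_haplotig_record() for c in cl]
        files = variantio.write_haplotig_outputs(records, fastq_index, stage_dir)
        variantio.write_membership_tsv(records, stage_dir / "membership.tsv")
        plot_haplotigs(cl, stage_dir / "haplotigs.png")
        entry = {
            "n_haplotigs": len(cl),
            "dir": str(stage_dir),
            "haplotigs": files,
        }
        if truth is not None:
            assignment = assign_haplotigs(cl, truth)
            report = compute_metrics(cl, assignment, truth)
            report.to_json(stage_dir / "metrics.json")
            report.to_tsv(stage_dir / "metrics.tsv")
            entry["metrics"] = {
                "accuracy": report.accuracy,
                "error": report.error,
                "missing": report.missing,
                "haplotigs_per_haplotype": report.haplotigs_per_haplotype,
            }
        manifest["stages"][name] = entry

    with open(out / "merge_log.jsonl", "w") as fh:
        for rec in merge_log:
            fh.write(json.dumps(rec) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
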