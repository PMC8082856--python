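import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from haploclust.context import build_context_table
from haploclust.phaser import PhaseParams, run_phasing
from haploclust.simulate import SimulationConfig, simulate_dataset
from haploclust.variantio import ReducedRead, remove_subset_reads


def make_read(read_id, calls, chrom="chr1", split=False, hap=None, weights=None):
    return ReducedRead(
        read_id=read_id,
        chromosome=chrom,
        calls=tuple(calls),
        is_split_segment=split,
        true_haplotype=hap,
        weights=weights,
    )


@pytest.fixture(scope="session")
def small_tetraploid():
    """One noisy tetraploid chromosome, phased once, shared across tests."""
    cfg = SimulationConfig(
        ploidy=4,
        n_chromosomes=1,
        chromosome_length=100_000,
        heterozygosity=0.005,
        coverage_per_haplotype=15,
        per_base_error_rate=0.10,
        seed=42,
    )
    ds = simulate_dataset(cfg)
    reads = remove_subset_reads(ds.reads)
    table = build_context_table(reads)
    clusters = run_phasing(reads, table, PhaseParams(rng_seed=42))
    return ds, reads, table, clusters


@pytest.fixture(scope="session")
def noisy_suite():
    """Five noisy tetraploid studies at the default conditions (k=4,
    h=0.5%, 20X/haplotype, e=0.10, 2 x 200 kb), phased raw.  Shared by the
    recovery and cleaning acceptance tests."""
    runs = []
    for seed in (1, 2, 3, 4, 5):
        ds = simulate_dataset(SimulationConfig(seed=seed))
        reads = remove_subset_reads(ds.reads)
        table = build_context_table(reads)
        clusters = run_phasing(reads, table, PhaseParams(rng_seed=seed))
        runs.append((ds, reads, table, clusters))
    return runs
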