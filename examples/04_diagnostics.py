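"""Truth-free quality diagnostics: allele frequencies and coverage.

Without a truth set, two signals reveal what happened inside a cluster:
(1) the in-cluster allele-frequency distribution — a chimera of two
equally covered haplotypes piles up near 50% while a pure cluster stays
near 100%; (2) windowed read depth per haplotig — a region phased into
two haplotigs where one carries twice the depth is one haplotype present
in two genomic copies, not a phasing failure.
"""

import numpy as np

from haploclust import (
    Cluster,
    PhaseParams,
    SimulationConfig,
    TruthSet,
    allele_frequency_distribution,
    build_context_table,
    coverage_profile,
    generate_truth,
    remove_subset_reads,
    run_phasing,
    simulate_dataset,
    simulate_reads,
)

# --- allele-frequency chimera flag ---------------------------------------
ds = simulate_dataset(
    SimulationConfig(ploidy=2, n_chromosomes=1, chromosome_length=60_000,
                     heterozygosity=0.005, coverage_per_haplotype=15,
                     per_base_error_rate=0.10, seed=3)
)
hap1 = [r for r in ds.reads if r.true_haplotype == "hap1"]
hap2 = [r for r in ds.reads if r.true_haplotype == "hap2"]
pure = allele_frequency_distribution(Cluster.from_reads("pure", hap1))
chimera = allele_frequency_distribution(Cluster.from_reads("chimera", hap1 + hap2))
print(f"pure cluster:    {pure.fraction_near_half:5.1%} of sites near AF 0.5 -> flagged={pure.flagged}")
print(f"chimera cluster: {chimera.fraction_near_half:5.1%} of sites near AF 0.5 -> flagged={chimera.flagged}")

# --- duplicated-haplotype coverage ratio ----------------------------------
_, diploid = generate_truth(
    SimulationConfig(ploidy=2, n_chromosomes=1, chromosome_length=100_000,
                     heterozygosity=0.005, seed=5)
)
# a triploid whose second haplotype is present in two copies
tri = TruthSet({
    "hap1": dict(diploid.haplotypes["hap1"]),
    "hap2": dict(diploid.haplotypes["hap2"]),
    "hap3": dict(diploid.haplotypes["hap2"]),
})
cfg = SimulationConfig(ploidy=3, n_chromosomes=1, chromosome_length=100_000,
                       heterozygosity=0.005, coverage_per_haplotype=12,
                       per_base_error_rate=0.05, seed=5)
reads = remove_subset_reads(simulate_reads(tri, cfg))
clusters = run_phasing(reads, build_context_table(reads), PhaseParams(rng_seed=5))
profile = coverage_profile(clusters, window=5000, coverage_fraction=0.9)
depths = sorted(float(np.mean(v)) for v in profile.values())
print(f"triploid with a duplicated haplotype phases into {len(profile)} haplotigs")
print(f"mean depths {depths[0]:.1f}X and {depths[1]:.1f}X (ratio {depths[1]/depths[0]:.2f}, expected ~2)")
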