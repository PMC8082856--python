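"""Automated cleaning: fewer haplotigs at negligible accuracy cost.

Phases a noisy tetraploid, then applies the three cleaning steps
(discordance-gated merging, low-coverage filtering, duplicate-haplotype
gap filling) and compares contiguity and accuracy before and after.
"""

from haploclust import (
    CleanOptions,
    PhaseParams,
    SimulationConfig,
    assign_haplotigs,
    build_context_table,
    clean,
    compute_metrics,
    remove_subset_reads,
    run_phasing,
    simulate_dataset,
)

dataset = simulate_dataset(SimulationConfig(seed=2))
reads = remove_subset_reads(dataset.reads)
table = build_context_table(reads)
raw = run_phasing(reads, table, PhaseParams(rng_seed=2))
cleaned = clean(raw, CleanOptions(seed=2))

for name, clusters in (("raw", raw), ("cleaned", cleaned)):
    m = compute_metrics(clusters, assign_haplotigs(clusters, dataset.truth), dataset.truth)
    print(
        f"{name:8s} {len(clusters):3d} haplotigs "
        f"({m.haplotigs_per_haplotype:.2f}/haplotype), accuracy {m.accuracy:.1f}%"
    )
# cleaning merges same-haplotype fragments whose pooled discordance stays
# at the dataset noise floor and drops sub-1%-coverage noise clusters;
# accuracy should move by well under a percentage point.
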