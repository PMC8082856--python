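import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read
from _reference import reference_phase
from haploclust.context import build_context_table
from haploclust.phaser import (
    Cluster,
    PhaseParams,
    identity_change,
    merge_clusters,
    pair_allowed,
    run_phasing,
    select_best_pair,
    similarity,
)
from haploclust.variantio import remove_subset_reads

BASES = "ACGT"


def _read_over(read_id, positions, bases, chrom="chr1"):
    return make_read(read_id, list(zip(positions, bases)), chrom=chrom)


class TestSimilarity:
    def test_direct_ratio(self):
        pos = list(range(10, 110, 10))
        a = _read_over("a", pos, "AAAAAAAAAA")
        b = _read_over("b", pos, "AAAAAAAAAT")
        assert similarity(a, b) == (0.9, 10)

    def test_identity(self):
        pos = list(range(10, 60, 10))
        a = _read_over("a", pos, "ACGTA")
        assert similarity(a, a) == (1.0, 5)

    def test_disjoint_positions_signal_no_overlap(self):
        a = _read_over("a", [10, 20], "AC")
        b = _read_over("b", [30, 40], "AC")
        assert similarity(a, b) is None

    def test_cross_chromosome_signals_no_overlap(self):
        a = _read_over("a", [10, 20], "AC")
        b = _read_over("b", [10, 20], "AC", chrom="chr2")
        assert similarity(a, b) is None

    def test_tied_consensus_counts_as_match_when_sets_intersect(self):
        pos = [10, 20]
        c1 = Cluster.from_reads("c1", [_read_over("a", pos, "AC"), _read_over("b", pos, "TC")])
        r = _read_over("q", pos, "AC")
        # position 10 is tied {A, T} in c1; A intersects
        assert similarity(c1, r) == (1.0, 2)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_symmetry(self, data):
        def rand_read(rid):
            n = data.draw(st.integers(1, 8))
            pos = sorted(data.draw(st.sets(st.integers(1, 12), min_size=n, max_size=n)))
            return _read_over(rid, pos, [data.draw(st.sampled_from(BASES)) for _ in pos])

        a, b = rand_read("a"), rand_read("b")
        assert similarity(a, b) == similarity(b, a)


class TestPairAllowed:
    def _pair(self, n_shared, size_a=None, size_b=None, mismatches=0):
        size_a = size_a or n_shared
        size_b = size_b or n_shared
        pos_shared = [10 * i for i in range(1, n_shared + 1)]
        extra_a = [10 * i for i in range(n_shared + 1, size_a + 1)]
        extra_b = [10 * (size_b + i) for i in range(n_shared + 1, size_b + 1)]
        bases_b = ["A"] * n_shared
        for i in range(mismatches):
            bases_b[i] = "T"
        a = _read_over("a", pos_shared + extra_a, "A" * size_a)
        b = _read_over("b", sorted(pos_shared + extra_b), bases_b + ["A"] * (size_b - n_shared))
        return a, b

    def test_below_min_overlap_count_never_allowed(self):
        a, b = self._pair(9)
        assert not pair_allowed(a, b, PhaseParams())

    def test_below_min_similarity_never_allowed(self):
        # 200 shared positions, 1 match: S = 0.005 < 0.01
        a, b = self._pair(200, mismatches=199)
        assert not pair_allowed(a, b, PhaseParams())

    def test_overlap_fraction_ignored_above_threshold(self):
        # 150 shared, smaller covers 2000 positions: fraction 0.075 < O,
        # but shared > 100 so the O rule is ignored
        a, b = self._pair(150, size_a=2000, size_b=2000)
        assert pair_allowed(a, b, PhaseParams())

    def test_overlap_fraction_enforced_below_threshold(self):
        # 15 shared of a 400-position smaller read: 0.0375 < O = 0.1
        a, b = self._pair(15, size_a=400, size_b=400)
        assert not pair_allowed(a, b, PhaseParams())
        # but fine for a 100-position read (0.15 >= 0.1)
        a, b = self._pair(15, size_a=100, size_b=100)
        assert pair_allowed(a, b, PhaseParams())


class TestSelectBestPair:
    def test_highest_similarity_wins(self):
        got = select_best_pair([(("a", "b"), 0.9, 12), (("c", "d"), 0.8, 50)], random.Random(0))
        assert got == ("a", "b")

    def test_tie_broken_by_shared_positions(self):
        got = select_best_pair([(("a", "b"), 0.9, 12), (("c", "d"), 0.9, 20)], random.Random(0))
        assert got == ("c", "d")

    def test_full_tie_is_seeded_deterministic(self):
        cands = [(("a", "b"), 0.9, 12), (("c", "d"), 0.9, 12), (("e", "f"), 0.9, 12)]
        picks = {select_best_pair(cands, random.Random(7)) for _ in range(5)}
        assert len(picks) == 1

    def test_empty_candidates_signal_termination(self):
        assert select_best_pair([], random.Random(0)) is None


class TestMergeClusters:
    def test_single_read_cluster_consensus_is_the_read(self):
        r = _read_over("a", [10, 20, 30], "ACG")
        c = Cluster.from_reads("c", [r])
        assert c.consensus == {10: frozenset("A"), 20: frozenset("C"), 30: frozenset("G")}

    def test_majority_wins(self):
        a = Cluster.from_reads("a", [make_read("a", [(10, "A")], weights=(5,))])
        b = Cluster.from_reads("b", [make_read("b", [(10, "T")], weights=(2,))])
        merged = merge_clusters(a, b)
        assert merged.consensus[10] == frozenset("A")
        assert merged.tallies[10] == {"A": 5, "T": 2}

    def test_tied_bases_all_included(self):
        a = Cluster.from_reads("a", [make_read("a", [(10, "A")], weights=(3,))])
        b = Cluster.from_reads("b", [make_read("b", [(10, "T")], weights=(3,))])
        assert merge_clusters(a, b).consensus[10] == frozenset("AT")

    def test_cross_chromosome_merge_rejected(self):
        a = Cluster.from_reads("a", [_read_over("a", [10], "A")])
        b = Cluster.from_reads("b", [_read_over("b", [10], "A", chrom="chr2")])
        with pytest.raises(ValueError):
            merge_clusters(a, b)


class TestIdentityChange:
    def _unit_cluster(self, rid, positions, bases):
        return Cluster.from_reads(
            rid, [make_read(rid, list(zip(positions, bases)), weights=(1,) * len(positions))]
        )

    def test_merging_identical_copies_changes_nothing(self):
        pos = list(range(10, 110, 10))
        c1 = self._unit_cluster("a", pos, "A" * 10)
        c2 = self._unit_cluster("b", pos, "A" * 10)
        for mode in ("per_cluster", "summed"):
            assert identity_change(c1, c2, mode) == 0.0

    def test_one_dissent_in_ten_unit_votes_is_ten_percent(self):
        # two single-read clusters agreeing at 9/10 shared positions:
        # each cluster's consensus loses the other's vote at the one
        # disagreeing position -> 2 votes lost of 20 total
        pos = list(range(10, 110, 10))
        c1 = self._unit_cluster("a", pos, "AAAAAAAAAA")
        c2 = self._unit_cluster("b", pos, "AAAAAAAAAT")
        assert identity_change(c1, c2, "summed") == pytest.approx(0.10)
        assert identity_change(c1, c2, "per_cluster") == pytest.approx(0.10)

    def test_no_common_positions_signals_no_overlap(self):
        c1 = self._unit_cluster("a", [10, 20], "AC")
        c2 = self._unit_cluster("b", [30, 40], "AC")
        assert identity_change(c1, c2) is None

    def test_deep_cluster_absorbs_noisy_read_but_not_vice_versa(self):
        # per-cluster mode: a lone erroneous read cannot shift a deep
        # cluster's identity, so the merge is judged by the deep side
        pos = list(range(10, 110, 10))
        deep = Cluster.from_reads(
            "deep", [make_read(f"d{i}", list(zip(pos, "A" * 10)), weights=(8,) * 10) for i in range(5)]
        )
        noisy = self._unit_cluster("n", pos, "ATATAAAAAA")
        assert identity_change(deep, noisy, "per_cluster") < 0.05
        assert identity_change(deep, noisy, "summed") > 0.05

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_symmetry(self, data):
        def rand_cluster(cid):
            reads = []
            for i in range(data.draw(st.integers(1, 3))):
                pos = sorted(data.draw(st.sets(st.integers(1, 8), min_size=2, max_size=6)))
                reads.append(
                    make_read(f"{cid}{i}", [(p, data.draw(st.sampled_from(BASES))) for p in pos])
                )
            return Cluster.from_reads(cid, reads)

        c1, c2 = rand_cluster("a"), rand_cluster("b")
        for mode in ("per_cluster", "summed"):
            assert identity_change(c1, c2, mode) == identity_change(c2, c1, mode)


def _haplotype_reads(hap_bases, n_reads, positions, chrom="chr1", prefix="r"):
    """Tiling reads of one haplotype with generous overlaps."""
    reads = []
    n = len(positions)
    for i in range(n_reads):
        lo = (i * (n - 12)) // max(1, n_reads - 1) if n_reads > 1 else 0
        hi = min(n, lo + 12 + (n - 12) // max(1, n_reads - 1) + 1)
        reads.append(
            make_read(
                f"{prefix}{i}",
                [(positions[j], hap_bases[j]) for j in range(lo, hi)],
                chrom=chrom,
            )
        )
    return reads


class TestRunPhasing:
    def test_three_distinct_haplotypes_fully_recovered(self):
        rng = np.random.default_rng(0)
        positions = [10 * (i + 1) for i in range(40)]
        haps = ["".join(rng.choice(list(BASES), 40)) for _ in range(3)]
        reads = []
        for h, bases in enumerate(haps):
            reads += _haplotype_reads(bases, 4, positions, prefix=f"h{h}_")
        table = build_context_table(reads)
        clusters = run_phasing(reads, table, PhaseParams(rng_seed=0))
        partition = {frozenset(c.member_read_ids) for c in clusters}
        expected = {frozenset(f"h{h}_{i}" for i in range(4)) for h in range(3)}
        assert partition == expected

    def test_identical_reads_collapse_to_one_cluster(self):
        reads = [make_read(f"r{i}", [(10 * j, "A") for j in range(1, 15)]) for i in range(5)]
        table = build_context_table(reads)
        clusters = run_phasing(reads, table, PhaseParams(rng_seed=0))
        assert len(clusters) == 1
        assert clusters[0].member_read_ids == {f"r{i}" for i in range(5)}

    def test_reads_below_min_overlap_stay_singletons(self):
        a = make_read("a", [(i, "A") for i in range(1, 13)])
        b = make_read("b", [(i, "A") for i in range(8, 20)])  # 5 shared < 10
        table = build_context_table([a, b])
        clusters = run_phasing([a, b], table, PhaseParams(rng_seed=0))
        assert len(clusters) == 2

    def test_empty_input_gives_empty_output(self):
        assert run_phasing([], None, PhaseParams()) == []

    def test_partition_property_and_consensus_invariant(self, small_tetraploid):
        ds, reads, table, clusters = small_tetraploid
        seen = [rid for c in clusters for rid in c.member_read_ids]
        assert sorted(seen) == sorted(r.read_id for r in reads)
        for c in clusters:
            for pos, bases in c.consensus.items():
                top = max(c.tallies[pos].values())
                assert bases == frozenset(
                    b for b, w in c.tallies[pos].items() if w == top
                )

    def test_min_cluster_reads_filters_output(self, small_tetraploid):
        ds, reads, table, _ = small_tetraploid
        clusters = run_phasing(reads, table, PhaseParams(rng_seed=42, min_cluster_reads=5))
        assert all(c.n_reads >= 5 for c in clusters)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        positions = [10 * (i + 1) for i in range(30)]
        haps = ["".join(rng.choice(list(BASES), 30)) for _ in range(2)]
        reads = []
        for h, bases in enumerate(haps):
            reads += _haplotype_reads(bases, 5, positions, prefix=f"h{h}_")
        table = build_context_table(reads)
        runs = [run_phasing(reads, table, PhaseParams(rng_seed=9)) for _ in range(2)]
        assert [c.member_read_ids for c in runs[0]] == [c.member_read_ids for c in runs[1]]
        assert [c.consensus for c in runs[0]] == [c.consensus for c in runs[1]]

    def test_never_merges_across_chromosomes(self):
        reads = []
        for chrom in ("chr1", "chr2"):
            reads += [
                make_read(f"{chrom}_r{i}", [(10 * j, "A") for j in range(1, 15)], chrom=chrom)
                for i in range(3)
            ]
        table = build_context_table(reads)
        clusters = run_phasing(reads, table, PhaseParams(rng_seed=0))
        assert len(clusters) == 2
        assert all(len({r.chromosome for r in c.members}) == 1 for c in clusters)


class TestOracleEquivalence:
    def _random_instance(self, rng):
        n_pos = rng.integers(15, 30)
        positions = sorted(rng.choice(2000, size=n_pos, replace=False) + 1)
        k = int(rng.integers(1, 4))
        haps = [rng.integers(0, 4, size=n_pos) for _ in range(k)]
        n_reads = int(rng.integers(2, 13))
        err = float(rng.choice([0.0, 0.05, 0.1]))
        reads = []
        for i in range(n_reads):
            h = int(rng.integers(0, k))
            lo = int(rng.integers(0, max(1, n_pos - 12)))
            hi = int(min(n_pos, lo + rng.integers(10, n_pos)))
            calls = []
            for j in range(lo, hi):
                b = int(haps[h][j])
                if rng.random() < err:
                    b = (b + int(rng.integers(1, 4))) % 4
                calls.append((int(positions[j]), BASES[b]))
            if calls:
                reads.append(make_read(f"r{i}", calls))
        return reads

    def test_incremental_engine_matches_exhaustive_rescoring(self):
        rng = np.random.default_rng(2024)
        params = PhaseParams(rng_seed=5)
        for trial in range(200):
            reads = self._random_instance(rng)
            if not reads:
                continue
            table = build_context_table(reads)
            engine = {
                frozenset(c.member_read_ids)
                for c in run_phasing(reads, table, params)
            }
            oracle = reference_phase(reads, table, params)
            assert engine == oracle, f"trial {trial}: {engine} != {oracle}"
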