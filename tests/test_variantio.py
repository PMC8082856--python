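import warnings

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read
from _reference import brute_force_subset_filter
from haploclust.variantio import (
    HaplotigRecord,
    ReducedRead,
    VariantPosition,
    parse_het_positions,
    read_reduced_reads_tsv,
    reduce_alignments,
    remove_subset_reads,
    write_haplotig_outputs,
    write_reduced_reads_tsv,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t100\t.\tA\tT\t50\tPASS\tAF=1.00\tGT\t1/1
chr1\t200\t.\tA\tAT\t50\tPASS\tAF=0.50\tGT\t0/1
chr1\t300\t.\tG\tC\t50\tPASS\tAF=0.50\tGT\t0/1
chr1\t400\t.\tG\tC,T\t50\tPASS\tAF=0.25,0.25\tGT\t1/2
"""

INDEL_ONLY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t200\t.\tA\tAT\t50\tPASS\tAF=1.00\tGT\t0/1
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "sites.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestParseHetPositions:
    def test_af_1_mode_keeps_only_fixed_snps(self, vcf_path):
        got = parse_het_positions(vcf_path, mode="af_1")
        assert got == {VariantPosition("chr1", 100)}

    def test_het_genotype_mode_keeps_het_snps(self, vcf_path):
        got = parse_het_positions(vcf_path, mode="het_genotype")
        assert got == {VariantPosition("chr1", 300), VariantPosition("chr1", 400)}

    def test_indel_records_always_skipped(self, tmp_path):
        p = tmp_path / "indels.vcf"
        p.write_text(INDEL_ONLY_VCF)
        for mode in ("af_1", "het_genotype"):
            assert parse_het_positions(p, mode=mode) == set()

    def test_unknown_mode_rejected(self, vcf_path):
        with pytest.raises(ValueError):
            parse_het_positions(vcf_path, mode="everything")


SAM_TEXT = """\
@HD\tVN:1.6
@SQ\tSN:chr1\tLN:10000
@SQ\tSN:chr2\tLN:10000
full\t0\tchr1\t96\t60\t30M\t*\t0\t0\tAAAACAAAACGAAACTAAACAAAACAAAAC\t*
secondary\t256\tchr1\t96\t60\t30M\t*\t0\t0\tAAAACAAAACGAAACTAAACAAAACAAAAC\t*
unmapped\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*
withdel\t0\tchr1\t96\t60\t10M10D10M\t*\t0\t0\tAAAACAAAACAAAACAAAAC\t*
splitr\t0\tchr1\t96\t60\t15M\t*\t0\t0\tAAAACAAAACGAAAC\t*\tSA:Z:chr2,96,+,15M,60,0;
splitr\t2048\tchr2\t96\t60\t15M\t*\t0\t0\tAAAACAAAACGAAAC\t*\tSA:Z:chr1,96,+,15M,60,0;
"""
# het sites: chr1 100,106,111 / chr2 100,106  (1-based)
HET = {
    VariantPosition("chr1", 100),
    VariantPosition("chr1", 106),
    VariantPosition("chr1", 111),
    VariantPosition("chr2", 100),
    VariantPosition("chr2", 106),
}


@pytest.fixture
def sam_path(tmp_path):
    p = tmp_path / "aln.sam"
    p.write_text(SAM_TEXT)
    return p


class TestReduceAlignments:
    def test_primary_read_calls_at_het_sites(self, sam_path):
        reads = {r.read_id: r for r in reduce_alignments(sam_path, HET)}
        # "full" starts at 96; offsets 4,10,15 -> bases C,G,T
        assert reads["full"].calls == ((100, "C"), (106, "G"), (111, "T"))

    def test_secondary_and_unmapped_excluded(self, sam_path):
        ids = {r.read_id for r in reduce_alignments(sam_path, HET)}
        assert "secondary" not in ids
        assert "unmapped" not in ids

    def test_deleted_site_absent_from_calls(self, sam_path):
        reads = {r.read_id: r for r in reduce_alignments(sam_path, HET)}
        # 10M10D10M from 96: ref 96-105 aligned, 106-115 deleted, 116-125 aligned
        assert reads["withdel"].calls == ((100, "C"),)

    def test_split_read_yields_one_segment_per_alignment(self, sam_path):
        reads = reduce_alignments(sam_path, HET)
        segs = [r for r in reads if r.read_id.startswith("splitr")]
        assert len(segs) == 2
        assert all(r.is_split_segment for r in segs)
        assert {r.chromosome for r in segs} == {"chr1", "chr2"}

    def test_positions_never_outside_het_set(self, sam_path):
        wanted = {(vp.chromosome, vp.position) for vp in HET}
        for r in reduce_alignments(sam_path, HET):
            assert all((r.chromosome, p) in wanted for p, _ in r.calls)


class TestRemoveSubsetReads:
    def test_strict_subset_removed(self):
        a = make_read("a", [(1, "A"), (2, "C"), (3, "G")])
        b = make_read("b", [(1, "A"), (2, "C")])
        assert remove_subset_reads([a, b]) == [a]

    def test_identical_reads_keep_one_representative(self):
        a = make_read("a", [(1, "A"), (2, "C")])
        b = make_read("b", [(1, "A"), (2, "C")])
        kept = remove_subset_reads([a, b])
        assert len(kept) == 1

    def test_conflicting_call_is_not_a_subset(self):
        a = make_read("a", [(1, "A"), (2, "C")])
        b = make_read("b", [(1, "A"), (2, "T")])
        assert len(remove_subset_reads([a, b])) == 2

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_and_idempotent(self, data):
        n = data.draw(st.integers(1, 10))
        reads = []
        for i in range(n):
            npos = data.draw(st.integers(1, 5))
            pos = sorted(data.draw(st.sets(st.integers(1, 8), min_size=npos, max_size=npos)))
            calls = [(p, data.draw(st.sampled_from("ACGT"))) for p in pos]
            reads.append(make_read(f"r{i}", calls))
        once = remove_subset_reads(reads)
        assert [r.read_id for r in once] == [r.read_id for r in brute_force_subset_filter(reads)]
        assert remove_subset_reads(once) == once


class TestReducedReadTsv:
    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_round_trip_identity(self, tmp_path_factory, data):
        n = data.draw(st.integers(1, 8))
        reads = []
        for i in range(n):
            npos = data.draw(st.integers(1, 6))
            pos = sorted(data.draw(st.sets(st.integers(1, 1000), min_size=npos, max_size=npos)))
            calls = [(p, data.draw(st.sampled_from("ACGT"))) for p in pos]
            reads.append(
                make_read(
                    f"r{i}",
                    calls,
                    chrom=data.draw(st.sampled_from(["chr1", "chr2"])),
                    split=data.draw(st.booleans()),
                    hap=data.draw(st.sampled_from([None, "hap1", "hap2"])),
                )
            )
        path = tmp_path_factory.mktemp("tsv") / "reads.tsv"
        write_reduced_reads_tsv(reads, path)
        assert read_reduced_reads_tsv(path) == reads


class TestReducedReadInvariants:
    def test_unsorted_calls_rejected(self):
        with pytest.raises(ValueError):
            ReducedRead("r", "chr1", ((5, "A"), (3, "C")))

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            ReducedRead("r", "chr1", ())

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            ReducedRead("r", "chr1", ((1, "N"),))


class TestWriteHaplotigOutputs:
    def _fastq_index(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        index = {}
        for rid in ("r1", "r2", "r3"):
            rec = SeqRecord(Seq("ACGTACGT"), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [30] * 8
            index[rid] = rec
        return index

    def test_fastq_and_tsv_written(self, tmp_path):
        h = HaplotigRecord("tig1", "chr1", ((10, "A"), (20, "C")), ("r1", "r2", "r3"))
        manifest = write_haplotig_outputs([h], self._fastq_index(), tmp_path)
        assert set(manifest) == {"tig1"}
        fastq = (tmp_path / "tig1.fastq").read_text()
        assert fastq.count("@") == 3
        tsv = (tmp_path / "tig1.tsv").read_text().splitlines()
        assert tsv == ["chr1\t10\tA", "chr1\t20\tC"]

    def test_tied_consensus_bases_on_separate_lines(self, tmp_path):
        h = HaplotigRecord("tig1", "chr1", ((10, "A"), (10, "T"), (20, "C")), ("r1",))
        write_haplotig_outputs([h], None, tmp_path)
        tsv = (tmp_path / "tig1.tsv").read_text().splitlines()
        assert tsv == ["chr1\t10\tA", "chr1\t10\tT", "chr1\t20\tC"]

    def test_empty_haplotig_list_gives_empty_manifest(self, tmp_path):
        assert write_haplotig_outputs([], None, tmp_path) == {}

    def test_missing_read_skipped_with_warning(self, tmp_path):
        h = HaplotigRecord("tig1", "chr1", ((10, "A"),), ("r1", "ghost"))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            write_haplotig_outputs([h], self._fastq_index(), tmp_path)
        assert any("ghost" not in str(w.message) or "absent" in str(w.message) for w in caught)
        fastq = (tmp_path / "tig1.fastq").read_text()
        assert fastq.count("@") == 1
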