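"""FASTA/GFF3/BED12/SAM/tabular readers, bedGraph round-trips, coordinates."""

import numpy as np
import pytest

from tds import ioformats as io


# ---------------------------------------------------------------------------
# FASTA

@pytest.mark.parametrize(
    "content, expected",
    [
        (">a\nACGT\n", [("a", "ACGT")]),
        (">a\nac\ngu\n", [("a", "ACGT")]),  # case and U->T normalization
        (">a\nACG\n>b\nTT\n", [("a", "ACG"), ("b", "TT")]),
    ],
)
def test_read_fasta(tmp_path, content, expected):
    p = tmp_path / "x.fa"
    p.write_text(content)
    seqs = io.read_fasta(p)
    assert [(s.id, s.seq) for s in seqs] == expected


def test_read_fasta_duplicate_id_errors(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">a\nAC\n>a\nGG\n")
    with pytest.raises(ValueError, match="duplicate sequence id 'a'"):
        io.read_fasta(p)


def test_read_fasta_empty_errors(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text("")
    with pytest.raises(ValueError):
        io.read_fasta(p)


def test_fasta_round_trip(tmp_path):
    seqs = [io.NamedSequence("s1", "ACGTN" * 30), io.NamedSequence("s2", "TTTT")]
    p = tmp_path / "rt.fa"
    io.write_fasta(seqs, p)
    assert io.read_fasta(p) == seqs


# ---------------------------------------------------------------------------
# Transcript models

TOY_GENOME = ">chr1\n" + "ACGTACGTACGTACGTACGT\n"  # 20 nt toy chromosome


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_single_exon_plus_cds_whole_exon(tmp_path):
    genome = io.read_fasta(_write(tmp_path, "g.fa", TOY_GENOME))
    gff = (
        "##gff-version 3\n"
        "chr1\t.\tmRNA\t1\t12\t.\t+\t.\tID=t1;Parent=gene1\n"
        "chr1\t.\texon\t1\t12\t.\t+\t.\tParent=t1\n"
        "chr1\t.\tCDS\t1\t12\t.\t+\t0\tParent=t1\n"
    )
    (m,) = io.read_transcript_models(_write(tmp_path, "a.gff3", gff), genome)
    assert (m.cds_start, m.cds_end) == (0, 12)
    assert m.sequence == "ACGTACGTACGT"


def test_two_exon_minus_strand_sequence(tmp_path):
    # hand-built 20-nt toy locus: exons (0,6) and (10,16) on '-'
    genome = io.read_fasta(_write(tmp_path, "g.fa", TOY_GENOME))
    gff = (
        "chr1\t.\tmRNA\t1\t16\t.\t-\t.\tID=t1;Parent=gene1\n"
        "chr1\t.\texon\t1\t6\t.\t-\t.\tParent=t1\n"
        "chr1\t.\texon\t11\t16\t.\t-\t.\tParent=t1\n"
    )
    (m,) = io.read_transcript_models(_write(tmp_path, "a.gff3", gff), genome)
    # reverse complement of exon concatenation in ascending genomic order
    from Bio.Seq import Seq

    expected = str(Seq("ACGTAC" + "GTACGT").reverse_complement())
    assert m.sequence == expected
    assert m.exons == [(10, 16), (0, 6)]  # transcript order on '-'


def test_bed12_gff3_equivalence(tmp_path):
    genome = io.read_fasta(_write(tmp_path, "g.fa", TOY_GENOME))
    gff = (
        "chr1\t.\tmRNA\t1\t16\t.\t+\t.\tID=t1;Parent=t1\n"
        "chr1\t.\texon\t1\t6\t.\t+\t.\tParent=t1\n"
        "chr1\t.\texon\t11\t16\t.\t+\t.\tParent=t1\n"
        "chr1\t.\tCDS\t1\t6\t.\t+\t0\tParent=t1\n"
        "chr1\t.\tCDS\t11\t13\t.\t+\t0\tParent=t1\n"
    )
    bed = "chr1\t0\t16\tt1\t0\t+\t0\t13\t0\t2\t6,6\t0,10\n"
    (mg,) = io.read_transcript_models(_write(tmp_path, "a.gff3", gff), genome)
    (mb,) = io.read_transcript_models(_write(tmp_path, "a.bed", bed), genome)
    for attr in ("chrom", "strand", "exons", "cds_start", "cds_end", "sequence"):
        assert getattr(mg, attr) == getattr(mb, attr)


def test_unknown_chromosome_errors(tmp_path):
    genome = io.read_fasta(_write(tmp_path, "g.fa", TOY_GENOME))
    gff = "chrX\t.\tmRNA\t1\t10\t.\t+\t.\tID=t1\nchrX\t.\texon\t1\t10\t.\t+\t.\tParent=t1\n"
    with pytest.raises(ValueError, match="unknown chromosome"):
        io.read_transcript_models(_write(tmp_path, "a.gff3", gff), genome)


def test_cds_not_multiple_of_three_flags_non_qualifying(tmp_path):
    genome = io.read_fasta(_write(tmp_path, "g.fa", TOY_GENOME))
    gff = (
        "chr1\t.\tmRNA\t1\t10\t.\t+\t.\tID=t1\n"
        "chr1\t.\texon\t1\t10\t.\t+\t.\tParent=t1\n"
        "chr1\t.\tCDS\t1\t10\t.\t+\t0\tParent=t1\n"
    )
    with pytest.warns(UserWarning, match="non-qualifying"):
        (m,) = io.read_transcript_models(_write(tmp_path, "a.gff3", gff), genome)
    assert not m.qualified


# ---------------------------------------------------------------------------
# Alignments

SAM = """@HD\tVN:1.6
@SQ\tSN:t1\tLN:1000
r1\t0\tt1\t101\t255\t28M\t*\t0\t0\t*\t*
r2\t0\tt1\t11\t255\t28M\t*\t0\t0\t*\t*\tNH:i:2
r2\t256\tt1\t51\t255\t28M\t*\t0\t0\t*\t*\tNH:i:2
r3\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*
"""


def test_sam_primary_single_alignment(tmp_path):
    p = _write(tmp_path, "a.sam", SAM)
    reads = {r.read_id: r for r in io.read_alignments(p, kind="sam") if r.read_id == "r1"}
    r = reads["r1"]
    assert (r.start, r.length, r.strand, r.weight) == (100, 28, "+", 1.0)


def test_sam_fractional_multimapper_weights(tmp_path):
    p = _write(tmp_path, "a.sam", SAM)
    r2 = [r for r in io.read_alignments(p, kind="sam") if r.read_id == "r2"]
    assert len(r2) == 2
    assert all(r.weight == 0.5 for r in r2)
    assert sum(r.weight for r in r2) == pytest.approx(1.0)


def test_sam_unmapped_skipped(tmp_path):
    p = _write(tmp_path, "a.sam", SAM)
    ids = {r.read_id for r in io.read_alignments(p, kind="sam")}
    assert "r3" not in ids


def test_tabular_round_trip(tmp_path):
    reads = [
        io.AlignedRead("a", "t1", 5, 21, "+", 1.0),
        io.AlignedRead("b", "t1", 9, 24, "-", 0.5),
        io.AlignedRead("b", "t1", 40, 24, "-", 0.5),
    ]
    p = tmp_path / "aln.tab"
    io.write_tabular_alignments(reads, p)
    assert list(io.read_alignments(p, kind="tabular")) == reads


# ---------------------------------------------------------------------------
# bedGraph

def test_bedgraph_merges_runs_and_drops_zeros(tmp_path):
    track = io.CoverageTrack("ref", np.array([0, 0, 3, 3, 1]), offset=10)
    p = tmp_path / "t.bedgraph"
    io.write_bedgraph(track, p)
    lines = [l for l in p.read_text().splitlines() if not l.startswith("track")]
    assert lines == ["ref\t12\t14\t3", "ref\t14\t15\t1"]


def test_bedgraph_all_zero_empty(tmp_path):
    p = tmp_path / "t.bedgraph"
    io.write_bedgraph(io.CoverageTrack("ref", np.zeros(5)), p)
    assert [l for l in p.read_text().splitlines() if not l.startswith("track")] == []


def test_bedgraph_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    values = rng.integers(0, 5, size=50).astype(float)
    track = io.CoverageTrack("ref", values, offset=7)
    p = tmp_path / "t.bedgraph"
    io.write_bedgraph(track, p)
    back = io.read_bedgraph(p)
    # round-trip reproduces values over the nonzero support
    nz = np.nonzero(values)[0]
    assert back.offset == 7 + nz[0]
    for i in nz:
        assert back.values[7 + i - back.offset] == values[i]
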