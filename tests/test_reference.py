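"""Reference construction from annotations and FASTA pairs."""

import pytest

from pseudoscan.reference import (
    GeneNotFoundError,
    InconsistentReferenceError,
    SequenceNotFoundError,
    build_from_annotation,
    build_from_fasta_pair,
    make_reference,
    validate_reference,
    write_reference_pair,
)
from pseudoscan.synth import emit, make_gene


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


TOY_GENOME = ">chr1\n" + "AACCGGTTAA" + "TCGATCGAT" + "A" + "CGCGCGATATAT" + "TTTTTTTTT" + "\n"
# CDS segments 10-19 and 30-41 (1-based inclusive): "TCGATCGATA" (10 nt), "CGATATATTTTT"? no:
# seq = AACCGGTTAA TCGATCGAT A CGCGCGATAT ATTTTTTTTT ; positions 10..19 -> indices 9..18


@pytest.fixture
def toy_gff3(tmp_path):
    genome = "AACCGGTTAATCGATCGATACGCGCGATATATTTTTTTTTT"
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttoy\tgene\t10\t41\t.\t+\t.\tID=g1",
            "chr1\ttoy\tmRNA\t10\t41\t.\t+\t.\tID=g1.t1;Parent=g1",
            "chr1\ttoy\tCDS\t10\t19\t.\t+\t0\tID=c1;Parent=g1.t1",
            "chr1\ttoy\tCDS\t30\t41\t.\t+\t1\tID=c2;Parent=g1.t1",
        ]
    ) + "\n"
    return (
        _write(tmp_path, "genome.fa", f">chr1\n{genome}\n"),
        _write(tmp_path, "ann.gff3", gff),
        genome,
    )


def test_two_exon_plus_strand_coordinates(toy_gff3):
    genome_path, gff_path, genome = toy_gff3
    ref = build_from_annotation(genome_path, gff_path, "g1")
    assert [len(e) for e in ref.exons] == [10, 12]
    assert len(ref.cds) == 22
    assert ref.exons[0].seq == genome[9:19]
    assert ref.exons[1].seq == genome[29:41]
    assert [e.phase for e in ref.exons] == [0, 1]
    assert ref.strand == "+"


def test_minus_strand_reverses_and_complements(tmp_path, toy_gff3):
    _, _, genome = toy_gff3
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttoy\tgene\t10\t41\t.\t-\t.\tID=g1",
            "chr1\ttoy\tmRNA\t10\t41\t.\t-\t.\tID=g1.t1;Parent=g1",
            "chr1\ttoy\tCDS\t10\t19\t.\t-\t0\tID=c1;Parent=g1.t1",
            "chr1\ttoy\tCDS\t30\t41\t.\t-\t0\tID=c2;Parent=g1.t1",
        ]
    ) + "\n"
    genome_path = _write(tmp_path, "g.fa", f">chr1\n{genome}\n")
    gff_path = _write(tmp_path, "a.gff3", gff)
    ref = build_from_annotation(genome_path, gff_path, "g1")
    from pseudoscan.align import reverse_complement

    assert ref.strand == "-"
    # highest-coordinate segment comes first, reverse-complemented
    assert ref.exons[0].seq == reverse_complement(genome[29:41])
    assert ref.exons[1].seq == reverse_complement(genome[9:19])


def test_gtf_dialect_is_autodetected(tmp_path, toy_gff3):
    _, _, genome = toy_gff3
    gtf = "\n".join(
        [
            'chr1\ttoy\tCDS\t10\t19\t.\t+\t0\tgene_id "g1"; transcript_id "g1.t1";',
            'chr1\ttoy\tCDS\t30\t41\t.\t+\t1\tgene_id "g1"; transcript_id "g1.t1";',
        ]
    ) + "\n"
    genome_path = _write(tmp_path, "g.fa", f">chr1\n{genome}\n")
    gtf_path = _write(tmp_path, "a.gtf", gtf)
    ref = build_from_annotation(genome_path, gtf_path, "g1")
    assert len(ref.cds) == 22


def test_longest_cds_transcript_selected_with_lexicographic_ties(tmp_path, toy_gff3):
    _, _, genome = toy_gff3
    gtf = "\n".join(
        [
            'chr1\ttoy\tCDS\t10\t19\t.\t+\t0\tgene_id "g1"; transcript_id "tB";',
            'chr1\ttoy\tCDS\t30\t41\t.\t+\t1\tgene_id "g1"; transcript_id "tB";',
            'chr1\ttoy\tCDS\t10\t19\t.\t+\t0\tgene_id "g1"; transcript_id "tA";',
        ]
    ) + "\n"
    genome_path = _write(tmp_path, "g.fa", f">chr1\n{genome}\n")
    gtf_path = _write(tmp_path, "a.gtf", gtf)
    assert len(build_from_annotation(genome_path, gtf_path, "g1").cds) == 22  # tB: longest
    # explicit transcript wins
    assert len(build_from_annotation(genome_path, gtf_path, "g1", "tA").cds) == 10
    # equal-length tie -> lexicographically smallest transcript id
    gtf2 = "\n".join(
        [
            'chr1\ttoy\tCDS\t30\t39\t.\t+\t0\tgene_id "g1"; transcript_id "tB";',
            'chr1\ttoy\tCDS\t10\t19\t.\t+\t0\tgene_id "g1"; transcript_id "tA";',
        ]
    ) + "\n"
    gtf2_path = _write(tmp_path, "a2.gtf", gtf2)
    ref = build_from_annotation(genome_path, gtf2_path, "g1")
    assert ref.exons[0].seq == genome[9:19]  # tA's segment


def test_missing_gene_and_sequence_errors(tmp_path, toy_gff3):
    genome_path, gff_path, genome = toy_gff3
    with pytest.raises(GeneNotFoundError, match="gene not found"):
        build_from_annotation(genome_path, gff_path, "nope")
    bad_genome = _write(tmp_path, "bad.fa", f">chrX\n{genome}\n")
    with pytest.raises(SequenceNotFoundError, match="sequence not found"):
        build_from_annotation(bad_genome, gff_path, "g1")


def test_fasta_pair_phases_and_ordering(tmp_path):
    cds = _write(tmp_path, "cds.fa", ">g\nATGAAATGA\n")
    exons = _write(tmp_path, "ex.fa", ">g_exon_0\nATGAAA\n>g_exon_1\nTGA\n")
    ref = build_from_fasta_pair(cds, exons)
    assert [e.phase for e in ref.exons] == [0, 0]
    assert ref.cds == "ATGAAATGA"
    # ordinal sorting beats file order
    exons_shuffled = _write(tmp_path, "ex2.fa", ">g_exon_1\nTGA\n>g_exon_0\nATGAAA\n")
    assert build_from_fasta_pair(cds, exons_shuffled).cds == "ATGAAATGA"
    # uneven split -> phase 5 mod 3 == 2
    exons_52 = _write(tmp_path, "ex3.fa", ">g_exon_0\nATGAA\n>g_exon_1\nATGA\n")
    assert [e.phase for e in build_from_fasta_pair(cds, exons_52).exons] == [0, 2]


def test_fasta_pair_mismatch_reports_first_divergence(tmp_path):
    cds = _write(tmp_path, "cds.fa", ">g\nATGAAATGA\n")
    exons = _write(tmp_path, "ex.fa", ">g_exon_0\nATGACA\n>g_exon_1\nTGA\n")
    with pytest.raises(InconsistentReferenceError, match="position 4"):
        build_from_fasta_pair(cds, exons)


def test_validate_reference_warnings():
    clean = make_gene(seed=2).ref
    assert validate_reference(clean) == []
    internal_stop = make_reference("g", ["ATGTAA", "CCCTGA"])
    warns = validate_reference(internal_stop)
    assert any("internal in-frame stop" in w and "codon 1" in w for w in warns)
    weird = make_reference("g", ["CCC", "ATAT"])
    warns = validate_reference(weird)
    assert any("ATG" in w for w in warns)
    assert any("terminal stop" in w for w in warns)
    assert sum("short exon" in w for w in warns) == 2


def test_annotation_round_trip_reproduces_fixture_cds(tmp_path):
    case = make_gene(seed=42, n_exons=5)
    paths = emit(case, tmp_path / "fx")
    rebuilt = build_from_annotation(paths["genome"], paths["annotation"], "gene1")
    assert rebuilt.cds == case.ref.cds
    assert [e.seq for e in rebuilt.exons] == [e.seq for e in case.ref.exons]


def test_minus_strand_involution_matches_plus_build(tmp_path):
    plus = make_gene(seed=42, n_exons=4, strand="+")
    minus = make_gene(seed=42, n_exons=4, strand="-")
    assert plus.ref.cds == minus.ref.cds  # same gene, either genomic orientation
    paths = emit_minus = None
    from pseudoscan.synth import _write_fasta  # reuse the writer

    gpath = tmp_path / "gm.fa"
    _write_fasta(gpath, [("chr1", minus.genome)])
    apath = tmp_path / "am.gff3"
    apath.write_text(minus.gff3)
    rebuilt = build_from_annotation(gpath, apath, "gene1")
    assert rebuilt.strand == "-"
    assert rebuilt.cds == plus.ref.cds
    assert [e.seq for e in rebuilt.exons] == [e.seq for e in plus.ref.exons]


def test_reference_pair_round_trip(tmp_path):
    ref = make_gene(seed=9).ref
    cds_p, ex_p = tmp_path / "c.fa", tmp_path / "e.fa"
    write_reference_pair(ref, cds_p, ex_p)
    rebuilt = build_from_fasta_pair(cds_p, ex_p)
    assert rebuilt.cds == ref.cds
    assert [e.seq for e in rebuilt.exons] == [e.seq for e in ref.exons]
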