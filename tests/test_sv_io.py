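"""VCF/GTF/FASTA canonicalization."""

from pathlib import Path

import pytest

from svneoantigen.model import Breakend, GenomeSequence, Orient
from svneoantigen.sv_io import (
    load_annotation,
    load_genome,
    parse_sv_vcf,
    write_bnd_vcf,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chr2,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=MATEID,Number=1,Type=String,Description="m">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf(tmp_path, body: str, name="x.vcf") -> str:
    path = tmp_path / name
    path.write_text(HEADER + body)
    return str(path)


def keyset(pairs):
    return {p.canonical_key() for p in pairs}


def test_header_only_vcf_yields_nothing(tmp_path):
    pairs, rejects = parse_sv_vcf(_vcf(tmp_path, ""))
    assert pairs == [] and rejects == []


def test_bnd_pair_canonicalized_per_bracket_semantics(tmp_path):
    body = ("chr1\t1000\tb1\tA\tA[chr2:5000[\t.\t.\tSVTYPE=BND;MATEID=b2\n"
            "chr2\t5000\tb2\tT\t]chr1:1000]T\t.\t.\tSVTYPE=BND;MATEID=b1\n")
    pairs, rejects = parse_sv_vcf(_vcf(tmp_path, body))
    assert not rejects
    assert len(pairs) == 1  # mates deduplicate to one junction
    assert pairs[0].canonical_key() == (
        ("chr1", 1000, "LEFT"), ("chr2", 5000, "RIGHT"))


def test_symbolic_del_matches_deletion_junction(tmp_path):
    body = "chr1\t1000\td1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=5000\n"
    pairs, rejects = parse_sv_vcf(_vcf(tmp_path, body))
    assert not rejects
    (p,) = pairs
    assert p.declared_type == "DEL"
    assert p.canonical_key() == (("chr1", 1000, "LEFT"), ("chr1", 5000, "RIGHT"))


def test_symbolic_and_bnd_encodings_are_equivalent(tmp_path):
    sym = "chr1\t1000\td1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=5000\n"
    bnd = ("chr1\t1000\td1_1\tN\tN[chr1:5000[\t.\t.\tSVTYPE=BND;MATEID=d1_2\n"
           "chr1\t5000\td1_2\tN\t]chr1:1000]N\t.\t.\tSVTYPE=BND;MATEID=d1_1\n")
    ps, _ = parse_sv_vcf(_vcf(tmp_path, sym, "s.vcf"))
    pb, _ = parse_sv_vcf(_vcf(tmp_path, bnd, "b.vcf"))
    assert keyset(ps) == keyset(pb)
    assert ps[0].id == pb[0].id == "d1"


def test_symbolic_inv_expands_to_both_junctions(tmp_path):
    body = "chr1\t1000\ti1\tN\t<INV>\t.\t.\tSVTYPE=INV;END=5000\n"
    pairs, _ = parse_sv_vcf(_vcf(tmp_path, body))
    assert {p.id for p in pairs} == {"i1_h2h", "i1_t2t"}
    assert keyset(pairs) == {
        (("chr1", 1000, "LEFT"), ("chr1", 5000, "LEFT")),
        (("chr1", 1000, "RIGHT"), ("chr1", 5000, "RIGHT"))}


@pytest.mark.parametrize("alt,reason", [
    ("A[chr2:5000", "unparseable ALT"),
    ("[chr2:5000[A[", "unparseable ALT"),
    ("<CPX>", "unknown symbolic type <CPX>"),
])
def test_bad_records_are_rejected_with_reason(tmp_path, alt, reason):
    body = f"chr1\t1000\tb1\tA\t{alt}\t.\t.\tSVTYPE=BND\n"
    pairs, rejects = parse_sv_vcf(_vcf(tmp_path, body))
    assert pairs == []
    assert [r.reason for r in rejects] == [reason]


def test_unpaired_bnd_rejected(tmp_path):
    body = "chr1\t1000\tb1\tA\tA[chr2:5000[\t.\t.\tSVTYPE=BND;MATEID=ghost\n"
    pairs, rejects = parse_sv_vcf(_vcf(tmp_path, body))
    assert pairs == []
    assert rejects[0].reason == "unpaired BND"


def test_mate_order_does_not_matter(tmp_path):
    a = ("chr1\t1000\tb1\tA\tA[chr2:5000[\t.\t.\tSVTYPE=BND;MATEID=b2\n"
         "chr2\t5000\tb2\tT\t]chr1:1000]T\t.\t.\tSVTYPE=BND;MATEID=b1\n")
    b = ("chr2\t5000\tb2\tT\t]chr1:1000]T\t.\t.\tSVTYPE=BND;MATEID=b1\n"
         "chr1\t1000\tb1\tA\tA[chr2:5000[\t.\t.\tSVTYPE=BND;MATEID=b2\n")
    pa, _ = parse_sv_vcf(_vcf(tmp_path, a, "a.vcf"))
    pb, _ = parse_sv_vcf(_vcf(tmp_path, b, "b.vcf"))
    assert keyset(pa) == keyset(pb)


def test_round_trip_through_bnd_vcf(bundle, tmp_path):
    pairs, rejects = parse_sv_vcf(str(bundle.vcf_bnd))
    assert not rejects
    out = tmp_path / "roundtrip.vcf"
    write_bnd_vcf(pairs, str(out))
    again, rejects2 = parse_sv_vcf(str(out))
    assert not rejects2
    assert keyset(again) == keyset(pairs)
    assert {p.id for p in again} == {p.id for p in pairs}


def test_fixture_dialects_parse_to_same_junctions(bundle):
    pb, _ = parse_sv_vcf(str(bundle.vcf_bnd))
    ps, _ = parse_sv_vcf(str(bundle.vcf_symbolic))
    assert keyset(pb) == keyset(ps)


def test_chromosome_normalization_against_genome(tmp_path):
    genome = GenomeSequence({"1": "ACGT" * 2000})
    body = "chr1\t100\td1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=500\n"
    pairs, _ = parse_sv_vcf(_vcf(tmp_path, body), genome=genome)
    assert pairs[0].first.chrom == "1"
    bad = GenomeSequence({"weird": "ACGT"})
    with pytest.raises(ValueError, match="not found in genome"):
        parse_sv_vcf(_vcf(tmp_path, body, "y.vcf"), genome=bad)


# -- annotation -------------------------------------------------------------


def test_fixture_annotation_reconstructs_all_genes(bundle):
    txdb = load_annotation(str(bundle.gtf))
    assert len(txdb.genes) == 7
    for gid in txdb.genes:
        tx = txdb.select_transcript(gid)
        assert tx is not None and tx.cds_length > 0
        assert tx.cds_length % 3 == 0


def test_utr_cds_lengths_partition_the_transcript(bundle):
    txdb = load_annotation(str(bundle.gtf))
    for tx in txdb.transcripts.values():
        assert tx.utr5_length + tx.cds_length + tx.utr3_length == tx.exonic_length


def test_minus_strand_exons_in_transcription_order(bundle):
    txdb = load_annotation(str(bundle.gtf))
    minus = [t for t in txdb.transcripts.values() if t.strand == "-"]
    assert minus
    for tx in minus:
        starts = [s for s, _ in tx.exons]
        assert starts == sorted(starts, reverse=True)


ISOFORM_GTF = """\
c\tx\texon\t1\t500\t.\t+\t.\tgene_id "g"; transcript_id "t_b";
c\tx\tCDS\t101\t550\t.\t+\t.\tgene_id "g"; transcript_id "t_b";
c\tx\texon\t1\t600\t.\t+\t.\tgene_id "g"; transcript_id "t_a";
c\tx\tCDS\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "t_a";
c\tx\texon\t700\t900\t.\t+\t.\tgene_id "g"; transcript_id "t_nc";
c\tx\texon\t1\t300\t.\t+\t.\tgene_id "h"; transcript_id "h_nc";
"""


def test_select_transcript_longest_cds_then_lexicographic(tmp_path):
    # t_b has CDS outside its exon -> excluded as malformed; t_a (300 nt CDS)
    # wins over the noncoding isoform; gene h has no coding isoform at all
    path = tmp_path / "iso.gtf"
    path.write_text(ISOFORM_GTF)
    txdb = load_annotation(str(path))
    assert "t_b" not in txdb.transcripts  # malformed: CDS not within exons
    assert txdb.select_transcript("g").transcript_id == "t_a"
    assert txdb.select_transcript("h") is None


def test_select_transcript_tie_breaks_on_id(tmp_path):
    rows = []
    for tid in ("t2", "t1"):
        rows.append(f'c\tx\texon\t1\t400\t.\t+\t.\tgene_id "g"; transcript_id "{tid}";')
        rows.append(f'c\tx\tCDS\t101\t400\t.\t+\t.\tgene_id "g"; transcript_id "{tid}";')
    path = tmp_path / "tie.gtf"
    path.write_text("\n".join(rows) + "\n")
    txdb = load_annotation(str(path))
    assert txdb.select_transcript("g").transcript_id == "t1"


# -- genome -----------------------------------------------------------------


def test_genome_accessors(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">c\nACGT\n")
    g = load_genome(str(path))
    assert g.fetch("c", 0, 2) == "AC"
    assert g.fetch("c", 2, 4) == "GT"
    assert GenomeSequence.revcomp("ACGT") == "ACGT"  # palindrome
    with pytest.raises(ValueError, match="out of bounds"):
        g.fetch("c", 2, 5)
    with pytest.raises(KeyError):
        g.fetch("missing", 0, 1)


def test_duplicate_fasta_name_is_an_error(tmp_path):
    path = tmp_path / "dup.fa"
    path.write_text(">c\nACGT\n>c\nTTTT\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_genome(str(path))


def test_breakend_position_must_be_positive():
    with pytest.raises(ValueError):
        Breakend("chr1", 0, Orient.LEFT)
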