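"""Neo-transcript assembly, frame arithmetic, translation, mutated spans."""

import pytest

from helpers import oracle_outcome, random_junctions, run_one_junction
from svneoantigen import _oracle
from svneoantigen.annotate import SINGLE_GENE, TWO_GENE, annotate_pair
from svneoantigen.model import (
    Breakend,
    NeoProtein,
    NeoTranscript,
    Orient,
    RejectReason,
    SvBreakendPair,
    Termination,
    TranscriptModel,
)
from svneoantigen.neoorf import (
    NeoOrfConfig,
    NeoOrfRejection,
    assemble_neo_transcript,
    determine_frame,
    mutated_interval,
    translate_neo,
)

L, R = Orient.LEFT, Orient.RIGHT


def pair(c1, p1, o1, c2, p2, o2, pid="t"):
    return SvBreakendPair(pid, Breakend(c1, p1, o1), Breakend(c2, p2, o2))


def _toy_tx(layout, genome_seq=None):
    return layout.tx_seq


# -- assembly: hand-spliced expectations on the toy genes -------------------


def test_intronic_deletion_splices_exon1_to_exon3(toy_txdb, toy_genome, toy_ref):
    # gene A: exon1 [100,200), intron1 [200,250), exon2 [250,330),
    # intron2 [330,380), exon3 [380,460) (0-based genomic)
    ann = annotate_pair(pair("cA", 220, L, "cA", 350, R), toy_txdb)
    assert ann.feasible
    nt = assemble_neo_transcript(ann, toy_txdb, toy_genome)
    tx = toy_ref["ref"].layout("GA").tx_seq
    assert nt.mrna == tx[:100] + tx[180:]  # exon1 + exon3
    assert nt.junction_nt == 100
    assert nt.donor_cds_contribution == 90


def test_two_gene_fusion_donorA_exon1_acceptorB_exon3(toy_txdb, toy_genome, toy_ref):
    # donor gene A intron 1; acceptor gene B intron 2 (genomic [180,230) on cB)
    ann = annotate_pair(pair("cA", 220, L, "cB", 200, L), toy_txdb)
    assert ann.feasible and ann.gene_context == TWO_GENE
    nt = assemble_neo_transcript(ann, toy_txdb, toy_genome)
    ta = toy_ref["ref"].layout("GA").tx_seq
    tb = toy_ref["ref"].layout("GB").tx_seq
    assert nt.mrna == ta[:100] + tb[180:]
    assert nt.junction_nt == 100


def test_exonic_breakends_truncate_at_retained_base(toy_txdb, toy_genome, toy_ref):
    ann = annotate_pair(pair("cA", 150, L, "cA", 440, R), toy_txdb)
    nt = assemble_neo_transcript(ann, toy_txdb, toy_genome)
    tx = toy_ref["ref"].layout("GA").tx_seq
    assert nt.mrna.startswith(tx[:50])  # 50 retained bases of exon 1
    assert nt.junction_nt == 50


def test_start_codon_loss_rejected_without_rescue(toy_txdb, toy_genome):
    ann = annotate_pair(pair("cA", 105, L, "cA", 220, R), toy_txdb)
    assert ann.feasible  # UTR5 donor passes the orientation filter
    with pytest.raises(NeoOrfRejection) as exc:
        assemble_neo_transcript(ann, toy_txdb, toy_genome)
    assert exc.value.reason is RejectReason.NO_UTR_STRUCTURE


def test_start_rescue_uses_first_downstream_atg(toy_txdb, toy_genome):
    ann = annotate_pair(pair("cA", 105, L, "cA", 220, R), toy_txdb)
    nt = assemble_neo_transcript(ann, toy_txdb, toy_genome,
                                 NeoOrfConfig(start_rescue=True))
    assert nt.start_rescued
    assert nt.mrna[nt.cds_start_nt:nt.cds_start_nt + 3] == "ATG"


# -- frame arithmetic -------------------------------------------------------


def _dummy_tx(tid="d"):
    return TranscriptModel(tid, "g", "g", "c", "+", [(0, 300)], [(0, 300)])


def _stub(mrna, junction_nt, cds_start=0, phase=None, gap=0, single=True):
    return NeoTranscript(
        sv_id="s", donor_transcript=_dummy_tx(), acceptor_transcript=_dummy_tx(),
        mrna=mrna, junction_nt=junction_nt, cds_start_nt=cds_start,
        donor_cds_contribution=junction_nt - cds_start,
        acceptor_native_phase=phase, acceptor_utr_gap=gap, single_gene=single)


@pytest.mark.parametrize("contrib,phase,expect", [
    (120, 0, False),  # 120 mod 3 == 0 == native phase
    (121, 0, True),
    (121, 1, False),
    (119, 2, False),
])
def test_determine_frame_phase_arithmetic(contrib, phase, expect):
    nt = _stub("A" * 400, junction_nt=contrib, cds_start=0, phase=phase)
    assert determine_frame(nt) is expect


def test_no_coding_context_is_always_frameshift():
    nt = _stub("A" * 60, junction_nt=30, phase=None)
    assert determine_frame(nt) is True


def test_acceptor_utr_gap_shifts_the_phase():
    # junction in the acceptor 5'UTR: gap nt precede its CDS (native phase 0)
    assert determine_frame(_stub("A" * 60, 30, phase=0, gap=3)) is False
    assert determine_frame(_stub("A" * 60, 30, phase=0, gap=2)) is True


# -- translation ------------------------------------------------------------


def test_translation_stops_at_first_stop_codon():
    np_ = translate_neo(_stub("ATGGCCTAAGGG", junction_nt=12))
    assert np_.sequence == "MA"
    assert np_.termination is Termination.STOP


def test_translation_reads_through_without_stop():
    np_ = translate_neo(_stub("ATGGCCGGA", junction_nt=9))
    assert np_.sequence == "MAG"
    assert np_.termination is Termination.READ_THROUGH


def test_trailing_partial_codon_discarded():
    np_ = translate_neo(_stub("ATGGCCGG", junction_nt=8))
    assert np_.sequence == "MA"
    assert np_.termination is Termination.READ_THROUGH


def test_codons_with_n_translate_to_x():
    np_ = translate_neo(_stub("ATGGNCGGA", junction_nt=9))
    assert np_.sequence == "MXG"


def test_frameshift_concat_matches_single_frame_oracle():
    donor, acceptor = "ATGGC", "CAGGTAAGGGCCC"
    mrna = donor + acceptor
    np_ = translate_neo(_stub(mrna, junction_nt=len(donor)))
    assert np_.sequence == _oracle.translate(mrna)


# -- mutated interval -------------------------------------------------------


def _prot(seq, frameshift=False, context=SINGLE_GENE,
          termination=Termination.STOP):
    return NeoProtein(sv_id="s", sequence=seq, junction_aa=0,
                      frameshift=frameshift, termination=termination,
                      start_rescued=False, mutated_span=(0, 0),
                      gene_context=context)


def test_mutated_span_first_difference_to_end_for_frameshift():
    p = _prot("MAXYZ", frameshift=True)
    assert mutated_interval(p, "MABCD") == (2, 5)


def test_mutated_span_in_frame_single_gene_trims_both_sides():
    assert mutated_interval(_prot("MAXYZ"), "MABCD") == (2, 5)
    # exact prefix+suffix of wild type: empty span
    assert mutated_interval(_prot("MABDE"), "MABCDE") == (3, 3)
    # in-frame duplication: minimum one junction residue
    assert mutated_interval(_prot("MABBCD"), "MABCD") == (3, 4)


def test_mutated_span_long_frameshift():
    wt = "M" + "A" * 40
    seq = wt[:7] + "W" * 23
    assert mutated_interval(_prot(seq, frameshift=True), wt) == (7, 30)


def test_identical_sequences_give_empty_span():
    assert mutated_interval(_prot("MABCD"), "MABCD") == (5, 5)


# -- fixture-level invariants ----------------------------------------------


def test_inframe_two_gene_fusion_is_prefix_plus_suffix(bundle, run_always,
                                                       truth_by_id):
    """donor wild-type prefix + acceptor wild-type suffix, junction at
    donor_cds_contribution / 3."""
    from svneoantigen.sv_io import load_annotation, load_genome
    txdb = load_annotation(str(bundle.gtf))
    genome = load_genome(str(bundle.fasta))
    prot = next(p for p in run_always.proteins if p.sv_id == "del_twogene_inframe")
    assert not prot.frameshift
    wt_d = txdb.proteome(genome)[prot.donor_gene]
    wt_a = txdb.proteome(genome)[prot.acceptor_gene]
    k = prot.junction_aa
    assert prot.sequence[:k] == wt_d[:k]
    assert prot.sequence[k + 1:] in wt_a  # suffix of the acceptor protein
    assert prot.sequence.endswith(wt_a[-10:])


def test_translation_agrees_with_oracle_on_randomized_junctions(bundle):
    """Randomized breakend pairs: the assembled/translated product equals
    the naive oracle's single-frame translation of the hand-assembled
    chimera, including STOP vs READ_THROUGH and the mutated span."""
    from svneoantigen.sv_io import load_annotation, load_genome
    txdb = load_annotation(str(bundle.gtf))
    genome = load_genome(str(bundle.fasta))
    gtf = _oracle.load_gtf(str(bundle.gtf))
    gdict = _oracle.load_fasta(str(bundle.fasta))
    n_feasible = 0
    for p in random_junctions(bundle.reference, seed=7, n=320):
        status, np_ = run_one_junction(p, txdb, genome)
        expected = oracle_outcome(p, gtf, gdict)
        if expected["feasible"]:
            assert status == "OK", (p, status)
            assert np_.sequence == expected["protein"]
            assert np_.termination.value == expected["termination"]
            assert tuple(np_.mutated_span) == tuple(expected["span"])
            assert np_.frameshift == expected["frameshift"]
            n_feasible += 1
        else:
            assert status == expected["reject"], (p, status, expected["reject"])
    assert n_feasible >= 100  # enough feasible junctions actually exercised
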