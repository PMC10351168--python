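"""Chimeric neo-transcript assembly and frameshift-aware translation.

For every feasible junction the donor transcript contributes its 5' portion
(from the transcription start to the breakend) and the acceptor its 3'
portion (from the breakend to the transcript end).  Intronic breakends
splice at the nearest complete exon boundary on the retained side — the
standard fusion-transcript convention (donor 5' splice site joined to the
acceptor 3' splice site); exonic breakends truncate the exon at the
retained base, producing junction-derived codons.

Translation starts at the donor's start codon and runs by the standard
codon table until the first stop codon (``STOP``) or the transcript's 3'
boundary (``READ_THROUGH``, trailing partial codon discarded).  Codons
containing N translate to X.  When the donor start codon is lost the event
is rejected unless start-codon rescue is enabled, in which case the first
downstream ATG is used and the protein is flagged ``start_rescued`` (such
proteins are excluded from neoantigen calling by default because the true
translation start is uncertain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .annotate import SINGLE_GENE, TWO_GENE
from .model import (
    AnnotatedBreakend,
    GenomeSequence,
    NeoProtein,
    NeoTranscript,
    RejectReason,
    SvAnnotation,
    Termination,
    TranscriptModel,
)
from .sv_io import TranscriptDatabase

_CODON = CodonTable.unambiguous_dna_by_name["Standard"].forward_table
_STOPS = set(CodonTable.unambiguous_dna_by_name["Standard"].stop_codons)


class NeoOrfRejection(Exception):
    """Structural rejection during assembly/translation."""

    def __init__(self, reason: RejectReason, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason.value}{': ' + detail if detail else ''}")


@dataclass
class NeoOrfConfig:
    start_rescue: bool = False
    include_start_rescued: bool = False
    intergenic_tail_nt: int = 300  # acceptor tail length for intergenic acceptors


def donor_prefix_length(tx: TranscriptModel, end: AnnotatedBreakend) -> int:
    """Transcript nt retained 5' of the junction on the donor side."""
    pos0 = end.breakend.pos0
    off = tx.genomic_to_tx(pos0)
    if off is not None:  # exonic: truncate at the retained base (inclusive)
        return off + 1
    intron_i = tx.containing_intron(pos0)
    if intron_i is None:
        raise ValueError(f"donor breakend {end.breakend} outside transcript "
                         f"{tx.transcript_id}")
    return tx.cumulative_exon_length(intron_i + 1)


def acceptor_suffix_start(tx: TranscriptModel, end: AnnotatedBreakend) -> int:
    """Transcript offset of the first retained acceptor base."""
    pos0 = end.breakend.pos0
    off = tx.genomic_to_tx(pos0)
    if off is not None:
        return off
    intron_i = tx.containing_intron(pos0)
    if intron_i is None:
        raise ValueError(f"acceptor breakend {end.breakend} outside transcript "
                         f"{tx.transcript_id}")
    return tx.cumulative_exon_length(intron_i + 1)  # first base of the next exon


def _intergenic_tail(end: AnnotatedBreakend, genome: GenomeSequence,
                     length: int) -> str:
    """Genomic tail read 5'->3' away from an intergenic acceptor breakend."""
    b = end.breakend
    contig_len = genome.length(b.chrom)
    if b.orient.value == "RIGHT":
        return genome.fetch(b.chrom, b.pos0, min(b.pos0 + length, contig_len))
    seg = genome.fetch(b.chrom, max(0, b.pos0 + 1 - length), b.pos0 + 1)
    return GenomeSequence.revcomp(seg)


def assemble_neo_transcript(ann: SvAnnotation, txdb: TranscriptDatabase,
                            genome: GenomeSequence,
                            config: Optional[NeoOrfConfig] = None) -> NeoTranscript:
    """Build the spliced chimeric mRNA for a feasible junction.

    Raises :class:`NeoOrfRejection` with reason ``NO_UTR_STRUCTURE`` when the
    chimera lacks the donor 5'UTR/start codon or any 3' sequence, or
    ``NO_START`` when rescue is on but no downstream ATG exists.
    """
    config = config or NeoOrfConfig()
    if not ann.feasible or ann.donor is None:
        raise ValueError("assemble_neo_transcript requires a feasible annotation")
    donor, acceptor = ann.donor, ann.acceptor
    donor_tx = donor.transcript
    assert donor_tx is not None

    prefix_len = donor_prefix_length(donor_tx, donor)
    prefix = donor_tx.sequence(genome)[:prefix_len]

    acceptor_tx = acceptor.transcript
    acc_phase: Optional[int] = None
    acc_gap = 0
    if acceptor_tx is not None:
        acc_start = acceptor_suffix_start(acceptor_tx, acceptor)
        suffix = acceptor_tx.sequence(genome)[acc_start:]
        if acceptor_tx.is_coding:
            a5, acds = acceptor_tx.utr5_length, acceptor_tx.cds_length
            if acc_start < a5:
                acc_phase, acc_gap = 0, a5 - acc_start
            elif acc_start < a5 + acds:
                acc_phase, acc_gap = (acc_start - a5) % 3, 0
        single_gene = donor_tx.gene_id == acceptor_tx.gene_id
    else:
        suffix = _intergenic_tail(acceptor, genome, config.intergenic_tail_nt)
        acceptor_tx = donor_tx  # read-through into intergenic space
        single_gene = True

    if not suffix:
        raise NeoOrfRejection(RejectReason.NO_UTR_STRUCTURE, "no 3' sequence")

    mrna = prefix + suffix
    utr5 = donor_tx.utr5_length
    cds_contrib = min(max(prefix_len - utr5, 0), donor_tx.cds_length)
    start_rescued = False
    if prefix_len < utr5 + 3:  # donor start codon lost (fully or split)
        if not config.start_rescue:
            raise NeoOrfRejection(RejectReason.NO_UTR_STRUCTURE,
                                  "donor start codon lost")
        idx = mrna.find("ATG")
        if idx < 0:
            raise NeoOrfRejection(RejectReason.NO_START)
        cds_start, start_rescued = idx, True
    else:
        cds_start = utr5

    return NeoTranscript(
        sv_id=ann.pair.id,
        donor_transcript=donor_tx,
        acceptor_transcript=acceptor_tx,
        mrna=mrna,
        junction_nt=prefix_len,
        cds_start_nt=cds_start,
        donor_cds_contribution=cds_contrib,
        start_rescued=start_rescued,
        acceptor_native_phase=acc_phase,
        acceptor_utr_gap=acc_gap,
        single_gene=single_gene,
    )


def determine_frame(nt: NeoTranscript) -> bool:
    """True when the junction shifts the reading frame.

    The first acceptor-derived coding base must land at its native codon
    phase for the downstream wild-type protein to reappear; acceptor tails
    with no native coding context (3'UTR, intergenic) are always novel.
    """
    if nt.acceptor_native_phase is None:
        return True
    chim_off = nt.junction_nt + nt.acceptor_utr_gap - nt.cds_start_nt
    return chim_off % 3 != nt.acceptor_native_phase


def translate_neo(nt: NeoTranscript,
                  config: Optional[NeoOrfConfig] = None) -> NeoProtein:
    """Translate the chimeric mRNA into a neo-protein."""
    config = config or NeoOrfConfig()
    cds = nt.mrna[nt.cds_start_nt:]
    residues: list[str] = []
    termination = Termination.READ_THROUGH
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if codon in _STOPS:
            termination = Termination.STOP
            break
        residues.append(_CODON.get(codon, "X"))
    sequence = "".join(residues)
    if not sequence:
        raise NeoOrfRejection(RejectReason.NO_UTR_STRUCTURE, "empty translation")
    junction_aa = max(0, nt.junction_nt - nt.cds_start_nt) // 3
    return NeoProtein(
        sv_id=nt.sv_id,
        sequence=sequence,
        junction_aa=min(junction_aa, len(sequence)),
        frameshift=determine_frame(nt),
        termination=termination,
        start_rescued=nt.start_rescued,
        mutated_span=(0, 0),  # filled by mutated_interval
        donor_gene=nt.donor_transcript.gene_id,
        acceptor_gene=nt.acceptor_transcript.gene_id,
        gene_context=SINGLE_GENE if nt.single_gene else TWO_GENE,
    )


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def mutated_interval(np_: NeoProtein, wt: str) -> tuple[int, int]:
    """Half-open residue interval of ``np_.sequence`` differing from the
    donor wild-type protein.

    Frameshift, two-gene, and read-through products diverge from the first
    mismatch to the protein's end.  In-frame single-gene events are trimmed
    from both sides, so a deletion whose junction residues are identical to
    wild type yields an empty span (and thus zero neo-peptides).
    """
    s = np_.sequence
    p = _common_prefix(s, wt)
    open_ended = (np_.frameshift or np_.gene_context == TWO_GENE
                  or np_.termination is Termination.READ_THROUGH)
    if open_ended:
        span = (p, len(s)) if p < len(s) else (p, p)
    else:
        suf = _common_suffix(s, wt)
        suf = min(suf, len(s) - p, len(wt) - p)
        span = (p, max(p, len(s) - suf))
    np_.mutated_span = span
    return span


# ---------------------------------------------------------------------------
# Output writers


def write_neoprotein_fasta(proteins, path: str) -> None:
    with open(path, "w") as fh:
        for np_ in proteins:
            fh.write(f">{np_.sv_id}|{np_.donor_gene}|{np_.acceptor_gene}|"
                     f"{'frameshift' if np_.frameshift else 'inframe'}|"
                     f"{np_.termination.value}\n{np_.sequence}\n")


def write_neoorf_table(proteins, path: str) -> None:
    cols = ["sv_id", "donor_gene", "acceptor_gene", "gene_context", "frameshift",
            "termination", "start_rescued", "junction_aa", "mutated_start",
            "mutated_end", "length", "sequence"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for np_ in proteins:
            fh.write("\t".join(map(str, [
                np_.sv_id, np_.donor_gene, np_.acceptor_gene, np_.gene_context,
                np_.frameshift, np_.termination.value, np_.start_rescued,
                np_.junction_aa, np_.mutated_span[0], np_.mutated_span[1],
                len(np_.sequence), np_.sequence,
            ])) + "\n")
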