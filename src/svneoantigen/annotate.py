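"""Breakend-to-transcript mapping, SV classification, and feasibility filters.

An SV junction can only produce a protein-altering transcript when a
continuous 5'->3' transcription path exists across it: one breakend must
retain the side containing its transcript's promoter (the *donor*) and the
other the side containing its transcript's 3' remainder (the *acceptor*).
Junctions with intergenic breakends, or orientations admitting no such
donor/acceptor assignment, are filtered with an explicit reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    AnnotatedBreakend,
    Breakend,
    Orient,
    RegionKind,
    RejectReason,
    SvAnnotation,
    SvBreakendPair,
    SvClass,
    TranscriptModel,
)
from .sv_io import TranscriptDatabase

SINGLE_GENE = "SINGLE_GENE"
TWO_GENE = "TWO_GENE"


def classify_sv(pair: SvBreakendPair) -> SvClass:
    """Junction class from breakend orientations (swap-invariant)."""
    a, b = pair.ordered()
    if a.chrom != b.chrom:
        return SvClass.TRANSLOCATION
    key = (a.orient, b.orient)
    return {
        (Orient.LEFT, Orient.RIGHT): SvClass.DELETION_LIKE,
        (Orient.RIGHT, Orient.LEFT): SvClass.DUPLICATION_LIKE,
        (Orient.LEFT, Orient.LEFT): SvClass.H2H_INVERSION,
        (Orient.RIGHT, Orient.RIGHT): SvClass.T2T_INVERSION,
    }[key]


def _pick_gene(gene_ids: list[str], txdb: TranscriptDatabase) -> Optional[str]:
    """Among overlapping genes, the one whose selected isoform has the
    longest CDS; ties broken by lexicographic gene id."""
    best: Optional[tuple[int, str]] = None
    for gid in gene_ids:
        t = txdb.select_transcript(gid)
        if t is None:
            continue
        cand = (-t.cds_length, gid)
        if best is None or cand < best:
            best = cand
    return best[1] if best else None


def map_breakend(b: Breakend, txdb: TranscriptDatabase) -> AnnotatedBreakend:
    """Attach the selected isoform of the overlapping gene and locate the
    breakend within it (exon/intron index, UTR class, coding offset)."""
    gid = _pick_gene(txdb.genes_at(b.chrom, b.pos0), txdb)
    if gid is None:
        return AnnotatedBreakend(b, None, RegionKind.INTERGENIC)
    tx = txdb.select_transcript(gid)
    assert tx is not None
    exon_i = tx.containing_exon(b.pos0)
    if exon_i is not None:
        off = tx.genomic_to_tx(b.pos0)
        assert off is not None
        cds_off = min(max(off - tx.utr5_length, 0), tx.cds_length)
        if off < tx.utr5_length:
            region, idx = RegionKind.UTR5, exon_i + 1
        elif off >= tx.utr5_length + tx.cds_length:
            region, idx = RegionKind.UTR3, exon_i + 1
        else:
            region, idx = RegionKind.EXON, exon_i + 1
        return AnnotatedBreakend(b, tx, region, idx, cds_off)
    intron_i = tx.containing_intron(b.pos0)
    if intron_i is not None:
        upstream = tx.cumulative_exon_length(intron_i + 1)
        cds_off = min(max(upstream - tx.utr5_length, 0), tx.cds_length)
        if upstream <= tx.utr5_length:
            region: RegionKind = RegionKind.UTR5
        elif upstream >= tx.utr5_length + tx.cds_length:
            region = RegionKind.UTR3
        else:
            region = RegionKind.INTRON
        return AnnotatedBreakend(b, tx, region, intron_i + 1, cds_off)
    # overlaps the gene span of some isoform but not the selected one
    return AnnotatedBreakend(b, None, RegionKind.INTERGENIC)


def _promoter_side(strand: str) -> Orient:
    return Orient.LEFT if strand == "+" else Orient.RIGHT


def _three_prime_side(strand: str) -> Orient:
    return Orient.RIGHT if strand == "+" else Orient.LEFT


def _donor_ok(end: AnnotatedBreakend) -> bool:
    """Retained side of a donor must contain its transcript's promoter."""
    return end.transcript is not None and \
        end.breakend.orient is _promoter_side(end.transcript.strand)


def _acceptor_ok(end: AnnotatedBreakend, allow_intergenic: bool) -> bool:
    """Retained side of an acceptor must contain the 3' remainder."""
    if end.transcript is None:
        return allow_intergenic
    return end.breakend.orient is _three_prime_side(end.transcript.strand)


@dataclass
class FilterConfig:
    allow_one_intergenic: bool = False


def annotate_pair(pair: SvBreakendPair, txdb: TranscriptDatabase,
                  config: Optional[FilterConfig] = None) -> SvAnnotation:
    """Map both breakends, classify, and apply feasibility filters."""
    ends = (map_breakend(pair.first, txdb), map_breakend(pair.second, txdb))
    a, b = pair.ordered()
    span = abs(a.pos - b.pos) if a.chrom == b.chrom and a.pos != b.pos else None
    ann = SvAnnotation(pair=pair, ends=ends, sv_class=classify_sv(pair), span=span)
    return apply_filters(ann, config)


def apply_filters(ann: SvAnnotation,
                  config: Optional[FilterConfig] = None) -> SvAnnotation:
    """Set the feasible flag / reject reason and record donor/acceptor roles.

    Rejection reasons, in precedence order: INTERGENIC (either end outside
    any coding gene, unless ``allow_one_intergenic`` spares single-end
    cases), ORIENTATION (no continuous transcription path), and
    NO_CODING_EFFECT (only a 3'UTR-donor assignment exists, which leaves the
    protein unchanged).
    """
    config = config or FilterConfig()
    n_intergenic = sum(1 for e in ann.ends if e.transcript is None)
    allow = config.allow_one_intergenic and n_intergenic == 1
    if n_intergenic and not allow:
        ann.feasible = False
        ann.reject_reason = RejectReason.INTERGENIC
        return ann

    viable: list[int] = []  # donor end index of each orientation-feasible assignment
    for donor_idx in (0, 1):
        donor, acceptor = ann.ends[donor_idx], ann.ends[1 - donor_idx]
        if _donor_ok(donor) and _acceptor_ok(acceptor, allow):
            viable.append(donor_idx)
    if not viable:
        ann.feasible = False
        ann.reject_reason = RejectReason.ORIENTATION
        return ann

    coding = [i for i in viable if ann.ends[i].region is not RegionKind.UTR3]
    if not coding:
        ann.feasible = False
        ann.reject_reason = RejectReason.NO_CODING_EFFECT
        return ann

    ann.donor_index = coding[0]
    ann.feasible = True
    donor_tx = ann.donor.transcript
    acceptor_tx = ann.acceptor.transcript
    if acceptor_tx is None or donor_tx.gene_id == acceptor_tx.gene_id:
        ann.gene_context = SINGLE_GENE
    else:
        ann.gene_context = TWO_GENE
    return ann


def write_annotation_table(annotations, path: str) -> None:
    cols = ["id", "sv_class", "chromA", "posA", "orientA", "regionA", "geneA",
            "chromB", "posB", "orientB", "regionB", "geneB", "span",
            "gene_context", "feasible", "reject_reason", "donor_gene"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in annotations:
            row = [ann.pair.id, ann.sv_class.value]
            for e in ann.ends:
                gene = e.transcript.gene_id if e.transcript else "."
                region = e.region.value
                if e.region_index is not None and e.region in (RegionKind.EXON, RegionKind.INTRON):
                    region = f"{region}{e.region_index}"
                row += [e.breakend.chrom, str(e.breakend.pos),
                        e.breakend.orient.value, region, gene]
            donor_gene = "."
            if ann.donor is not None and ann.donor.transcript is not None:
                donor_gene = ann.donor.transcript.gene_id
            row += [str(ann.span) if ann.span else ".",
                    ann.gene_context or ".", str(ann.feasible),
                    ann.reject_reason.value if ann.reject_reason else ".",
                    donor_gene]
            fh.write("\t".join(row) + "\n")
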