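"""Readers and writers for the three standard inputs.

Somatic SV calls arrive as VCF (breakend ``BND`` records or symbolic
``<DEL>/<DUP>/<INV>`` alleles), transcript structure as Ensembl-style GTF,
and the reference as FASTA.  Everything is canonicalized into the internal
data model at this boundary: VCF/GTF 1-based coordinates become 0-based
half-open intervals, and the four VCF bracket forms become side-retained
{LEFT, RIGHT} orientations.

Symbolic-allele convention used throughout this package: ``POS`` and ``END``
are the two junction bases themselves, so a ``<DEL>`` with POS=p, END=e
joins base p (left flank) to base e (right flank) and deletes the bases
strictly between them.  A ``<INV>`` expands into its two junctions
(head-to-head and tail-to-tail), processed independently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .model import (
    Breakend,
    Clonality,
    GenomeSequence,
    Orient,
    SvBreakendPair,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

# t[p[ / t]p] / ]p]t / [p[t
_BND_RE = re.compile(
    r"^(?P<prefix>[A-Za-z]*)(?P<br1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)"
    r"(?P<br2>[\[\]])(?P<suffix>[A-Za-z]*)$"
)

_SYMBOLIC_RE = re.compile(r"^<(?P<kind>[A-Za-z0-9:]+)>$")


@dataclass
class RejectedRecord:
    record_id: str
    reason: str


def _normalize_chrom(chrom: str, genome: Optional[GenomeSequence]) -> str:
    """Match the genome's chromosome naming, toggling the 'chr' prefix."""
    if genome is None:
        return chrom
    if chrom in genome:
        return chrom
    alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
    if alt in genome:
        return alt
    raise ValueError(f"chromosome {chrom!r} not found in genome (tried {alt!r} too)")


def _parse_bracket_alt(alt: str) -> Optional[tuple[Orient, str, int, Orient, str]]:
    """Decode a BND bracket ALT.

    Returns (local_orient, mate_chrom, mate_pos, mate_orient, inserted_seq)
    or None when the ALT does not parse.  The local breakend retains its
    left flank when the replacement string leads with reference sequence
    (``t[p[`` / ``t]p]``) and its right flank otherwise; ``[`` points at a
    mate that retains its right flank, ``]`` one that retains its left.
    """
    m = _BND_RE.match(alt)
    if not m:
        return None
    if m.group("br1") != m.group("br2"):
        return None
    prefix, suffix = m.group("prefix"), m.group("suffix")
    if bool(prefix) == bool(suffix):  # exactly one side must carry sequence
        return None
    local_orient = Orient.LEFT if prefix else Orient.RIGHT
    mate_orient = Orient.RIGHT if m.group("br1") == "[" else Orient.LEFT
    # bases beyond the single REF base are novel inserted sequence (metadata)
    ins = prefix[1:] if prefix else suffix[:-1]
    return local_orient, m.group("chrom"), int(m.group("pos")), mate_orient, ins


def _clonality_of(rec: pysam.VariantRecord) -> Clonality:
    raw = rec.info.get("CLONALITY") if "CLONALITY" in rec.info else None
    if raw is None:
        return Clonality.UNKNOWN
    if isinstance(raw, tuple):
        raw = raw[0]
    try:
        return Clonality(str(raw).upper())
    except ValueError:
        return Clonality.UNKNOWN


def parse_sv_vcf(
    path: str,
    sample: Optional[str] = None,
    genome: Optional[GenomeSequence] = None,
) -> tuple[list[SvBreakendPair], list[RejectedRecord]]:
    """Read an SV VCF into canonical breakend pairs.

    Both BND bracket notation and symbolic <DEL>/<DUP>/<INV> alleles are
    supported; <INV> expands into its h2h and t2t junctions.  Each junction
    appears exactly once (mates deduplicated via MATEID / junction identity).
    Records that cannot be canonicalized are returned in the rejects list
    with a reason, never silently dropped.
    """
    pairs: list[SvBreakendPair] = []
    rejects: list[RejectedRecord] = []
    seen_junctions: set[tuple] = set()
    mate_ids: dict[str, str] = {}  # record id -> MATEID
    record_ids: set[str] = set()

    with pysam.VariantFile(path) as vcf:
        records = list(vcf)

    for rec in records:
        if rec.id:
            record_ids.add(rec.id)
            mid = rec.info.get("MATEID") if "MATEID" in rec.info else None
            if mid is not None:
                if isinstance(mid, tuple):
                    mid = mid[0]
                mate_ids[rec.id] = str(mid)

    for rec in records:
        rid = rec.id or f"{rec.chrom}:{rec.pos}"
        alt = rec.alts[0] if rec.alts else None
        if alt is None:
            rejects.append(RejectedRecord(rid, "no ALT"))
            continue
        sym = _SYMBOLIC_RE.match(alt)
        try:
            if sym:
                new_pairs = _canonicalize_symbolic(rec, rid, sym.group("kind"), genome)
            else:
                new_pairs = _canonicalize_bnd(rec, rid, alt, genome, mate_ids, record_ids)
        except _Reject as exc:
            rejects.append(RejectedRecord(rid, exc.reason))
            continue
        for pair in new_pairs:
            key = pair.canonical_key()
            if key in seen_junctions:
                continue
            seen_junctions.add(key)
            pair.patient = sample
            pair.clonality = _clonality_of(rec)
            pairs.append(pair)
    return pairs, rejects


class _Reject(Exception):
    def __init__(self, reason: str):
        self.reason = reason


def _canonicalize_bnd(
    rec: pysam.VariantRecord,
    rid: str,
    alt: str,
    genome: Optional[GenomeSequence],
    mate_ids: dict[str, str],
    record_ids: set[str],
) -> list[SvBreakendPair]:
    decoded = _parse_bracket_alt(alt)
    if decoded is None:
        raise _Reject("unparseable ALT")
    local_orient, mate_chrom, mate_pos, mate_orient, ins = decoded
    if rec.id in mate_ids and mate_ids[rec.id] not in record_ids:
        raise _Reject("unpaired BND")
    local = Breakend(_normalize_chrom(rec.chrom, genome), rec.pos, local_orient)
    mate = Breakend(_normalize_chrom(mate_chrom, genome), mate_pos, mate_orient)
    # stable pair id shared by both mates: the common stem of ids like
    # <pair>_1 / <pair>_2, otherwise the lexicographically smaller mate id
    pid = rid
    if rec.id and rec.id in mate_ids:
        other = mate_ids[rec.id]
        stem = re.sub(r"_[12]$", "", rec.id)
        if {rec.id, other} == {stem + "_1", stem + "_2"}:
            pid = stem
        else:
            pid = min(rec.id, other)
    return [SvBreakendPair(id=pid, first=local, second=mate, declared_type="BND",
                           insert_seq=ins or None)]


def _canonicalize_symbolic(
    rec: pysam.VariantRecord,
    rid: str,
    kind: str,
    genome: Optional[GenomeSequence],
) -> list[SvBreakendPair]:
    chrom = _normalize_chrom(rec.chrom, genome)
    pos, end = rec.pos, rec.stop
    kind = kind.upper()
    if kind.startswith("DEL"):
        return [SvBreakendPair(rid, Breakend(chrom, pos, Orient.LEFT),
                               Breakend(chrom, end, Orient.RIGHT), declared_type="DEL")]
    if kind.startswith("DUP"):
        return [SvBreakendPair(rid, Breakend(chrom, pos, Orient.RIGHT),
                               Breakend(chrom, end, Orient.LEFT), declared_type="DUP")]
    if kind == "INV":
        return [
            SvBreakendPair(f"{rid}_h2h", Breakend(chrom, pos, Orient.LEFT),
                           Breakend(chrom, end, Orient.LEFT), declared_type="INV"),
            SvBreakendPair(f"{rid}_t2t", Breakend(chrom, pos, Orient.RIGHT),
                           Breakend(chrom, end, Orient.RIGHT), declared_type="INV"),
        ]
    if kind == "TRA":
        chr2 = rec.info.get("CHR2") if "CHR2" in rec.info else None
        if chr2 is None:
            raise _Reject("TRA without CHR2")
        return [SvBreakendPair(rid, Breakend(chrom, pos, Orient.LEFT),
                               Breakend(_normalize_chrom(str(chr2), genome), end,
                                        Orient.RIGHT),
                               declared_type="TRA")]
    raise _Reject(f"unknown symbolic type <{kind}>")


# ---------------------------------------------------------------------------
# VCF / TSV writers


def write_bnd_vcf(pairs: Iterable[SvBreakendPair], path: str,
                  contigs: Optional[dict[str, int]] = None) -> None:
    """Write canonical pairs as two-mate BND records (round-trippable)."""
    pairs = list(pairs)
    if contigs is None:
        contigs = {}
        for p in pairs:
            for b in (p.first, p.second):
                contigs[b.chrom] = max(contigs.get(b.chrom, 0), b.pos + 1000)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs.items()]
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    lines.append('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">')
    lines.append('##INFO=<ID=CLONALITY,Number=1,Type=String,Description="Clonality label">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for p in pairs:
        a_id, b_id = f"{p.id}_1", f"{p.id}_2"
        for local, mate, lid, mid in ((p.first, p.second, a_id, b_id),
                                      (p.second, p.first, b_id, a_id)):
            alt = _bnd_alt("N", local.orient, mate)
            info = f"SVTYPE=BND;MATEID={mid}"
            if p.clonality is not Clonality.UNKNOWN:
                info += f";CLONALITY={p.clonality.value}"
            lines.append(f"{local.chrom}\t{local.pos}\t{lid}\tN\t{alt}\t.\t.\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _bnd_alt(ref: str, local_orient: Orient, mate: Breakend) -> str:
    bracket = "[" if mate.orient is Orient.RIGHT else "]"
    anchor = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
    if local_orient is Orient.LEFT:
        return f"{ref}{anchor}"
    return f"{anchor}{ref}"


def write_junction_table(pairs: Iterable[SvBreakendPair], path: str) -> None:
    cols = ["id", "chromA", "posA", "orientA", "chromB", "posB", "orientB",
            "declared_type", "patient", "clonality"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in pairs:
            fh.write("\t".join(map(str, [
                p.id, p.first.chrom, p.first.pos, p.first.orient.value,
                p.second.chrom, p.second.pos, p.second.orient.value,
                p.declared_type or ".", p.patient or ".", p.clonality.value,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Genome FASTA


def load_genome(path: str) -> GenomeSequence:
    """Load a FASTA into memory; duplicate sequence names are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


# ---------------------------------------------------------------------------
# Transcript annotation


@dataclass
class GeneEntry:
    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


class TranscriptDatabase:
    """Gene -> isoforms plus a genomic interval index for point queries."""

    def __init__(self, genes: dict[str, GeneEntry]):
        self.genes = genes
        self.transcripts: dict[str, TranscriptModel] = {
            t.transcript_id: t for g in genes.values() for t in g.transcripts
        }
        self._trees: dict[str, IntervalTree] = {}
        for g in genes.values():
            for t in g.transcripts:
                s, e = t.span
                self._trees.setdefault(t.chrom, IntervalTree()).addi(s, e, g.gene_id)
        self._proteome_cache: Optional[dict[str, str]] = None

    def genes_at(self, chrom: str, pos0: int) -> list[str]:
        """Gene ids whose transcript span covers a 0-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos0)})

    def select_transcript(self, gene_id: str) -> Optional[TranscriptModel]:
        """The coding isoform with the longest CDS (ties: smallest id)."""
        gene = self.genes[gene_id]
        coding = [t for t in gene.transcripts if t.is_coding]
        if not coding:
            return None
        return min(coding, key=lambda t: (-t.cds_length, t.transcript_id))

    def wild_type_protein(self, transcript: TranscriptModel,
                          genome: GenomeSequence) -> str:
        tx_seq = transcript.sequence(genome)
        cds = tx_seq[transcript.utr5_length:
                     transcript.utr5_length + transcript.cds_length]
        prot = str(Seq(cds).translate())
        return prot.rstrip("*")

    def proteome(self, genome: GenomeSequence) -> dict[str, str]:
        """Longest-CDS isoform of every gene, translated (cached)."""
        if self._proteome_cache is None:
            out: dict[str, str] = {}
            for gid in self.genes:
                t = self.select_transcript(gid)
                if t is not None:
                    out[gid] = self.wild_type_protein(t, genome)
            self._proteome_cache = out
        return self._proteome_cache


def select_transcript(txdb: "TranscriptDatabase",
                      gene_id: str) -> Optional[TranscriptModel]:
    """Longest-CDS coding isoform of a gene; None for noncoding genes."""
    return txdb.select_transcript(gene_id)


def _attr(feature, *keys: str) -> Optional[str]:
    for key in keys:
        if key in feature.attributes:
            val = feature.attributes[key]
            return val[0] if isinstance(val, list) else val
    return None


def load_annotation(path: str) -> TranscriptDatabase:
    """Build the transcript database from an Ensembl-style GTF (or GFF3).

    Coding transcripts get strand-ordered exons and CDS; noncoding isoforms
    are retained (``cds_length == 0``) but never candidate-eligible.  A
    transcript whose CDS is not contained in its exons is excluded with a
    logged reason.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cdss: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene_id, name, chrom, strand)
    for ftype, store in (("exon", exons), ("CDS", cdss)):
        for feat in db.features_of_type(ftype):
            tid = _attr(feat, "transcript_id", "Parent")
            gid = _attr(feat, "gene_id") or tid
            name = _attr(feat, "gene_name") or gid
            if tid is None:
                continue
            store.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta.setdefault(tid, (gid, name, feat.seqid, feat.strand))

    genes: dict[str, GeneEntry] = {}
    for tid, ex in exons.items():
        gid, name, chrom, strand = meta[tid]
        ex = sorted(ex)
        cd = sorted(cdss.get(tid, []))
        if not _contained(cd, ex):
            logger.warning("transcript %s: CDS not contained in exons; excluded", tid)
            continue
        if strand == "-":
            ex, cd = ex[::-1], cd[::-1]
        tm = TranscriptModel(transcript_id=tid, gene_id=gid, gene_name=name,
                             chrom=chrom, strand=strand, exons=ex, cds_intervals=cd)
        genes.setdefault(gid, GeneEntry(gid, name)).transcripts.append(tm)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return TranscriptDatabase(genes)


def _contained(cds: list[tuple[int, int]], exons: list[tuple[int, int]]) -> bool:
    return all(any(es <= cs and ce <= ee for es, ee in exons) for cs, ce in cds)
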