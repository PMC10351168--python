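"""Synthetic genomes, annotations, spiked SV call sets, and cohort tables.

The generator is the test bed for the whole pipeline: it builds a toy
genome of small multi-exon coding genes (clean ATG...stop ORFs, both
strands, exons 30-300 nt so brute-force oracles run in milliseconds),
spikes SV junctions of every class — deletion-like, duplication-like,
head-to-head and tail-to-tail inversion, translocation — in both in-frame
and frameshift variants plus designed rejects (intergenic, infeasible
orientation, start-codon loss, 3'UTR donor) and a read-through event, and
writes the same truth set in two VCF dialects (pure BND, and symbolic
<DEL>/<DUP>/<INV> where expressible) to harden the parser.

Every spike carries a :class:`TruthRecord` computed by the naive string
oracle in :mod:`._oracle` directly from the written files, independent of
the pipeline.  Gene geometry is controlled so that spike intents are always
satisfiable: internal exons are fully coding with a chosen length mod 3,
exonic breakends are slid base-by-base to hit a target codon phase, and the
read-through gene gets a T-free (hence stop-free in every frame) 3'UTR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _oracle

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_OF = {}
for _codon, _aa in _oracle.CODON.items():
    if _aa != "*":
        _CODONS_OF.setdefault(_aa, []).append(_codon)


@dataclass
class SimSpec:
    """Parameters of the synthetic study; the seed fixes all randomness."""

    seed: int = 0
    n_genes: int = 7
    exons_per_gene: tuple[int, int] = (3, 3)
    exon_len: tuple[int, int] = (30, 300)
    intron_len: tuple[int, int] = (40, 90)
    utr5_len: tuple[int, int] = (12, 30)
    utr3_len: tuple[int, int] = (30, 45)
    intergenic_gap: tuple[int, int] = (250, 400)
    # cohort layer
    n_patients: int = 100
    svs_per_patient_mean: float = 10.0
    true_beta: tuple[float, float, float, float] = (-1.0, -1.2, 0.01, 1.5)
    true_subclonal_or: float = 2.0
    subclonal_base_rate: float = 0.35
    oncogenic_rate: float = 0.2
    frameshift_rate: float = 0.6
    snv_neo_mean: float = 65.0
    indel_neo_mean: float = 7.0


@dataclass
class GeneLayout:
    """Geometry of one synthetic gene, in both transcript and genome space."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based genomic start of the gene body
    exon_lens: list[int]  # transcription order
    intron_lens: list[int]
    utr5: int
    utr3: int
    tx_seq: str
    gene_seq: str  # genomic-orientation sequence of the gene body

    @property
    def tx_len(self) -> int:
        return sum(self.exon_lens)

    @property
    def cds_len(self) -> int:
        return self.tx_len - self.utr5 - self.utr3

    @property
    def end(self) -> int:
        return self.start + len(self.gene_seq)

    def exons_genomic(self) -> list[tuple[int, int]]:
        """0-based half-open genomic exon intervals, transcription order."""
        # lay out exon/intron blocks along the gene body in transcription
        # order; for '-' genes transcription runs right-to-left
        blocks = []
        off = 0
        for i, el in enumerate(self.exon_lens):
            blocks.append((off, off + el))
            off += el
            if i < len(self.intron_lens):
                off += self.intron_lens[i]
        if self.strand == "+":
            return [(self.start + s, self.start + e) for s, e in blocks]
        glen = len(self.gene_seq)
        return [(self.start + glen - e, self.start + glen - s) for s, e in blocks]

    def tx_to_genomic(self, off: int) -> int:
        """0-based genomic position of a transcript offset."""
        for (gs, ge), el in zip(self.exons_genomic(), self.exon_lens):
            if off < el:
                return gs + off if self.strand == "+" else ge - 1 - off
            off -= el
        raise ValueError("transcript offset beyond transcript end")

    def intron_genomic_mid(self, i: int) -> int:
        """0-based midpoint of intron i (transcription order)."""
        ex = self.exons_genomic()
        a, b = ex[i], ex[i + 1]
        lo, hi = (a[1], b[0]) if self.strand == "+" else (b[1], a[0])
        return (lo + hi) // 2


@dataclass
class ToyReference:
    genome: dict[str, str]
    layouts: list[GeneLayout]
    proteome: dict[str, str]

    def layout(self, gene_id: str) -> GeneLayout:
        return next(g for g in self.layouts if g.gene_id == gene_id)

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta, gtf = outdir / "genome.fa", outdir / "annotation.gtf"
        with open(fasta, "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(gtf, "w") as fh:
            fh.write(self._gtf_text())
        return fasta, gtf

    def _gtf_text(self) -> str:
        lines = []
        for g in self.layouts:
            tid = g.gene_id + "T1"
            attrs = (f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                     f'gene_name "{g.gene_id}";')
            exons = g.exons_genomic()
            span = (min(s for s, _ in exons) + 1, max(e for _, e in exons))
            lines.append("\t".join([g.chrom, "sim", "gene", str(span[0]),
                                    str(span[1]), ".", g.strand, ".",
                                    f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";']))
            lines.append("\t".join([g.chrom, "sim", "transcript", str(span[0]),
                                    str(span[1]), ".", g.strand, ".", attrs]))
            off = 0
            for (gs, ge), el in zip(exons, g.exon_lens):
                lines.append("\t".join([g.chrom, "sim", "exon", str(gs + 1),
                                        str(ge), ".", g.strand, ".", attrs]))
                # CDS portion of this exon in transcript space
                clo = max(off, g.utr5)
                chi = min(off + el, g.utr5 + g.cds_len)
                if clo < chi:
                    if g.strand == "+":
                        cs, ce = gs + (clo - off), gs + (chi - off)
                    else:
                        cs, ce = ge - (chi - off), ge - (clo - off)
                    lines.append("\t".join([g.chrom, "sim", "CDS", str(cs + 1),
                                            str(ce), ".", g.strand, ".", attrs]))
                off += el
        return "\n".join(lines) + "\n"


def _rand_dna(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _rand_cds(rng, n_codons: int) -> str:
    """ATG + n_codons random sense codons + TAA."""
    body = "".join(rng.choice(_CODONS_OF[aa])
                   for aa in rng.choice(list(_AA20), size=n_codons))
    return "ATG" + body + "TAA"


# recipe per gene index: (chrom, strand, internal-exon length mod 3,
# stop-free 3'UTR).  Cycled when n_genes exceeds the table.
_RECIPES = [
    ("chr1", "+", 0, False),
    ("chr1", "+", 1, False),
    ("chr1", "+", 2, False),
    ("chr1", "-", 0, False),
    ("chr1", "+", 0, True),   # read-through gene: T-free 3'UTR
    ("chr2", "+", 1, False),
    ("chr2", "-", 0, False),
]


def make_toy_reference(spec: SimSpec) -> ToyReference:
    """Deterministic toy genome + annotation with controlled gene geometry."""
    rng = np.random.default_rng(spec.seed)
    layouts: list[GeneLayout] = []
    cursors: dict[str, int] = {}
    chrom_seqs: dict[str, list[str]] = {}
    for gi in range(spec.n_genes):
        chrom, strand, e2mod, stopfree = _RECIPES[gi % len(_RECIPES)]
        u = int(rng.integers(*spec.utr5_len))
        w = int(rng.integers(*spec.utr3_len))
        n_exons = int(rng.integers(spec.exons_per_gene[0],
                                   spec.exons_per_gene[1] + 1))
        e1 = u + 3 + int(rng.integers(15, 40))
        e_last = w + 3 + int(rng.integers(9, 40))
        internal = [60 + 3 * int(rng.integers(0, 40)) + e2mod]
        for _ in range(n_exons - 3):
            internal.append(60 + 3 * int(rng.integers(0, 20)))
        if stopfree:  # align exon1's coding length to a codon boundary
            e1 += (-(e1 - u)) % 3
        exon_lens = [e1, *internal, e_last]
        cds_len = sum(exon_lens) - u - w
        e_last += (-cds_len) % 3  # pad last exon so the CDS is whole codons
        exon_lens[-1] = e_last
        cds_len = sum(exon_lens) - u - w
        if cds_len < 30:
            raise ValueError("gene geometry infeasible: CDS shorter than 30 nt")
        n_codons = cds_len // 3 - 2
        utr5_seq = _rand_dna(rng, u)
        utr3_seq = _rand_dna(rng, w, alphabet="ACG") if stopfree else _rand_dna(rng, w)
        tx = utr5_seq + _rand_cds(rng, n_codons) + utr3_seq
        introns = [_rand_dna(rng, int(rng.integers(*spec.intron_len)))
                   for _ in range(len(exon_lens) - 1)]
        # assemble the gene body in transcription order, then orient
        body_parts, off = [], 0
        for i, el in enumerate(exon_lens):
            body_parts.append(tx[off:off + el])
            off += el
            if i < len(introns):
                body_parts.append(introns[i])
        body = "".join(body_parts)
        if strand == "-":
            body = _oracle.rc(body)
        gap = int(rng.integers(*spec.intergenic_gap))
        cursors.setdefault(chrom, 0)
        chrom_seqs.setdefault(chrom, [])
        chrom_seqs[chrom].append(_rand_dna(rng, gap))
        start = cursors[chrom] + gap
        chrom_seqs[chrom].append(body)
        cursors[chrom] = start + len(body)
        layouts.append(GeneLayout(
            gene_id=f"G{gi + 1}", chrom=chrom, strand=strand, start=start,
            exon_lens=exon_lens, intron_lens=[len(x) for x in introns],
            utr5=u, utr3=w, tx_seq=tx, gene_seq=body))
    for chrom in chrom_seqs:
        chrom_seqs[chrom].append(_rand_dna(rng, 300))
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    prot = {g.gene_id: _oracle.translate(
        g.tx_seq[g.utr5:g.utr5 + g.cds_len]) for g in layouts}
    return ToyReference(genome=genome, layouts=layouts, proteome=prot)


# ---------------------------------------------------------------------------
# SV spiking


@dataclass
class Spike:
    """One intended junction: breakends plus the designed outcome."""

    sv_id: str
    end1: tuple[str, int, str]  # (chrom, 1-based pos, 'L'/'R')
    end2: tuple[str, int, str]
    symbolic: Optional[tuple[str, str, int, int]] = None  # (kind, chrom, pos, end)
    symbolic_group: Optional[str] = None  # shared <INV> record id
    intent: str = ""


@dataclass
class TruthRecord:
    sv_id: str
    intent: str
    feasible: bool
    reject_reason: Optional[str]
    frameshift: Optional[bool] = None
    protein: Optional[str] = None
    mutated_span: Optional[tuple[int, int]] = None
    termination: Optional[str] = None
    peptides: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["peptides"] = sorted(self.peptides)
        return d


@dataclass
class SpikeSet:
    spikes: list[Spike]
    truth: list[TruthRecord] = field(default_factory=list)

    def write_vcfs(self, outdir: str | Path,
                   contigs: dict[str, int]) -> tuple[Path, Path]:
        """Write the same junctions as pure-BND and symbolic-where-possible
        dialects; returns (bnd_path, symbolic_path)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = ["##fileformat=VCFv4.2"]
        header += [f"##contig=<ID={c},length={n}>" for c, n in sorted(contigs.items())]
        header += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        bnd_lines, sym_lines = list(header), list(header)
        seen_groups: set[str] = set()
        for sp in self.spikes:
            bnd_lines += _bnd_records(sp)
            if sp.symbolic is not None:
                kind, chrom, pos, end = sp.symbolic
                rid = sp.symbolic_group or sp.sv_id
                if rid in seen_groups:
                    continue
                seen_groups.add(rid)
                sym_lines.append(f"{chrom}\t{pos}\t{rid}\tN\t<{kind}>\t.\t.\t"
                                 f"SVTYPE={kind};END={end}")
            else:
                sym_lines += _bnd_records(sp)
        bnd_path, sym_path = outdir / "svs_bnd.vcf", outdir / "svs_symbolic.vcf"
        bnd_path.write_text("\n".join(bnd_lines) + "\n")
        sym_path.write_text("\n".join(sym_lines) + "\n")
        return bnd_path, sym_path

    def write_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [t.to_dict() for t in self.truth], indent=1, sort_keys=True))


def _bnd_records(sp: Spike) -> list[str]:
    out = []
    for local, mate, suffix, mate_suffix in ((sp.end1, sp.end2, "_1", "_2"),
                                             (sp.end2, sp.end1, "_2", "_1")):
        chrom, pos, orient = local
        mchrom, mpos, morient = mate
        bracket = "[" if morient == "R" else "]"
        anchor = f"{bracket}{mchrom}:{mpos}{bracket}"
        alt = f"N{anchor}" if orient == "L" else f"{anchor}N"
        out.append(f"{chrom}\t{pos}\t{sp.sv_id}{suffix}\tN\t{alt}\t.\t.\t"
                   f"SVTYPE=BND;MATEID={sp.sv_id}{mate_suffix}")
    return out


def _coding_pos_with_phase(layout: GeneLayout, phase: int,
                           exon_index: int = 1) -> int:
    """1-based genomic position of a base inside a fully coding internal
    exon whose CDS offset has the requested phase."""
    base_off = sum(layout.exon_lens[:exon_index]) + 6  # a few nt into the exon
    cds_off = base_off - layout.utr5
    off = base_off + ((phase - cds_off) % 3)
    return layout.tx_to_genomic(off) + 1


def _donor_contribution_via_intron(layout: GeneLayout, intron: int) -> int:
    """Coding nt contributed by a donor splicing at intron i."""
    return sum(layout.exon_lens[:intron + 1]) - layout.utr5


def spike_svs(ref: ToyReference, spec: SimSpec) -> SpikeSet:
    """Spike junctions of every class x frame x gene-context where the toy
    geometry permits, plus designed rejects and a read-through event."""
    if len(ref.layouts) < 7:
        raise ValueError("spiking needs the 7-gene default geometry "
                         "(n_genes >= 7)")
    L = {g.gene_id: g for g in ref.layouts}
    g1, g2, g3, g4, g5, g6, g7 = (L[f"G{i}"] for i in range(1, 8))
    spikes: list[Spike] = []

    def imid(g: GeneLayout, i: int) -> int:
        return g.intron_genomic_mid(i) + 1  # 1-based

    def add(sv_id, end1, end2, intent, symbolic=None, group=None):
        spikes.append(Spike(sv_id, end1, end2, symbolic=symbolic,
                            symbolic_group=group, intent=intent))

    # single-gene deletions skipping the internal exon (len mod 3 controls frame)
    for g, tag in ((g1, "del_single_inframe"), (g2, "del_single_frameshift")):
        p1, p2 = sorted((imid(g, 0), imid(g, 1)))
        add(f"{tag}", (g.chrom, p1, "L"), (g.chrom, p2, "R"), tag,
            symbolic=("DEL", g.chrom, p1, p2))
    # single-gene tandem duplications of the internal exon
    for g, tag in ((g1, "dup_single_inframe"), (g2, "dup_single_frameshift")):
        p1, p2 = sorted((imid(g, 0), imid(g, 1)))
        add(f"{tag}", (g.chrom, p1, "R"), (g.chrom, p2, "L"), tag,
            symbolic=("DUP", g.chrom, p1, p2))
    # two-gene deletion-like fusions G1 -> G3 (phase-tuned exonic acceptor)
    d = _donor_contribution_via_intron(g1, 0)
    for shift, tag in ((0, "del_twogene_inframe"), (1, "del_twogene_frameshift")):
        pa = _coding_pos_with_phase(g3, (d + shift) % 3)
        add(tag, (g1.chrom, imid(g1, 0), "L"), (g3.chrom, pa, "R"), tag,
            symbolic=("DEL", g1.chrom, imid(g1, 0), pa))
    # translocations G2(chr1,+) -> G6(chr2,+)
    d = _donor_contribution_via_intron(g2, 0)
    for shift, tag in ((0, "tra_inframe"), (1, "tra_frameshift")):
        pa = _coding_pos_with_phase(g6, (d + shift) % 3)
        add(tag, (g2.chrom, imid(g2, 0), "L"), (g6.chrom, pa, "R"), tag)
    # inversions between G2(+) and G4(-): the h2h junction is phase-tuned
    d = _donor_contribution_via_intron(g2, 0)
    for shift, tag in ((0, "inv_h2h_inframe"), (1, "inv_h2h_frameshift")):
        pa = _coding_pos_with_phase(g4, (d + shift) % 3)
        p, e = sorted((imid(g2, 0), pa))
        add(f"{tag}_h2h", (g2.chrom, p, "L"), (g2.chrom, e, "L"),
            tag, symbolic=("INV", g2.chrom, p, e), group=tag)
        add(f"{tag}_t2t", (g2.chrom, p, "R"), (g2.chrom, e, "R"),
            tag + "_twin", symbolic=("INV", g2.chrom, p, e), group=tag)
    # inversions with the t2t junction phase-tuned: donor G4(-) intron,
    # acceptor slid inside G1's internal exon
    d = _donor_contribution_via_intron(g4, 0)
    for shift, tag in ((0, "inv_t2t_inframe"), (1, "inv_t2t_frameshift")):
        pa = _coding_pos_with_phase(g1, (d + shift) % 3)
        p, e = sorted((pa, imid(g4, 0)))
        add(f"{tag}_t2t", (g1.chrom, p, "R"), (g1.chrom, e, "R"),
            tag, symbolic=("INV", g1.chrom, p, e), group=tag)
        add(f"{tag}_h2h", (g1.chrom, p, "L"), (g1.chrom, e, "L"),
            tag + "_twin", symbolic=("INV", g1.chrom, p, e), group=tag)
    # read-through: G5 donor intron (codon-aligned), acceptor in its own
    # stop-free 3'UTR
    utr3_off = g5.utr5 + g5.cds_len + 3
    pa = g5.tx_to_genomic(utr3_off) + 1
    add("readthrough", (g5.chrom, imid(g5, 0), "L"), (g5.chrom, pa, "R"),
        "readthrough", symbolic=("DEL", g5.chrom, imid(g5, 0), pa))
    # designed rejects -----------------------------------------------------
    gap_mid = (g1.end + L["G2"].start) // 2 + 1
    gap_mid2 = (g2.end + g3.start) // 2 + 1
    add("reject_intergenic_both", (g1.chrom, gap_mid, "L"),
        (g1.chrom, gap_mid2, "R"), "reject_intergenic_both",
        symbolic=("DEL", g1.chrom, gap_mid, gap_mid2))
    add("reject_intergenic_one", (g1.chrom, imid(g1, 0), "L"),
        (g1.chrom, gap_mid2, "R"), "reject_intergenic_one",
        symbolic=("DEL", g1.chrom, imid(g1, 0), gap_mid2))
    # inversion between two '+' genes: neither junction has a valid acceptor
    p, e = imid(g1, 0), imid(g3, 0)
    add("reject_orientation_h2h", (g1.chrom, p, "L"), (g1.chrom, e, "L"),
        "reject_orientation", symbolic=("INV", g1.chrom, p, e),
        group="reject_orientation")
    add("reject_orientation_t2t", (g1.chrom, p, "R"), (g1.chrom, e, "R"),
        "reject_orientation", symbolic=("INV", g1.chrom, p, e),
        group="reject_orientation")
    # start-codon loss: donor breakend in the 5'UTR
    p5 = g2.tx_to_genomic(g2.utr5 // 2) + 1
    add("reject_startloss", (g2.chrom, p5, "L"), (g2.chrom, imid(g2, 0), "R"),
        "reject_startloss", symbolic=("DEL", g2.chrom, p5, imid(g2, 0)))
    # 3'UTR donor: protein cannot change
    p3 = g3.tx_to_genomic(g3.utr5 + g3.cds_len + 2) + 1
    add("reject_utr3_donor", (g3.chrom, p3, "L"), (g5.chrom, imid(g5, 0), "R"),
        "reject_utr3_donor", symbolic=("DEL", g3.chrom, p3, imid(g5, 0)))
    return SpikeSet(spikes=spikes)


_EXPECTED_REJECTS = {
    "reject_intergenic_both": "INTERGENIC",
    "reject_intergenic_one": "INTERGENIC",
    "reject_orientation": "ORIENTATION",
    "reject_startloss": "NO_UTR_STRUCTURE",
    "reject_utr3_donor": "NO_CODING_EFFECT",
}

_INTENT_FRAME = {
    "del_single_inframe": False, "del_single_frameshift": True,
    "dup_single_inframe": False, "dup_single_frameshift": True,
    "del_twogene_inframe": False, "del_twogene_frameshift": True,
    "tra_inframe": False, "tra_frameshift": True,
    "inv_h2h_inframe": False, "inv_h2h_frameshift": True,
    "inv_t2t_inframe": False, "inv_t2t_frameshift": True,
    "readthrough": True,
}


def compute_truth(spikeset: SpikeSet, fasta_path: str | Path,
                  gtf_path: str | Path, vcf_path: str | Path) -> list[TruthRecord]:
    """Run the naive oracle on the written files and cross-check intents."""
    genome = _oracle.load_fasta(str(fasta_path))
    gtf = _oracle.load_gtf(str(gtf_path))
    pairs = {p[0]: p for p in _oracle.load_vcf_pairs(str(vcf_path))}
    truth: list[TruthRecord] = []
    for sp in spikeset.spikes:
        res = _oracle.evaluate(pairs[sp.sv_id], gtf, genome)
        base_intent = sp.intent.removesuffix("_twin")
        if not res["feasible"]:
            expected = _EXPECTED_REJECTS.get(base_intent)
            if expected is not None and res["reject"] != expected:
                raise ValueError(f"{sp.sv_id}: designed reject {expected} "
                                 f"but oracle says {res['reject']}")
            truth.append(TruthRecord(sp.sv_id, sp.intent, False, res["reject"]))
            continue
        if base_intent in _EXPECTED_REJECTS:
            raise ValueError(f"{sp.sv_id}: designed reject but oracle "
                             f"found it feasible")
        want = _INTENT_FRAME.get(base_intent)
        if want is not None and not sp.intent.endswith("_twin") \
                and res["frameshift"] != want:
            raise ValueError(f"{sp.sv_id}: intended frameshift={want} but "
                             f"oracle computed {res['frameshift']}")
        if base_intent == "readthrough" and res["termination"] != "READ_THROUGH":
            raise ValueError(f"{sp.sv_id}: intended read-through but oracle "
                             f"computed {res['termination']}")
        truth.append(TruthRecord(
            sp.sv_id, sp.intent, True, None, frameshift=res["frameshift"],
            protein=res["protein"], mutated_span=tuple(res["span"]),
            termination=res["termination"],
            peptides=frozenset(res["peptides"])))
    spikeset.truth = truth
    return truth


@dataclass
class FixtureBundle:
    fasta: Path
    gtf: Path
    vcf_bnd: Path
    vcf_symbolic: Path
    truth_json: Path
    reference: ToyReference
    spikes: SpikeSet


def generate_fixture(spec: SimSpec, outdir: str | Path) -> FixtureBundle:
    """Reference + spiked VCFs (both dialects) + truth table, in one call."""
    ref = make_toy_reference(spec)
    fasta, gtf = ref.write(outdir)
    spikes = spike_svs(ref, spec)
    contigs = {c: len(s) for c, s in ref.genome.items()}
    vcf_bnd, vcf_sym = spikes.write_vcfs(outdir, contigs)
    compute_truth(spikes, fasta, gtf, vcf_bnd)
    truth_json = Path(outdir) / "truth.json"
    spikes.write_truth(truth_json)
    return FixtureBundle(fasta, gtf, vcf_bnd, vcf_sym, truth_json, ref, spikes)


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort tables with known generative parameters.

    Per-SV rows are drawn from the depletion logistic model at the spec's
    true beta; clonality labels are drawn conditional on the neoantigenic
    outcome so that the odds ratio linking subclonality and neoantigen
    generation equals ``true_subclonal_or``.  Returns (sv_table,
    patient_counts).
    """
    rng = np.random.default_rng(spec.seed + 1)
    b0, b1, b2, b3 = spec.true_beta
    # clonality | outcome keeps the subclonal/clonal odds ratio at target
    p0 = spec.subclonal_base_rate
    odds1 = spec.true_subclonal_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    rows = []
    counts = []
    for pi in range(spec.n_patients):
        patient = f"P{pi + 1:04d}"
        n_sv = max(2, rng.poisson(spec.svs_per_patient_mean))
        x1 = rng.random(n_sv) < spec.oncogenic_rate
        x2 = rng.gamma(shape=2.0, scale=15.0, size=n_sv).round().clip(1)
        x3 = rng.random(n_sv) < spec.frameshift_rate
        logit = b0 + b1 * x1 + b2 * x2 + b3 * x3
        y = rng.random(n_sv) < 1.0 / (1.0 + np.exp(-logit))
        subclonal = np.where(y, rng.random(n_sv) < p1, rng.random(n_sv) < p0)
        for j in range(n_sv):
            rows.append({
                "patient": patient, "sv_id": f"{patient}_sv{j + 1}",
                "clonality": "SUBCLONAL" if subclonal[j] else "CLONAL",
                "X1": int(x1[j]), "X2": float(x2[j]), "X3": int(x3[j]),
                "neoantigenic": int(y[j]),
            })
        counts.append({
            "patient": patient,
            "snv_neo": int(rng.poisson(spec.snv_neo_mean)),
            "indel_neo": int(rng.poisson(spec.indel_neo_mean)),
            "sv_neo": int(y.sum()),
            "snv_mut": int(rng.poisson(spec.snv_neo_mean * 2.5)),
            "indel_mut": int(rng.poisson(spec.indel_neo_mean * 1.8)),
            "sv_mut": int(n_sv),
        })
    return pd.DataFrame(rows), pd.DataFrame(counts)
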