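"""Core data model for SV-derived neoantigen prediction.

Coordinate conventions
----------------------
External formats (VCF, GTF) are 1-based inclusive.  Every internal interval
is 0-based half-open; conversion happens only at the I/O boundary.  A
:class:`Breakend` keeps the VCF-facing 1-based position of the last retained
base; ``pos0`` exposes the 0-based index of that same base.

Orientation uses side-retained semantics: ``LEFT`` means reference bases at
coordinates <= pos survive and are joined at the junction, ``RIGHT`` means
bases >= pos survive.  This is unambiguous from either mate's perspective,
unlike strand symbols.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Orient(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Clonality(str, enum.Enum):
    CLONAL = "CLONAL"
    SUBCLONAL = "SUBCLONAL"
    UNKNOWN = "UNKNOWN"


class SvClass(str, enum.Enum):
    DELETION_LIKE = "DELETION_LIKE"
    DUPLICATION_LIKE = "DUPLICATION_LIKE"
    H2H_INVERSION = "H2H_INVERSION"
    T2T_INVERSION = "T2T_INVERSION"
    TRANSLOCATION = "TRANSLOCATION"


class RegionKind(str, enum.Enum):
    EXON = "EXON"
    INTRON = "INTRON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTERGENIC = "INTERGENIC"


class Termination(str, enum.Enum):
    STOP = "STOP"
    READ_THROUGH = "READ_THROUGH"


class RejectReason(str, enum.Enum):
    INTERGENIC = "INTERGENIC"
    ORIENTATION = "ORIENTATION"
    NO_CODING_EFFECT = "NO_CODING_EFFECT"
    NO_UTR_STRUCTURE = "NO_UTR_STRUCTURE"
    NO_START = "NO_START"


@dataclass(frozen=True)
class Breakend:
    """One side of an SV junction."""

    chrom: str
    pos: int  # 1-based coordinate of the last retained base
    orient: Orient

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based index of the retained base."""
        return self.pos - 1

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.orient.value)


@dataclass
class SvBreakendPair:
    """A somatic junction: two breakends plus identifiers."""

    id: str
    first: Breakend
    second: Breakend
    declared_type: Optional[str] = None
    clonality: Clonality = Clonality.UNKNOWN
    patient: Optional[str] = None
    insert_seq: Optional[str] = None  # micro-homology / inserted bases, metadata only

    def canonical_key(self) -> tuple:
        """Order-insensitive identity of the junction."""
        return tuple(sorted([self.first.key(), self.second.key()]))

    def ordered(self) -> tuple[Breakend, Breakend]:
        """Breakends sorted by (chrom, pos) for classification."""
        a, b = self.first, self.second
        if (a.chrom, a.pos) <= (b.chrom, b.pos):
            return a, b
        return b, a


@dataclass
class TranscriptModel:
    """One isoform with strand-aware exon/CDS structure.

    ``exons`` and ``cds_intervals`` are lists of 0-based half-open genomic
    intervals ordered in *transcription* order (descending genomic start for
    minus-strand transcripts).
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    # -- derived geometry ------------------------------------------------

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def is_coding(self) -> bool:
        return self.cds_length > 0

    @property
    def utr5_length(self) -> int:
        """Transcript nt upstream of the CDS (transcription order)."""
        if not self.is_coding:
            return 0
        cds_first = self.cds_intervals[0]
        # transcript offset of the first CDS base
        if self.strand == "+":
            return self.genomic_to_tx(cds_first[0])
        return self.genomic_to_tx(cds_first[1] - 1)

    @property
    def utr3_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.exonic_length - self.utr5_length - self.cds_length

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval covered by the transcript (0-based half-open)."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_tx(self, gpos0: int) -> Optional[int]:
        """Transcript offset of an exonic genomic base; None if intronic."""
        off = 0
        for s, e in self.exons:
            if s <= gpos0 < e:
                if self.strand == "+":
                    return off + (gpos0 - s)
                return off + (e - 1 - gpos0)
            off += e - s
        return None

    def containing_exon(self, gpos0: int) -> Optional[int]:
        """0-based exon index (transcription order) containing the base."""
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos0 < e:
                return i
        return None

    def containing_intron(self, gpos0: int) -> Optional[int]:
        """0-based intron index (transcription order) containing the base."""
        for i in range(len(self.exons) - 1):
            a, b = self.exons[i], self.exons[i + 1]
            if self.strand == "+":
                lo, hi = a[1], b[0]
            else:
                lo, hi = b[1], a[0]
            if lo <= gpos0 < hi:
                return i
        return None

    def cumulative_exon_length(self, n_exons: int) -> int:
        return sum(e - s for s, e in self.exons[:n_exons])

    def sequence(self, genome: "GenomeSequence") -> str:
        """Spliced transcript sequence, 5'->3'."""
        parts = []
        for s, e in self.exons:
            seg = genome.fetch(self.chrom, s, e)
            if self.strand == "-":
                seg = genome.revcomp(seg)
            parts.append(seg)
        return "".join(parts)


@dataclass
class AnnotatedBreakend:
    breakend: Breakend
    transcript: Optional[TranscriptModel]
    region: RegionKind
    region_index: Optional[int] = None  # 1-based exon/intron index
    cds_offset: Optional[int] = None  # coding nt strictly 5' of the breakend


@dataclass
class SvAnnotation:
    pair: SvBreakendPair
    ends: tuple[AnnotatedBreakend, AnnotatedBreakend]
    sv_class: SvClass
    span: Optional[int] = None  # junction size in bp, intrachromosomal only
    gene_context: Optional[str] = None  # SINGLE_GENE | TWO_GENE
    feasible: bool = False
    reject_reason: Optional[RejectReason] = None
    donor_index: Optional[int] = None  # which of ends is the 5' donor (0/1)

    @property
    def donor(self) -> Optional[AnnotatedBreakend]:
        return None if self.donor_index is None else self.ends[self.donor_index]

    @property
    def acceptor(self) -> Optional[AnnotatedBreakend]:
        return None if self.donor_index is None else self.ends[1 - self.donor_index]


@dataclass
class NeoTranscript:
    """Chimeric mRNA assembled across a junction, 5'->3'."""

    sv_id: str
    donor_transcript: TranscriptModel
    acceptor_transcript: TranscriptModel
    mrna: str
    junction_nt: int  # offset of the first acceptor-derived base
    cds_start_nt: int  # offset of the start codon in mrna
    donor_cds_contribution: int  # donor coding nt retained
    start_rescued: bool = False
    # native codon phase of the first acceptor-derived coding base in its own
    # wild-type transcript; None when the acceptor tail has no coding context
    acceptor_native_phase: Optional[int] = None
    # acceptor-derived nt preceding the acceptor CDS in the chimera (junction
    # landed in the acceptor 5'UTR), 0 when the junction is inside the CDS
    acceptor_utr_gap: int = 0
    single_gene: bool = False


@dataclass
class NeoProtein:
    sv_id: str
    sequence: str
    junction_aa: int
    frameshift: bool
    termination: Termination
    start_rescued: bool
    mutated_span: tuple[int, int]  # half-open residue interval vs donor wild type
    donor_gene: str = ""
    acceptor_gene: str = ""
    gene_context: str = ""
    sv_class: Optional[SvClass] = None
    patient: Optional[str] = None


@dataclass
class NeoPeptide:
    sequence: str
    sv_id: str
    patient: Optional[str]
    donor_gene: str
    acceptor_gene: str
    protein_offset: int
    mutated_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.mutated_positions:
            raise ValueError("neo-peptide must cover at least one mutated residue")


@dataclass(frozen=True)
class BindingCall:
    peptide: str
    allele: str
    ic50: float
    rank: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.rank < 0:
            raise ValueError("rank must be non-negative")


@dataclass
class NeoantigenRecord:
    peptide: NeoPeptide
    calls: list[BindingCall]
    best_allele: str

    @property
    def best_ic50(self) -> float:
        return min(c.ic50 for c in self.calls)


@dataclass
class GenomeSequence:
    """In-memory genome with bounds-checked half-open accessors."""

    sequences: dict[str, str]

    _COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} has non-ACGTN characters: {sorted(bad)}")

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        if name not in self.sequences:
            raise KeyError(f"unknown contig {name!r}")
        seq = self.sequences[name]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for contig {name!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    @classmethod
    def revcomp(cls, seq: str) -> str:
        return seq.translate(cls._COMP)[::-1]


@dataclass
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = outcome."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class LogisticFit:
    params: dict[str, float]
    bse: dict[str, float]
    converged: bool
    iterations: int
    wald_p: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()


@dataclass
class BurdenRecord:
    patient: str
    tnb: int
    svnb: int
    ganb: int
    tnb_high: bool
    ganb_high: bool
    rescued: bool
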