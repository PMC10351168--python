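"""Peptide windowing, self-filtering, and binding-threshold neoantigen calls.

Neo-proteins are fragmented into 8-11-mer sliding windows; only windows
touching at least one mutated residue survive, and any window occurring as
an exact substring of a wild-type protein is discarded as self.  Surviving
peptides are scored against the patient's MHC-I alleles and called
neoantigens when at least one allele passes IC50 < 500 nM AND percentile
rank < 2.0 (both strict).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .backends import BindingBackend
from .model import BindingCall, NeoantigenRecord, NeoPeptide, NeoProtein

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = set("VILFMWC")

DEFAULT_IC50_NM = 500.0
DEFAULT_RANK = 2.0
K_MIN, K_MAX = 8, 11


def window_peptides(np_: NeoProtein, k_min: int = K_MIN,
                    k_max: int = K_MAX) -> list[NeoPeptide]:
    """All k-mers (k_min..k_max) overlapping the mutated span by >= 1 residue.

    Windows containing X (or any non-standard residue) are dropped because
    downstream binding predictors reject them.
    """
    seq = np_.sequence
    lo, hi = np_.mutated_span
    peptides: list[NeoPeptide] = []
    if hi <= lo:
        return peptides
    for k in range(k_min, k_max + 1):
        for i in range(len(seq) - k + 1):
            mut = tuple(j - i for j in range(max(i, lo), min(i + k, hi)))
            if not mut:
                continue
            window = seq[i:i + k]
            if set(window) - STANDARD_AA:
                continue
            peptides.append(NeoPeptide(
                sequence=window, sv_id=np_.sv_id, patient=np_.patient,
                donor_gene=np_.donor_gene, acceptor_gene=np_.acceptor_gene,
                protein_offset=i, mutated_positions=mut))
    return peptides


def filter_self(peptides: Sequence[NeoPeptide],
                proteome: Iterable[str]) -> list[NeoPeptide]:
    """Drop peptides occurring verbatim in any wild-type protein, then
    collapse duplicates (same sequence, same patient) merging provenance."""
    haystack = "|".join(proteome)  # '|' is outside the residue alphabet
    kept: dict[tuple, NeoPeptide] = {}
    for pep in peptides:
        if pep.sequence in haystack:
            continue
        key = (pep.sequence, pep.patient)
        if key in kept:
            prev = kept[key]
            ids = sorted(set(prev.sv_id.split(",")) | set(pep.sv_id.split(",")))
            prev.sv_id = ",".join(ids)
        else:
            kept[key] = pep
    return list(kept.values())


def predict_binding(peptides: Sequence[NeoPeptide], alleles: Sequence[str],
                    backend: BindingBackend) -> list[BindingCall]:
    """One call per peptide x allele through the configured backend."""
    if not peptides or not alleles:
        return []
    return backend.predict([p.sequence for p in peptides], alleles)


def passes_thresholds(call: BindingCall, ic50_threshold: float = DEFAULT_IC50_NM,
                      rank_threshold: float = DEFAULT_RANK) -> bool:
    return call.ic50 < ic50_threshold and call.rank < rank_threshold


def call_neoantigens(peptides: Sequence[NeoPeptide],
                     calls: Sequence[BindingCall],
                     ic50_threshold: float = DEFAULT_IC50_NM,
                     rank_threshold: float = DEFAULT_RANK) -> list[NeoantigenRecord]:
    """A peptide becomes a neoantigen iff >= 1 call passes both thresholds
    strictly; all passing alleles are attached, best = minimum IC50."""
    by_seq: dict[str, list[BindingCall]] = {}
    for call in calls:
        if passes_thresholds(call, ic50_threshold, rank_threshold):
            by_seq.setdefault(call.peptide, []).append(call)
    records: list[NeoantigenRecord] = []
    for pep in peptides:
        passing = by_seq.get(pep.sequence, [])
        if not passing:
            continue
        best = min(passing, key=lambda c: (c.ic50, c.allele))
        records.append(NeoantigenRecord(peptide=pep, calls=list(passing),
                                        best_allele=best.allele))
    return records


def hydrophobic_fraction(peptide: str) -> float:
    """Fraction of residues in {V, I, L, F, M, W, C}."""
    if not peptide:
        raise ValueError("empty peptide")
    return sum(1 for aa in peptide if aa in HYDROPHOBIC) / len(peptide)


def binding_stability(peptides: Sequence[str], alleles: Sequence[str], backend):
    """Pass-through to a stability backend (external binary or mock)."""
    if not peptides or not alleles:
        return []
    return backend.predict(peptides, alleles)


def read_allele_list(path: str) -> list[str]:
    """One allele per line (e.g. HLA-A*02:01); blank lines/comments skipped."""
    alleles: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                alleles.append(line)
    return alleles


def write_neoantigen_table(records: Sequence[NeoantigenRecord], path: str,
                           extra: Optional[dict[str, dict]] = None) -> None:
    """Flat TSV, one row per (peptide, passing allele)."""
    cols = ["patient", "sv_id", "peptide", "length", "mutated_positions",
            "allele", "ic50", "rank", "donor_gene", "acceptor_gene",
            "sv_class", "frameshift", "termination", "gene_context"]
    extra = extra or {}
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            pep = rec.peptide
            meta = extra.get(pep.sv_id.split(",")[0], {})
            for call in sorted(rec.calls, key=lambda c: (c.ic50, c.allele)):
                fh.write("\t".join(map(str, [
                    pep.patient or ".", pep.sv_id, pep.sequence, len(pep.sequence),
                    ",".join(map(str, pep.mutated_positions)), call.allele,
                    f"{call.ic50:.2f}", f"{call.rank:.4f}",
                    pep.donor_gene, pep.acceptor_gene,
                    meta.get("sv_class", "."), meta.get("frameshift", "."),
                    meta.get("termination", "."), meta.get("gene_context", "."),
                ])) + "\n")


def write_peptide_fasta(peptides: Sequence[NeoPeptide], path: str) -> None:
    with open(path, "w") as fh:
        for i, pep in enumerate(peptides):
            fh.write(f">{pep.sv_id}|{i}|{pep.protein_offset}\n{pep.sequence}\n")
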