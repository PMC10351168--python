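"""Helpers shared by the unit and acceptance suites: truth comparison and
randomized-junction sampling against the naive string oracle."""

from __future__ import annotations

import numpy as np

from svneoantigen import _oracle
from svneoantigen.annotate import annotate_pair
from svneoantigen.model import Breakend, Orient, SvBreakendPair
from svneoantigen.neoorf import (
    NeoOrfRejection,
    assemble_neo_transcript,
    mutated_interval,
    translate_neo,
)


def truth_matches(result, truth) -> tuple[bool, str]:
    """Does a pipeline RunResult reproduce one TruthRecord exactly?"""
    status = result.sv_status.get(truth.sv_id, "MISSING")
    if not truth.feasible:
        ok = status == truth.reject_reason
        return ok, f"expected reject {truth.reject_reason}, got {status}"
    prot = next((p for p in result.proteins if p.sv_id == truth.sv_id), None)
    if status != "OK" or prot is None:
        return False, f"expected OK, got {status}"
    checks = [
        (prot.sequence == truth.protein, "protein sequence"),
        (prot.frameshift == truth.frameshift, "frameshift flag"),
        (tuple(prot.mutated_span) == tuple(truth.mutated_span), "mutated span"),
        (prot.termination.value == truth.termination, "termination"),
        (result.sv_peptides.get(truth.sv_id, set()) == set(truth.peptides),
         "peptide set"),
    ]
    for ok, what in checks:
        if not ok:
            return False, f"{what} mismatch"
    return True, ""


def random_junctions(ref, seed: int, n: int):
    """Random breakend pairs inside gene bodies of a toy reference."""
    rng = np.random.default_rng(seed)
    layouts = ref.layouts
    pairs = []
    for i in range(n):
        g1, g2 = rng.choice(layouts, size=2, replace=True)
        p1 = int(rng.integers(g1.start + 1, g1.end + 1))
        p2 = int(rng.integers(g2.start + 1, g2.end + 1))
        o1 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        o2 = Orient.LEFT if rng.random() < 0.5 else Orient.RIGHT
        if (g1.chrom, p1, o1) == (g2.chrom, p2, o2):
            continue
        pairs.append(SvBreakendPair(
            id=f"rand{i}", first=Breakend(g1.chrom, p1, o1),
            second=Breakend(g2.chrom, p2, o2)))
    return pairs


def run_one_junction(pair, txdb, genome):
    """Pipeline outcome for one pair: (status, protein|None)."""
    ann = annotate_pair(pair, txdb)
    if not ann.feasible:
        return ann.reject_reason.value, None
    try:
        nt = assemble_neo_transcript(ann, txdb, genome)
        np_ = translate_neo(nt)
    except NeoOrfRejection as exc:
        return exc.reason.value, None
    wt = txdb.wild_type_protein(nt.donor_transcript, genome)
    mutated_interval(np_, wt)
    return "OK", np_


def oracle_outcome(pair, gtf, genome_dict):
    """Naive-oracle outcome for the same pair, via its own data model."""
    t = (pair.id,
         (pair.first.chrom, pair.first.pos, pair.first.orient.value[0]),
         (pair.second.chrom, pair.second.pos, pair.second.orient.value[0]))
    return _oracle.evaluate(t, gtf, genome_dict)
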