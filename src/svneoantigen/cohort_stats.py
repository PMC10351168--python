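"""Cohort-level immunogenomic statistics.

Covers the per-patient and cross-patient summaries used to characterize
SV-derived neoantigens: per-mutation neoantigenic rate, shared-neoantigen
recurrence across patients, k-mer x MHC-allele interaction maps for shared
neo-peptides, BLOSUM62 self-dissimilarity against the wild-type peptidome,
intratumor heterogeneity (fraction of subclonal neoantigens), immunoediting
odds ratios with the Haldane-Anscombe correction, a covariate-adjusted
logistic model of neoantigen depletion in oncogenic SVs, and the neoantigen
burden metrics TNB / SVNB / GANB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .backends import BindingBackend
from .epitope import DEFAULT_IC50_NM, DEFAULT_RANK, K_MAX, K_MIN, passes_thresholds
from .model import BurdenRecord, Clonality, Contingency2x2, LogisticFit

TNB_HIGH_THRESHOLD = 323  # neoantigens per exome, mapped from TMB-High > 175
SELF_SIMILARITY_SCORE = 35.0  # raw alignment score; counterpart above => HIGH


# ---------------------------------------------------------------------------
# Rates, recurrence, ITH


def neoantigenic_rate(n_neoantigens: float, n_mutations: float) -> Optional[float]:
    """Neoantigens generated per mutation; None when there are no mutations."""
    if n_neoantigens < 0 or n_mutations < 0:
        raise ValueError("counts must be non-negative")
    if n_mutations == 0:
        return None
    return n_neoantigens / n_mutations


def shared_occurrence(records: pd.DataFrame,
                      peptide_col: str = "peptide",
                      patient_col: str = "patient",
                      recurrent_min_patients: int = 3) -> pd.DataFrame:
    """Distinct-patient count per peptide; recurrent means > 2 patients."""
    if records.empty:
        return pd.DataFrame(columns=[peptide_col, "n_patients", "recurrent"])
    counts = (records.groupby(peptide_col)[patient_col].nunique()
              .rename("n_patients").reset_index())
    counts["recurrent"] = counts["n_patients"] >= recurrent_min_patients
    return (counts.sort_values(["n_patients", peptide_col],
                               ascending=[False, True])
            .reset_index(drop=True))


def ith_fraction(clonality: Iterable[Clonality | str]) -> Optional[float]:
    """Fraction of labelled neoantigens that are subclonal; UNKNOWN excluded."""
    labels = [Clonality(c) if not isinstance(c, Clonality) else c
              for c in clonality]
    labelled = [c for c in labels if c is not Clonality.UNKNOWN]
    if not labelled:
        return None
    return sum(c is Clonality.SUBCLONAL for c in labelled) / len(labelled)


# ---------------------------------------------------------------------------
# k-mer x allele interactions (shared neo-peptide heatmaps)


def kmer_allele_interactions(neo_peptide: str, alleles: Sequence[str],
                             backend: BindingBackend,
                             ic50_threshold: float = DEFAULT_IC50_NM,
                             rank_threshold: float = DEFAULT_RANK,
                             k_min: int = K_MIN, k_max: int = K_MAX) -> pd.DataFrame:
    """Score every k-mer (8-11) of a shared neo-peptide against an allele set.

    An interaction is one (k-mer, allele) call passing the neoantigen
    thresholds.  Counts are reported per k-mer together with log10(n + 1)
    for heatmap export.
    """
    if len(neo_peptide) < k_min:
        raise ValueError(f"neo-peptide shorter than k_min={k_min}")
    kmers = [(k, i, neo_peptide[i:i + k])
             for k in range(k_min, k_max + 1)
             for i in range(len(neo_peptide) - k + 1)]
    rows = []
    for k, start, kmer in kmers:
        calls = backend.predict([kmer], list(alleles))
        n = sum(passes_thresholds(c, ic50_threshold, rank_threshold)
                for c in calls)
        rows.append({"kmer": kmer, "k": k, "start": start,
                     "n_interactions": n,
                     "log10_interactions": math.log10(n + 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Self-dissimilarity


class SelfSimilarityScorer:
    """Best local-alignment score of a peptide against the normal peptidome.

    Smith-Waterman under BLOSUM62 with blast-style affine gaps (a gap of
    length k costs gap_open + k * gap_extend).  ``mode='protein'`` scans the
    full wild-type proteins; ``mode='kmer'`` scans the explicit 8-11-mer
    universe.  For a short query the two give identical maxima, since a
    local alignment never rewards target context outside the aligned window.
    """

    def __init__(self, peptidome: Iterable[str], mode: str = "protein",
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 threshold: float = SELF_SIMILARITY_SCORE,
                 k_min: int = K_MIN, k_max: int = K_MAX):
        if mode not in ("protein", "kmer"):
            raise ValueError(f"unknown peptidome mode {mode!r}")
        members = [p for p in peptidome if p]
        if mode == "kmer":
            kmers: set[str] = set()
            for prot in members:
                for k in range(k_min, k_max + 1):
                    for i in range(len(prot) - k + 1):
                        kmers.add(prot[i:i + k])
            members = sorted(kmers)
        self.members = members
        self.threshold = threshold
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # PairwiseAligner charges open_gap_score at the first gap position,
        # so blast's open 11 / extend 1 maps to -(11 + 1) / -1
        self.aligner.open_gap_score = -(gap_open + gap_extend)
        self.aligner.extend_gap_score = -gap_extend

    def best_score(self, peptide: str) -> Optional[float]:
        if not self.members:
            return None
        return max(self.aligner.score(target, peptide) for target in self.members)

    def classify(self, peptide: str) -> tuple[Optional[float], str]:
        score = self.best_score(peptide)
        if score is None:
            return None, "LOW"
        return score, "HIGH" if score > self.threshold else "LOW"


def self_dissimilarity(peptide: str, peptidome: Iterable[str],
                       mode: str = "protein",
                       threshold: float = SELF_SIMILARITY_SCORE) -> tuple[Optional[float], str]:
    """Best BLOSUM62 local-alignment score and HIGH/LOW similarity class."""
    scorer = SelfSimilarityScorer(peptidome, mode=mode, threshold=threshold)
    return scorer.classify(peptide)


# ---------------------------------------------------------------------------
# Odds ratios


@dataclass
class OddsRatioResult:
    odds_ratio: float
    corrected: bool  # Haldane-Anscombe 0.5 applied
    degenerate: bool  # a row or column summed to zero before correction

    @property
    def log_odds_ratio(self) -> float:
        return math.log(self.odds_ratio)


def odds_ratio_haldane(table: Contingency2x2) -> OddsRatioResult:
    """(a*d)/(b*c) with 0.5 added to ALL cells when any cell is zero."""
    a, b, c, d = table.cells()
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return OddsRatioResult((a * d) / (b * c), corrected, degenerate)


def odds_ratio_from_proportions(p_group: float, p_reference: float) -> float:
    """Odds ratio implied by two outcome proportions.

    Example: neoantigenic proportions of oncogenic (0.291) vs passenger
    (0.569) SVs give (0.291/0.709) / (0.569/0.431) ~= 0.31.
    """
    if not (0 < p_group < 1 and 0 < p_reference < 1):
        raise ValueError("proportions must be strictly between 0 and 1")
    return (p_group / (1 - p_group)) / (p_reference / (1 - p_reference))


def clonal_subclonal_or(sv_table: pd.DataFrame,
                        patient_col: str = "patient",
                        clonality_col: str = "clonality",
                        outcome_col: str = "neoantigenic") -> tuple[pd.DataFrame, dict]:
    """Per-patient odds ratio of generating a neoantigen from subclonal vs
    clonal SVs (rows subclonal/clonal, columns neoantigenic/not), plus a
    cohort-level signed-rank test of the median log-OR against 0.

    Patients lacking both clonality classes are skipped with a reason.
    """
    rows, skipped = [], []
    for patient, grp in sv_table.groupby(patient_col):
        lab = grp[clonality_col].astype(str).str.upper()
        y = grp[outcome_col].astype(bool)
        sub, clo = lab == "SUBCLONAL", lab == "CLONAL"
        if sub.sum() == 0 or clo.sum() == 0:
            skipped.append({patient_col: patient,
                            "reason": "missing clonal or subclonal SVs"})
            continue
        table = Contingency2x2(
            a=int((sub & y).sum()), b=int((sub & ~y).sum()),
            c=int((clo & y).sum()), d=int((clo & ~y).sum()))
        res = odds_ratio_haldane(table)
        rows.append({patient_col: patient, "odds_ratio": res.odds_ratio,
                     "log_odds_ratio": res.log_odds_ratio,
                     "corrected": res.corrected,
                     "a": table.a, "b": table.b, "c": table.c, "d": table.d})
    per_patient = pd.DataFrame(rows)
    summary: dict = {"n_patients": len(rows), "n_skipped": len(skipped),
                     "skipped": skipped}
    if rows:
        log_ors = per_patient["log_odds_ratio"].to_numpy()
        summary["median_odds_ratio"] = float(np.exp(np.median(log_ors)))
        nonzero = log_ors[log_ors != 0]
        if len(nonzero) > 0:
            # exact signed-rank distribution below n=25, normal approx above
            method = "exact" if len(nonzero) < 25 else "approx"
            stat, p = stats.wilcoxon(nonzero, method=method)
            summary["wilcoxon_statistic"] = float(stat)
            summary["wilcoxon_p"] = float(p)
    return per_patient, summary


# ---------------------------------------------------------------------------
# Depletion logistic model


def depletion_logistic(design: pd.DataFrame, outcome_col: str = "y",
                       covariates: Sequence[str] = ("X1", "X2", "X3"),
                       maxiter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """logit P(neoantigen) = b0 + b1*X1 + b2*X2 + b3*X3.

    X1: oncogenic indicator, X2: number of affected amino acids,
    X3: frameshift indicator.  Non-varying covariates are dropped (their
    coefficient reported as 0); perfect separation or non-convergence sets
    the convergence flag false.
    """
    if len(design) < 10:
        raise ValueError("need at least 10 rows to fit the depletion model")
    y = design[outcome_col].astype(float).to_numpy()
    use = [c for c in covariates if design[c].nunique() > 1]
    dropped = tuple(c for c in covariates if c not in use)
    X = sm.add_constant(design[use].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
        converged = bool(res.mle_retvals.get("converged", False))
        iterations = int(res.mle_retvals.get("iterations", maxiter))
        params = dict(res.params)
        bse = dict(res.bse)
        pvals = dict(res.pvalues)
    except Exception:  # perfect separation or singular information
        converged = False
        iterations = maxiter
        params = {c: math.nan for c in ["const", *use]}
        bse = {c: math.nan for c in ["const", *use]}
        pvals = {}
    for c in dropped:
        params[c] = 0.0
        bse[c] = math.nan
    name_map = {"const": "beta0", "X1": "beta1", "X2": "beta2", "X3": "beta3"}
    remap = lambda d: {name_map.get(k, k): float(v) for k, v in d.items()}
    return LogisticFit(params=remap(params), bse=remap(bse),
                       converged=converged, iterations=iterations,
                       wald_p=remap(pvals), dropped=dropped)


# ---------------------------------------------------------------------------
# Burdens


def burdens(patient: str, snv_neo: int, indel_neo: int, sv_neo: int,
            threshold: int = TNB_HIGH_THRESHOLD) -> BurdenRecord:
    """TNB (SNV+indel), SVNB (SV), GANB (all three) and High/rescued flags.

    'Rescued' patients are TNB-low but GANB-high: enough neoantigens for
    checkpoint-inhibitor eligibility only once SV-derived ones are counted.
    """
    if min(snv_neo, indel_neo, sv_neo) < 0:
        raise ValueError("counts must be non-negative")
    tnb = snv_neo + indel_neo
    svnb = sv_neo
    ganb = tnb + svnb
    tnb_high = tnb > threshold
    ganb_high = ganb > threshold
    return BurdenRecord(patient=patient, tnb=tnb, svnb=svnb, ganb=ganb,
                        tnb_high=tnb_high, ganb_high=ganb_high,
                        rescued=(not tnb_high) and ganb_high)


# ---------------------------------------------------------------------------
# Cohort tables I/O


@dataclass
class CohortTables:
    """Per-SV and per-patient tables feeding the statistics layer.

    sv_table columns: patient, sv_id, clonality, X1, X2, X3, neoantigenic.
    patient_counts columns: patient, snv_neo, indel_neo, sv_neo,
    snv_mut, indel_mut, sv_mut.
    """

    sv_table: pd.DataFrame
    patient_counts: pd.DataFrame

    @classmethod
    def read_tsv(cls, sv_path: str, counts_path: str) -> "CohortTables":
        return cls(pd.read_csv(sv_path, sep="\t"),
                   pd.read_csv(counts_path, sep="\t"))

    def write_tsv(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sv_table.to_csv(out / "sv_table.tsv", sep="\t", index=False)
        self.patient_counts.to_csv(out / "patient_counts.tsv", sep="\t", index=False)

    def burden_records(self, threshold: int = TNB_HIGH_THRESHOLD) -> list[BurdenRecord]:
        return [burdens(r.patient, int(r.snv_neo), int(r.indel_neo),
                        int(r.sv_neo), threshold)
                for r in self.patient_counts.itertuples()]
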