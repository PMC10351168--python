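"""Cohort statistics: rates, recurrence, self-similarity, odds ratios,
depletion logistic model, burdens."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from svneoantigen.backends import MockBindingBackend
from svneoantigen.cohort_stats import (
    CohortTables,
    SelfSimilarityScorer,
    burdens,
    clonal_subclonal_or,
    depletion_logistic,
    ith_fraction,
    kmer_allele_interactions,
    neoantigenic_rate,
    odds_ratio_from_proportions,
    odds_ratio_haldane,
    self_dissimilarity,
    shared_occurrence,
)
from svneoantigen.model import Clonality, Contingency2x2
from svneoantigen.simdata import SimSpec, simulate_cohort

# -- rates / recurrence / ITH ----------------------------------------------


def test_neoantigenic_rate():
    assert neoantigenic_rate(12, 2) == 6.0
    assert neoantigenic_rate(0, 5) == 0.0
    assert neoantigenic_rate(3, 0) is None
    with pytest.raises(ValueError):
        neoantigenic_rate(-1, 5)


def test_shared_occurrence_counts_distinct_patients():
    df = pd.DataFrame({
        "peptide": ["AAAA", "AAAA", "AAAA", "BBBB", "BBBB", "CCCC"],
        "patient": ["P1", "P2", "P3", "P1", "P1", "P2"]})
    out = shared_occurrence(df)
    assert out.loc[out.peptide == "AAAA", "n_patients"].item() == 3
    assert out.loc[out.peptide == "AAAA", "recurrent"].item()
    assert out.loc[out.peptide == "BBBB", "n_patients"].item() == 1
    assert not out.loc[out.peptide == "BBBB", "recurrent"].item()
    assert list(out.peptide) == ["AAAA", "BBBB", "CCCC"]  # count desc, then seq
    # invariance under within-patient duplication
    again = shared_occurrence(pd.concat([df, df]))
    assert again.equals(out)


def test_shared_occurrence_empty():
    assert shared_occurrence(pd.DataFrame(columns=["peptide", "patient"])).empty


def test_ith_fraction():
    labels = [Clonality.SUBCLONAL] * 3 + [Clonality.CLONAL] * 7
    assert ith_fraction(labels) == pytest.approx(0.3)
    assert ith_fraction([Clonality.CLONAL] * 4) == 0.0
    assert ith_fraction([]) is None
    assert ith_fraction([Clonality.UNKNOWN] * 5) is None
    assert ith_fraction(labels + labels) == pytest.approx(0.3)  # duplication
    assert ith_fraction(["SUBCLONAL", "CLONAL"]) == 0.5  # string labels


# -- k-mer x allele interactions -------------------------------------------


def test_kmer_interactions_enumerate_all_windows():
    neo = "ACDEFGHIKLM"  # 11 residues -> 4+3+2+1 = 10 k-mers
    alleles = ["HLA-A*02:01", "HLA-B*07:02"]
    never = kmer_allele_interactions(neo, alleles,
                                     MockBindingBackend(seed=0, mode="never"))
    assert len(never) == 10
    assert never.n_interactions.sum() == 0
    always = kmer_allele_interactions(neo, alleles,
                                      MockBindingBackend(seed=0, mode="always"))
    assert always.n_interactions.sum() == 20  # 10 k-mers x 2 alleles
    assert np.allclose(always.log10_interactions,
                       np.log10(always.n_interactions + 1))
    with pytest.raises(ValueError):
        kmer_allele_interactions("SHORT", alleles, MockBindingBackend())


# -- self-dissimilarity -----------------------------------------------------


def test_identical_peptide_scores_the_blosum62_diagonal():
    score, cls = self_dissimilarity("CCCCCCCC", ["CCCCCCCC"])
    assert score == 72  # 8 x BLOSUM62 C:C = 9
    assert cls == "HIGH"


def test_score_exactly_35_is_low_similarity():
    # Y:Y = 7 plus 7 x (A:A = 4) = 35, not > 35
    score, cls = self_dissimilarity("YAAAAAAA", ["YAAAAAAA"])
    assert score == 35
    assert cls == "LOW"


def test_empty_peptidome_is_low():
    score, cls = self_dissimilarity("ACDEFGHI", [])
    assert score is None and cls == "LOW"


@pytest.mark.parametrize("pep", ["ACDEFGHI", "WWWWWWWW", "MKLVNPQRSTV"])
def test_self_score_equals_diagonal_sum_and_dominates_4l(pep):
    blosum = substitution_matrices.load("BLOSUM62")
    diag = sum(blosum[a, a] for a in pep)
    score, _ = self_dissimilarity(pep, [pep])
    assert score == diag
    assert score >= 4 * len(pep)


def test_protein_and_kmer_peptidome_modes_agree(bundle):
    proteome = list(bundle.reference.proteome.values())
    full = SelfSimilarityScorer(proteome, mode="protein")
    kmer = SelfSimilarityScorer(proteome, mode="kmer")
    for pep in ["ACDEFGHI", "WWWWWWWWY", proteome[0][3:12]]:
        assert full.best_score(pep) == kmer.best_score(pep)


# -- odds ratios ------------------------------------------------------------


def test_symmetric_table_gives_unit_odds_ratio():
    res = odds_ratio_haldane(Contingency2x2(10, 10, 10, 10))
    assert res.odds_ratio == 1.0 and not res.corrected


def test_haldane_correction_applied_to_all_cells():
    res = odds_ratio_haldane(Contingency2x2(5, 0, 3, 7))
    assert res.corrected
    assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))
    assert res.odds_ratio == pytest.approx(23.571, abs=5e-4)


def test_reciprocal_tables_multiply_to_one():
    for a, b, c, d in [(10, 4, 3, 9), (2, 7, 8, 1), (5, 5, 1, 9)]:
        x = odds_ratio_haldane(Contingency2x2(a, b, c, d)).odds_ratio
        y = odds_ratio_haldane(Contingency2x2(c, d, a, b)).odds_ratio
        assert x * y == pytest.approx(1.0)


def test_degenerate_table_flagged():
    res = odds_ratio_haldane(Contingency2x2(0, 0, 3, 7))
    assert res.degenerate and res.corrected and math.isfinite(res.odds_ratio)


def test_oncogenic_vs_passenger_worked_example():
    # neoantigenic proportions: 29.1% of oncogenic vs 56.9% of passenger SVs
    assert round(odds_ratio_from_proportions(0.291, 0.569), 2) == 0.31


def test_clonal_subclonal_or_direction_and_null():
    df = pd.DataFrame({
        "patient": ["P1"] * 6,
        "clonality": ["SUBCLONAL"] * 3 + ["CLONAL"] * 3,
        "neoantigenic": [1, 1, 1, 0, 0, 0]})
    pp, _ = clonal_subclonal_or(df)
    assert pp.odds_ratio.item() > 1  # enrichment in subclonal SVs
    df2 = df.assign(neoantigenic=[1, 0, 1, 1, 0, 1])
    pp2, _ = clonal_subclonal_or(df2)
    assert pp2.odds_ratio.item() == pytest.approx(1.0)


def test_patients_without_both_classes_are_skipped():
    df = pd.DataFrame({
        "patient": ["P1", "P1", "P2", "P2"],
        "clonality": ["SUBCLONAL", "CLONAL", "CLONAL", "CLONAL"],
        "neoantigenic": [1, 0, 1, 0]})
    pp, summary = clonal_subclonal_or(df)
    assert summary["n_patients"] == 1 and summary["n_skipped"] == 1


def test_simulated_subclonal_enrichment_recovered():
    """Monte-Carlo at true OR 2.0, 200 patients, fixed seed: the cohort
    median per-patient OR lands in [1.7, 2.3]."""
    sv, _ = simulate_cohort(SimSpec(seed=1, n_patients=200,
                                    true_subclonal_or=2.0))
    _, summary = clonal_subclonal_or(sv)
    assert 1.7 <= summary["median_odds_ratio"] <= 2.3
    assert summary["wilcoxon_p"] < 1e-6  # clearly shifted from OR = 1


# -- depletion logistic -----------------------------------------------------


def test_intercept_only_closed_form():
    n, k = 40, 10
    df = pd.DataFrame({"X1": 0, "X2": 1.0, "X3": 0,
                       "y": [1] * k + [0] * (n - k)})
    fit = depletion_logistic(df)
    assert fit.dropped == ("X1", "X2", "X3")
    assert fit.params["beta1"] == fit.params["beta2"] == fit.params["beta3"] == 0.0
    p_hat = k / n
    assert fit.params["beta0"] == pytest.approx(math.log(p_hat / (1 - p_hat)),
                                                abs=1e-6)


def test_parameter_recovery_within_three_se():
    true = {"beta0": -1.0, "beta1": -1.2, "beta2": 0.01, "beta3": 1.5}
    sv, _ = simulate_cohort(SimSpec(seed=1, n_patients=500))  # ~5000 SV rows
    assert len(sv) > 4000
    fit = depletion_logistic(sv.rename(columns={"neoantigenic": "y"}))
    assert fit.converged
    for name, truth in true.items():
        assert abs(fit.params[name] - truth) < 3 * fit.bse[name], name
    assert fit.wald_p["beta1"] < 1e-6  # oncogenic depletion detected


def _grid_search_mle(x, y):
    """Independent coarse-to-fine grid-search MLE for logit(p)=b0+b1*x."""
    best = (None, None, -np.inf)
    b0s = np.arange(-4, 4.0001, 0.05)
    b1s = np.arange(-4, 4.0001, 0.05)
    for _ in range(2):
        g0, g1 = np.meshgrid(b0s, b1s, indexing="ij")
        eta = g0[..., None] + g1[..., None] * x[None, None, :]
        ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (g0[i, j], g1[i, j], ll[i, j])
        b0s = np.arange(best[0] - 0.06, best[0] + 0.0601, 0.002)
        b1s = np.arange(best[1] - 0.06, best[1] + 0.0601, 0.002)
    return best[0], best[1]


def test_twenty_row_fit_matches_grid_search_oracle():
    x = np.array([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
    y = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    df = pd.DataFrame({"X1": x, "X2": 1.0, "X3": 0, "y": y})
    fit = depletion_logistic(df)
    b0, b1 = _grid_search_mle(x.astype(float), y.astype(float))
    assert fit.params["beta0"] == pytest.approx(b0, abs=5e-3)
    assert fit.params["beta1"] == pytest.approx(b1, abs=5e-3)


def test_perfect_separation_flagged_not_crashed():
    df = pd.DataFrame({"X1": [0] * 10 + [1] * 10, "X2": 1.0, "X3": 0,
                       "y": [0] * 10 + [1] * 10})
    fit = depletion_logistic(df)
    assert not fit.converged or abs(fit.params["beta1"]) > 10


def test_too_few_rows_is_an_error():
    df = pd.DataFrame({"X1": [0, 1], "X2": [1, 2], "X3": [0, 1], "y": [0, 1]})
    with pytest.raises(ValueError):
        depletion_logistic(df)


# -- burdens ----------------------------------------------------------------


def test_burden_rescue_classification():
    rec = burdens("P1", snv_neo=200, indel_neo=50, sv_neo=100)
    assert (rec.tnb, rec.svnb, rec.ganb) == (250, 100, 350)
    assert not rec.tnb_high and rec.ganb_high and rec.rescued


def test_burden_zeros_and_identity():
    zero = burdens("P1", 0, 0, 0)
    assert zero.ganb == 0 and not (zero.tnb_high or zero.ganb_high or zero.rescued)
    no_sv = burdens("P2", 400, 10, 0)
    assert no_sv.ganb == no_sv.tnb and not no_sv.rescued


def test_burden_invariants_on_simulated_cohort():
    _, counts = simulate_cohort(SimSpec(seed=2, n_patients=50))
    tables = CohortTables(pd.DataFrame(), counts)
    for rec in tables.burden_records():
        assert rec.ganb >= rec.tnb >= 0
        assert rec.ganb == rec.tnb + rec.svnb
        if rec.rescued:
            assert rec.svnb > 323 - rec.tnb
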