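# svneoantigen

Neoantigen prediction from somatic **structural variants** (SVs), plus the
cohort-level immunogenomic statistics used to characterize SV-derived
neoantigens.

Most neoantigen pipelines start from SNVs and small indels. SV junctions are
a distinct and potent source: a breakpoint inside a gene can fuse two coding
regions, shift the reading frame, or remove a stop codon, producing long
stretches of entirely novel protein. `svneoantigen` is for cancer
immunogenomics analysts who have somatic SV calls in VCF, a transcript
annotation (GTF), a reference genome (FASTA), and per-patient HLA class I
types, and who want junction-resolved neoantigen calls and cohort summaries.

## What it computes

**Prediction pipeline** (five stages, each drop attributed to a reason):

1. **Parse & canonicalize** — VCF `BND` bracket records and symbolic
   `<DEL>/<DUP>/<INV>` alleles become orientation-resolved breakend pairs
   (side-retained LEFT/RIGHT semantics; `<INV>` expands to its head-to-head
   and tail-to-tail junctions).
2. **Annotate & filter** — breakends are mapped onto the longest-CDS isoform
   of the overlapping gene; junctions with intergenic breakends or
   orientations admitting no continuous 5'→3' transcription path
   (donor must retain its promoter side, acceptor its 3' remainder) are
   rejected.
3. **Assemble & translate** — the chimeric neo-transcript (donor 5' portion +
   acceptor 3' portion, spliced at exon boundaries for intronic breakends) is
   translated from the donor start codon until the first stop codon or the
   transcript 3' end (`READ_THROUGH`). Frameshift status follows from
   `donor coding contribution mod 3` versus the acceptor base's native codon
   phase.
4. **Window & de-self** — the mutated protein span is fragmented into all
   8–11-mers; windows occurring verbatim in the wild-type proteome are
   discarded.
5. **Call neoantigens** — each peptide × HLA allele is scored by a pluggable
   MHC-I binding backend (netMHCpan adapter, or a deterministic mock for
   testing); a peptide is a neoantigen iff some allele has
   **IC50 < 500 nM and %rank < 2.0** (both strict).

**Cohort statistics**: per-mutation neoantigenic rate; shared-neoantigen
recurrence (> 2 patients); k-mer × allele interaction maps; BLOSUM62
Smith–Waterman self-similarity against the normal peptidome (high-similarity
iff best score > 35); intratumor heterogeneity (fraction of subclonal
neoantigens); per-patient subclonal/clonal odds ratios with the
Haldane–Anscombe correction (0.5 added to all cells when any cell is zero)
and a signed-rank cohort test; the immunoediting depletion model

&nbsp;&nbsp;&nbsp;&nbsp;logit P(neoantigen) = β₀ + β₁·X₁ + β₂·X₂ + β₃·X₃

with X₁ = oncogenic indicator, X₂ = number of affected amino acids,
X₃ = frameshift indicator; and the burden metrics TNB (SNV+indel), SVNB
(SV), and GANB = TNB + SVNB with the TNB-High cutoff of > 323 neoantigens
per exome.

A first-class synthetic-data module generates toy genomes with multi-exon
genes on both strands, spikes SV junctions of every class (deletion-like,
duplication-like, h2h/t2t inversion, translocation) in in-frame and
frameshift variants plus designed rejects, and computes an independent
string-level truth table for every spike — the test bed for the whole
pipeline.

## Worked example

Generate a synthetic study and predict neoantigens with the deterministic
always-bind mock backend (no external binaries needed):

```bash
svneoantigen simulate --seed 7 --out demo
printf 'HLA-A*02:01\nHLA-B*07:02\n' > demo/alleles.txt
svneoantigen predict --vcf demo/svs_bnd.vcf --gtf demo/annotation.gtf \
    --fasta demo/genome.fa --alleles demo/alleles.txt --out demo/pred \
    --backend mock --backend-mode always --seed 7
```

The run report prints the stage funnel:

```json
{
 "parsed_svs": 23,
 "feasible_svs": 18,
 "assembled_proteins": 17,
 "candidate_peptides": 1060,
 "neoantigens": 1060,
 "drops": {
  "assembly:NO_UTR_STRUCTURE": 1,
  "filter:INTERGENIC": 2,
  "filter:NO_CODING_EFFECT": 1,
  "filter:ORIENTATION": 2
 }
}
```

Of 23 spiked junctions, 18 admit a continuous transcription path (2 are
intergenic, 2 have infeasible orientations, 1 touches only a 3'UTR), 17
assemble into neo-ORFs (1 loses its start codon), and — with the always-bind
backend — all 1060 non-self 8–11-mers are called. `demo/pred/neoantigens.tsv`
holds one row per peptide × passing allele:

```
patient  sv_id                  peptide   length  ...  allele       ic50   rank    ...
.        del_single_frameshift  EQVGGMSS  8       ...  HLA-A*02:01  9.56   0.5373  ...
```

The statistics layer runs on the simulated cohort tables:

```bash
svneoantigen stats --sv-table demo/cohort_svs.tsv \
    --counts demo/cohort_counts.tsv --out demo/stats.json
```

As a library, the one-line immunoediting check: neoantigenic proportions of
29.1% (oncogenic SVs) vs 56.9% (passenger SVs) give

```python
>>> from svneoantigen import odds_ratio_from_proportions
>>> round(odds_ratio_from_proportions(0.291, 0.569), 2)
0.31
```

i.e. oncogenic SVs are about three-fold depleted of neoantigens.

## Layout

- `src/svneoantigen/sv_io.py` — VCF/GTF/FASTA readers and writers
- `src/svneoantigen/annotate.py` — breakend mapping, SV classification, filters
- `src/svneoantigen/neoorf.py` — neo-transcript assembly and translation
- `src/svneoantigen/epitope.py`, `backends.py` — windowing, self filter, binding calls
- `src/svneoantigen/cohort_stats.py` — cohort statistics
- `src/svneoantigen/simdata.py`, `_oracle.py` — synthetic data + independent truth oracle
- `src/svneoantigen/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — the methods note (model, conventions, limitations)
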