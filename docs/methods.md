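# Methods

This note records the model and conventions behind `svneoantigen`: what is
computed, the choices made where the problem was genuinely open, and what
the synthetic test bed does and does not establish about real data.

## Breakend model and coordinates

An SV junction is two breakends, each a `(chromosome, position, orientation)`
triple. Orientation uses *side-retained* semantics: `LEFT` means reference
bases at coordinates ≤ pos survive and are joined at the junction, `RIGHT`
means bases ≥ pos survive. This is symmetric under exchanging the mates,
unlike strand/bracket notation, and maps one-to-one onto the four VCF
bracket forms (`t[p[`, `t]p]`, `]p]t`, `[p[t`).

VCF and GTF coordinates are 1-based inclusive on input; every internal
interval is 0-based half-open, with converters living only at the I/O
boundary. For symbolic alleles this package treats `POS` and `END` as the
two junction bases themselves: `<DEL>` with POS=p, END=e joins base p to
base e, deleting the bases strictly between; `<DUP>` joins e back to p;
`<INV>` expands into its two junctions — `(p LEFT, e LEFT)` (head-to-head)
and `(p RIGHT, e RIGHT)` (tail-to-tail) — which are processed independently
and may have different fates. The synthetic VCF writer uses the same
convention, so the symbolic and BND dialects describe identical junction
sets. Micro-homology/insertion sequence in a BND ALT is retained as
metadata but never moves coordinates: prediction uses breakpoint positions
and orientations only.

Intrachromosomal orientation pairs classify the junction: (LEFT, RIGHT) by
ascending position is deletion-like, (RIGHT, LEFT) duplication-like,
(LEFT, LEFT) head-to-head inversion, (RIGHT, RIGHT) tail-to-tail inversion;
different chromosomes give a translocation.

## Transcript selection and feasibility

Every breakend is mapped to the gene overlapping it; among a gene's
isoforms the coding transcript with the **longest CDS** is used (ties broken
by lexicographically smallest transcript id; overlapping genes by longest
selected CDS, then gene id). Genes with only noncoding isoforms are treated
as intergenic space for prediction purposes.

A junction is feasible iff some assignment of a 5' **donor** and 3'
**acceptor** exists such that transcription runs continuously across it:
the donor's retained side must contain its transcript's promoter (LEFT for
`+` genes, RIGHT for `−` genes) and the acceptor's retained side its 3'
remainder. Rejection reasons, in precedence order:

- `INTERGENIC` — either breakend outside any coding gene. Strict by
  default: one intergenic end suffices. The `allow_one_intergenic` switch
  relaxes this for exploratory read-through-into-intergenic analysis, in
  which case the acceptor tail is raw genomic sequence (default 300 nt)
  read away from the breakend.
- `ORIENTATION` — no donor/acceptor assignment yields a continuous path
  (e.g. a junction joining the promoter-proximal sides of two `+` genes).
- `NO_CODING_EFFECT` — the only viable donor breakend lies in a 3'UTR:
  the CDS is untouched and no mutant protein can result. A 5'UTR donor is
  feasible (the entire CDS context downstream of the junction changes).

Breakends exactly on an exon boundary take the region of the retained base
(a LEFT breakend at an exon's last base is exonic).

## Neo-ORF assembly and translation

The chimeric mRNA is the donor transcript's exonic sequence from its
transcription start to the breakend, concatenated with the acceptor's
exonic sequence from the breakend to its 3' end. Intronic breakends splice
at the nearest complete exon boundary on the retained side — the standard
fusion-transcript convention (donor 5' splice site joined to acceptor 3'
splice site). Exonic breakends truncate the exon at the retained base,
creating junction-derived codons. Splice-site destruction (breakends within
±2 nt of a splice site) is not modelled; the exon-boundary rule applies
regardless.

Assembly rejects with `NO_UTR_STRUCTURE` when the chimera lacks the donor
5'UTR/start codon or any 3' sequence. When the donor start codon is lost
and start-rescue is enabled, the first downstream ATG is used and the
product flagged `start_rescued`; rescued proteins are **excluded from
neoantigen calling by default** (`include_start_rescued=False`) because the
true translation start of such alleles is uncertain.

Translation runs from the donor start codon by the standard codon table to
the first stop codon (`STOP`; the stop is not part of the protein) or to
the transcript 3' boundary (`READ_THROUGH`; a trailing partial codon is
discarded). Codons containing N translate to X, and any peptide window
containing X is dropped downstream, since binding predictors reject
non-standard residues.

**Frameshift** is decided by codon-phase arithmetic: the junction is
in-frame iff the first acceptor-derived coding base lands at its native
phase, i.e. `(donor coding contribution + acceptor 5'UTR gap) mod 3` equals
the breakpoint's phase within the acceptor CDS. Acceptor tails with no
native coding context (3'UTR, intergenic) are always novel sequence and
flagged frameshift.

**Mutated span** (vs the donor wild-type protein): frameshift, two-gene,
and read-through products diverge from the first mismatched residue to the
protein's end. In-frame single-gene events are trimmed from both ends, so
an in-frame deletion whose junction residues reproduce wild type has an
empty span and correctly yields zero neo-peptides; an in-frame duplication
keeps at least the one junction residue whose context is novel.

## Epitopes and binding

All 8–11-mer windows overlapping the mutated span by ≥ 1 residue are
candidates. The self filter removes any window occurring as an **exact
substring of any wild-type protein** in the annotation proteome
(longest-CDS isoform per gene) — the conservative operationalization of
"at least one non-self residue"; comparison against only the two parent
proteins is available via `self_filter_mode="parents"`. Duplicates (same
sequence, same patient) collapse into one record with merged SV provenance.

Binding prediction is out of scope by design: netMHCpan (affinity) and
netMHCstabPan (complex stability) are driven through subprocess adapters
that parse their tabular output by header and map rows back positionally,
failing loudly on row-count mismatches. The deterministic mock backend
hashes `(peptide, allele, seed)` to an IC50 in [1, 50000) nM and a rank in
[0, 100), with `always`/`never` modes for round-trip tests. A peptide is
called a neoantigen iff at least one allele passes **IC50 < 500 nM AND
rank < 2.0**; both comparisons are strict, and the conjunction is the
conservative reading of the calling rule. Hydrophobicity is the fraction
of residues in {V, I, L, F, M, W, C}.

## Cohort statistics

- **Neoantigenic rate** = neoantigens per mutation; undefined (missing)
  at zero mutations.
- **Recurrence**: distinct-patient count per peptide; recurrent ⇔ > 2
  patients.
- **Self-similarity**: best Smith–Waterman score under BLOSUM62 with
  blast-style affine gaps (a gap of length k costs 11 + k; in
  `PairwiseAligner` terms open −12 / extend −1, since its open score is
  charged at the first gap position). High-similarity ⇔ best score > 35,
  strictly. The peptidome may be held as full proteins (default, memory-
  economical) or as the explicit 8–11-mer set; for short queries local
  alignment gives identical maxima, and the equivalence is tested.
- **ITH** = subclonal / (clonal + subclonal) neoantigens; UNKNOWN labels
  excluded; missing when nothing is labelled.
- **Odds ratios** use the Haldane–Anscombe correction: 0.5 added to **all
  four** cells whenever any cell is zero (the standard form). Per-patient
  subclonal/clonal ORs require both clonality classes; patients failing
  this are skipped with a logged reason. The cohort-level location test of
  log-ORs against 0 uses the exact signed-rank distribution below n = 25
  and the normal approximation above.
- **Depletion model**: logit P = β₀ + β₁X₁ + β₂X₂ + β₃X₃, fitted by
  Newton/IRLS maximum likelihood (statsmodels) with tolerance 1e-8 and at
  most 100 iterations; non-varying covariates are dropped with coefficient
  reported as 0; perfect separation clears the convergence flag. X₂,
  "number of affected amino acids", is implemented as the length of the
  mutated span — an interpretation, since the quantity admits several
  readings. The Wald test on β₁ quantifies oncogenic depletion.
- **Burdens**: TNB = SNV+indel neoantigens, SVNB = SV neoantigens,
  GANB = TNB + SVNB; High means strictly above the threshold (default
  323 per exome, the TNB transform of the TMB-High cutoff); "rescued"
  patients are TNB-low but GANB-high.

## Synthetic data and what the tests show

The generator builds small genes (exons ~30–300 nt, introns 40–90 nt,
clean ATG…stop ORFs without internal stops, both strands, two chromosomes)
so that brute-force oracles run in milliseconds. Geometry is controlled to
make every spike intent satisfiable: internal exons are fully coding with a
chosen length mod 3 (in-frame vs frameshift single-gene events), exonic
breakends are slid base-by-base to hit a target codon phase (two-gene
fusions, inversions), and the read-through gene receives a T-free — hence
stop-free in every frame — 3'UTR. The default spike set holds 23 junctions:
all five classes in in-frame and frameshift variants, single- and two-gene
contexts, a read-through, and five designed rejects; it is written in both
a pure-BND and a symbolic VCF dialect describing the same truth set.

Truth is computed by a **naive oracle** that shares no code with the
pipeline: its own FASTA/GTF/VCF line parsers, a hard-coded codon table,
splicing by string slicing, single-frame translation, exhaustive window
enumeration, and substring self-filtering. End-to-end truth recovery is
exact on these fixtures and on hundreds of additional fully random
junctions.

The cohort simulator draws per-SV covariates (oncogenic ~ Bernoulli(0.2),
affected amino acids ~ round(Gamma(2, 15)), frameshift ~ Bernoulli(0.6) —
magnitudes a cohort analyst would consider plausible for SV data), outcomes
from the logistic model at β = (−1.0, −1.2, 0.01, 1.5), and clonality
conditional on the outcome so the subclonal/clonal OR hits its target
(default 2.0, base subclonal rate 0.35), with ~10 SVs per patient.
Parameter-recovery tests use ~5000 SV rows (500 patients) and 200 patients
for the OR median.

What passing these tests does **not** show: performance on real genomes
(repeats, overlapping genes, alternative isoforms, imperfect annotations),
real SV-caller artifacts (imprecise breakpoints, strand errors,
micro-homology shifts), real MHC binding (the mock backend is a hash), or
NMD and expression effects on presentation. The toy genes are short and
GC-balanced; self-filter behaviour on a 20,000-protein proteome is
exercised only at reduced scale.

## Numerical and degenerate-input choices

- Tie-breaks are deterministic everywhere (lexicographic ids for isoform
  and gene ties; best allele = minimum IC50 then allele name).
- Zero-mutation rates, empty peptidomes, and unlabelled clonality return
  missing values rather than raising.
- An in-frame event identical to wild type yields an empty mutated span
  and zero peptides — a valid outcome, not an error.
- Junction spans are undefined for interchromosomal pairs; per-patient ORs
  always finite via the Haldane–Anscombe correction, with degenerate
  tables (a zero row/column) flagged.
- All randomness (mock backend, generator, cohort simulation) flows from
  explicit integer seeds; reruns are byte-identical.

## Known limitations

Single isoform per gene (longest CDS) rather than expression-guided
selection; no splice-site destruction modelling; no multi-junction event
reconstruction (chromothripsis chains); binding and stability predictions
are external tools' responsibility; MHC class II, immunogenicity scoring,
and proteasomal processing are out of scope.
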