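"""Shared fixtures: a spiked synthetic fixture bundle, pipeline runs on it,
and a small hand-specified two-gene reference for arithmetic unit tests."""

from __future__ import annotations

from pathlib import Path

import pytest

from svneoantigen import _oracle
from svneoantigen.pipeline import RunConfig, run_pipeline
from svneoantigen.simdata import GeneLayout, SimSpec, ToyReference, generate_fixture
from svneoantigen.sv_io import load_annotation, load_genome

SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seeded toy reference with 23 spiked SVs and oracle truth."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(SimSpec(seed=SEED), outdir)


@pytest.fixture(scope="session")
def allele_file(tmp_path_factory) -> Path:
    path = tmp_path_factory.mktemp("alleles") / "alleles.txt"
    path.write_text("HLA-A*02:01\nHLA-B*07:02\n")
    return path


@pytest.fixture(scope="session")
def truth_by_id(bundle):
    return {t.sv_id: t for t in bundle.spikes.truth}


def _run(bundle, allele_file, outdir, vcf, mode="always", **kw):
    cfg = RunConfig(vcf=str(vcf), gtf=str(bundle.gtf), fasta=str(bundle.fasta),
                    alleles=str(allele_file), outdir=str(outdir),
                    backend="mock", backend_mode=mode, seed=SEED, **kw)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def run_always(bundle, allele_file, tmp_path_factory):
    """Pipeline on the BND dialect with the always-bind mock backend."""
    return _run(bundle, allele_file, tmp_path_factory.mktemp("run_always"),
                bundle.vcf_bnd)


@pytest.fixture(scope="session")
def run_symbolic(bundle, allele_file, tmp_path_factory):
    """Same truth set through the symbolic VCF dialect."""
    return _run(bundle, allele_file, tmp_path_factory.mktemp("run_sym"),
                bundle.vcf_symbolic)


# ---------------------------------------------------------------------------
# hand-specified reference: gene A (+) and gene B (-) with round-number
# geometry so region/offset examples can be counted by hand.
#
# Gene A (+, contig cA, gene body at 0-based 100): exons of 100/80/80 nt,
# introns 50/50, 5'UTR 10 nt, 3'UTR 40 nt -> CDS 210 nt = 70 codons;
# exon 1 carries 90 coding nt, exon 2 is fully coding (80 nt).
# Gene B is the same geometry on the minus strand of contig cB.

_CODON_CYCLE = ["GCT", "TGC", "GAT", "GAA", "TTT",
                "GGT", "CAT", "ATT", "AAA", "CTG"]  # A C D E F G H I K L


def _toy_tx_seq() -> str:
    body = "".join(_CODON_CYCLE[i % 10] for i in range(68))
    cds = "ATG" + body + "TAA"
    assert len(cds) == 210
    return "C" * 10 + cds + "CT" * 20


def _toy_layout(gene_id: str, chrom: str, strand: str) -> GeneLayout:
    tx = _toy_tx_seq()
    exon_lens, intron_lens = [100, 80, 80], [50, 50]
    parts, off = [], 0
    for i, el in enumerate(exon_lens):
        parts.append(tx[off:off + el])
        off += el
        if i < len(intron_lens):
            parts.append("G" * 25 + "A" * 25)
        # introns are 50 nt of fixed sequence
    body = "".join(parts)
    if strand == "-":
        body = _oracle.rc(body)
    return GeneLayout(gene_id=gene_id, chrom=chrom, strand=strand, start=100,
                      exon_lens=exon_lens, intron_lens=intron_lens,
                      utr5=10, utr3=40, tx_seq=tx, gene_seq=body)


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    a = _toy_layout("GA", "cA", "+")
    b = _toy_layout("GB", "cB", "-")
    genome = {}
    for lay in (a, b):
        genome[lay.chrom] = "T" * 100 + lay.gene_seq + "T" * 100
    ref = ToyReference(genome=genome, layouts=[a, b],
                       proteome={lay.gene_id: _oracle.translate(
                           lay.tx_seq[10:220]) for lay in (a, b)})
    outdir = tmp_path_factory.mktemp("toy")
    fasta, gtf = ref.write(outdir)
    return {"ref": ref, "fasta": fasta, "gtf": gtf}


@pytest.fixture(scope="session")
def toy_txdb(toy_ref):
    return load_annotation(str(toy_ref["gtf"]))


@pytest.fixture(scope="session")
def toy_genome(toy_ref):
    return load_genome(str(toy_ref["fasta"]))
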