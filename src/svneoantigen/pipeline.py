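"""End-to-end orchestration: VCF -> annotation -> neo-ORFs -> neoantigens.

The run is a funnel — parsed junctions, feasible junctions, assembled
neo-transcripts, translated neo-proteins, candidate peptides, called
neoantigens — and every drop is attributed to a reason, so the stage counts
always reconcile: survivors + per-reason drops = stage input.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annotate as _annotate
from . import epitope as _epitope
from . import neoorf as _neoorf
from . import sv_io as _sv_io
from .backends import BindingBackend, get_backend
from .model import NeoantigenRecord, NeoPeptide, NeoProtein, SvAnnotation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    gtf: str
    fasta: str
    alleles: str  # path to an allele list, one per line
    outdir: str
    backend: str = "mock"
    backend_mode: str = "hash"
    seed: int = 0
    sample: Optional[str] = None
    ic50_threshold: float = _epitope.DEFAULT_IC50_NM
    rank_threshold: float = _epitope.DEFAULT_RANK
    k_min: int = _epitope.K_MIN
    k_max: int = _epitope.K_MAX
    include_start_rescued: bool = False
    start_rescue: bool = False
    allow_one_intergenic: bool = False
    self_filter_mode: str = "proteome"  # or "parents"

    def __post_init__(self) -> None:
        if self.ic50_threshold <= 0 or self.rank_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")


@dataclass
class RunResult:
    summary: dict
    annotations: list[SvAnnotation] = field(default_factory=list)
    proteins: list[NeoProtein] = field(default_factory=list)
    peptides: list[NeoPeptide] = field(default_factory=list)
    neoantigens: list[NeoantigenRecord] = field(default_factory=list)
    sv_status: dict[str, str] = field(default_factory=dict)  # sv_id -> OK / reason
    sv_peptides: dict[str, set] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig,
                 backend: Optional[BindingBackend] = None) -> RunResult:
    """Run the five prediction stages and write all outputs atomically."""
    for path in (cfg.vcf, cfg.gtf, cfg.fasta, cfg.alleles):
        if not Path(path).is_file():
            raise FileNotFoundError(f"input not readable: {path}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = _sv_io.load_genome(cfg.fasta)
    txdb = _sv_io.load_annotation(cfg.gtf)
    alleles = _epitope.read_allele_list(cfg.alleles)
    if backend is None:
        backend = get_backend(cfg.backend, seed=cfg.seed, mode=cfg.backend_mode)

    pairs, parse_rejects = _sv_io.parse_sv_vcf(cfg.vcf, sample=cfg.sample,
                                               genome=genome)
    filter_cfg = _annotate.FilterConfig(
        allow_one_intergenic=cfg.allow_one_intergenic)
    orf_cfg = _neoorf.NeoOrfConfig(start_rescue=cfg.start_rescue,
                                   include_start_rescued=cfg.include_start_rescued)

    result = RunResult(summary={})
    drops: Counter = Counter(f"parse:{r.reason}" for r in parse_rejects)
    annotations, feasible = [], []
    for pair in pairs:
        ann = _annotate.annotate_pair(pair, txdb, filter_cfg)
        annotations.append(ann)
        if ann.feasible:
            feasible.append(ann)
        else:
            drops[f"filter:{ann.reject_reason.value}"] += 1
            result.sv_status[pair.id] = ann.reject_reason.value
    result.annotations = annotations

    meta: dict[str, dict] = {}
    proteins: list[NeoProtein] = []
    for ann in feasible:
        try:
            nt = _neoorf.assemble_neo_transcript(ann, txdb, genome, orf_cfg)
            np_ = _neoorf.translate_neo(nt, orf_cfg)
        except _neoorf.NeoOrfRejection as exc:
            drops[f"assembly:{exc.reason.value}"] += 1
            result.sv_status[ann.pair.id] = exc.reason.value
            continue
        if np_.start_rescued and not cfg.include_start_rescued:
            drops["translate:START_RESCUED_EXCLUDED"] += 1
            result.sv_status[ann.pair.id] = "START_RESCUED_EXCLUDED"
            continue
        wt = txdb.wild_type_protein(nt.donor_transcript, genome)
        _neoorf.mutated_interval(np_, wt)
        np_.sv_class = ann.sv_class
        np_.patient = ann.pair.patient
        proteins.append(np_)
        result.sv_status[ann.pair.id] = "OK"
        meta[np_.sv_id] = {
            "sv_class": ann.sv_class.value, "frameshift": np_.frameshift,
            "termination": np_.termination.value,
            "gene_context": np_.gene_context,
        }
    result.proteins = proteins

    proteome = txdb.proteome(genome)
    peptides: list[NeoPeptide] = []
    for np_ in proteins:
        raw = _epitope.window_peptides(np_, cfg.k_min, cfg.k_max)
        if cfg.self_filter_mode == "parents":
            parents = [proteome[g] for g in
                       {np_.donor_gene, np_.acceptor_gene} if g in proteome]
            kept = _epitope.filter_self(raw, parents)
        else:
            kept = _epitope.filter_self(raw, proteome.values())
        result.sv_peptides[np_.sv_id] = {p.sequence for p in kept}
        peptides.extend(kept)
    # cross-SV patient-level deduplication
    peptides = _epitope.filter_self(peptides, [])
    result.peptides = peptides

    calls = _epitope.predict_binding(peptides, alleles, backend)
    neoantigens = _epitope.call_neoantigens(
        peptides, calls, cfg.ic50_threshold, cfg.rank_threshold)
    result.neoantigens = neoantigens

    summary = {
        "parsed_svs": len(pairs),
        "parse_rejects": len(parse_rejects),
        "feasible_svs": len(feasible),
        "assembled_proteins": len(proteins),
        "candidate_peptides": len(peptides),
        "neoantigens": len(neoantigens),
        "alleles": len(alleles),
        "drops": dict(sorted(drops.items())),
        "config": {
            "backend": backend.name, "seed": cfg.seed,
            "ic50_threshold": cfg.ic50_threshold,
            "rank_threshold": cfg.rank_threshold,
            "k_min": cfg.k_min, "k_max": cfg.k_max,
        },
    }
    result.summary = summary

    _write_outputs(result, cfg, outdir, meta)
    logger.info("pipeline: %s", summary)
    return result


def _write_outputs(result: RunResult, cfg: RunConfig, outdir: Path,
                   meta: dict) -> None:
    """Write every table to a temp name then rename (atomic per file)."""
    def atomic(name: str, writer) -> None:
        tmp = outdir / (name + ".tmp")
        writer(str(tmp))
        tmp.replace(outdir / name)

    atomic("junctions.tsv", lambda p: _sv_io.write_junction_table(
        [a.pair for a in result.annotations], p))
    atomic("annotations.tsv", lambda p: _annotate.write_annotation_table(
        result.annotations, p))
    atomic("neoproteins.fa", lambda p: _neoorf.write_neoprotein_fasta(
        result.proteins, p))
    atomic("neoorfs.tsv", lambda p: _neoorf.write_neoorf_table(
        result.proteins, p))
    atomic("peptides.fa", lambda p: _epitope.write_peptide_fasta(
        result.peptides, p))
    atomic("neoantigens.tsv", lambda p: _epitope.write_neoantigen_table(
        result.neoantigens, p, extra=meta))
    atomic("run_report.json", lambda p: Path(p).write_text(
        json.dumps(result.summary, indent=1, sort_keys=True)))
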