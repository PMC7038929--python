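"""End-to-end orchestration of the filtering ladder and summaries.

Stage order is fixed: score -> identity -> ratio -> dedupe/classify ->
non-M/M -> recurrence -> profiling / summaries / peptides.  Classification
runs once per unique chimera (labels are determined by the junction key),
after the row-level filters, so annotation queries are not repeated per
call.  Every stage logs one structured line and contributes a
:class:`~rnachimera.model.FilterReport`; a manifest records parameters and
counts so a run can be reproduced exactly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import classify as cls
from . import filters as flt
from . import io as rio
from . import peptides as pep
from . import profiling as prof
from . import summarize as summ
from .annotation import GenomeAnnotation
from .model import ChimeraCall, ChimeraKey, UniqueChimera

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "call_from_key", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    calls: Union[str, Path]
    gtf: Union[str, Path]
    genome: Union[str, Path]
    transcriptome: Union[str, Path]
    metadata: Union[str, Path]
    outdir: Union[str, Path]
    expression: Optional[Union[str, Path]] = None
    psms: Optional[Union[str, Path]] = None
    min_score: float = 0.6
    min_identity: float = 0.90
    min_flank: int = 10
    kmer: int = 11
    ratio_mode: str = "either"
    min_frequency: int = 5
    readthrough_max_gap: int = 100_000
    peptide_flank: int = 200
    min_side: int = 2
    q_max: float = 0.05
    expression_cutoff: float = 0.04
    seed: int = 0

    def parameter_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclass
class PipelineResult:
    uniques_all: list[UniqueChimera]
    uniques_non_mm: list[UniqueChimera]
    uniques_recurrent: list[UniqueChimera]
    reports: list
    tissue_recurrent: dict
    manifest: dict


def call_from_key(key: ChimeraKey) -> ChimeraCall:
    """A minimal call carrying only the junction key, for classification
    and peptide prediction at unique-chimera resolution."""
    return ChimeraCall(
        sample_id="", gene5=key.gene5, gene3=key.gene3,
        chrom5=key.chrom5, pos5=key.pos5, strand5=key.strand5,
        chrom3=key.chrom3, pos3=key.pos3, strand3=key.strand3,
        junction_seq="", score=1.0,
        chimera_expr=0.0, gene5_expr=0.0, gene3_expr=0.0,
    )


def label_uniques(uniques: Sequence[UniqueChimera],
                  annotation: GenomeAnnotation,
                  genome: Optional[Mapping[str, str]] = None,
                  pair_cfg: Optional[cls.PairClassConfig] = None,
                  ) -> tuple[list[UniqueChimera], list[tuple[UniqueChimera, str]]]:
    """Classify each unique chimera; returns (labelled, failed) where each
    failure carries its error message (those chimeras are excluded from
    class-dependent stages, never silently dropped)."""
    pair_cfg = pair_cfg or cls.PairClassConfig()
    labelled, failed = [], []
    for u in uniques:
        try:
            u.labels = cls.classify_call(call_from_key(u.key), annotation,
                                         genome, pair_cfg)
            labelled.append(u)
        except cls.ClassificationError as exc:
            failed.append((u, str(exc)))
    if failed:
        logger.warning("classification failed for %d unique chimeras",
                       len(failed))
    return labelled, failed


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """Run the full ladder, writing stage outputs under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = []

    calls = rio.read_call_table(cfg.calls)
    annotation = rio.read_gtf(cfg.gtf)
    genome = rio.read_fasta(cfg.genome)
    transcriptome = rio.read_fasta(cfg.transcriptome)
    metadata = rio.read_metadata(cfg.metadata)
    logger.info("loaded %d calls, %d genes, %d samples",
                len(calls), len(annotation), len(metadata.samples))

    kept, _, report = flt.score_filter(calls, cfg.min_score)
    reports.append(report)
    logger.info("stage score: %d -> %d", report.n_input, report.n_kept)

    kept, _, report = flt.identity_filter(
        kept, transcriptome, min_identity=cfg.min_identity,
        min_flank=cfg.min_flank, k=cfg.kmer)
    reports.append(report)
    logger.info("stage identity: %d -> %d", report.n_input, report.n_kept)

    kept, _, report = flt.ratio_filter(kept, mode=cfg.ratio_mode)
    reports.append(report)
    logger.info("stage ratio: %d -> %d", report.n_input, report.n_kept)

    uniques = flt.dedupe(kept, metadata)
    pair_cfg = cls.PairClassConfig(readthrough_max_gap=cfg.readthrough_max_gap)
    uniques, failed = label_uniques(uniques, annotation, genome, pair_cfg)

    non_mm, _, report = flt.remove_mm(uniques)
    reports.append(report)
    logger.info("stage non-M/M: %d -> %d", report.n_input, report.n_kept)

    recurrent, _, report = flt.global_recurrence(non_mm, cfg.min_frequency)
    reports.append(report)
    logger.info("stage recurrence: %d -> %d", report.n_input, report.n_kept)

    per_tissue = flt.tissue_recurrent(non_mm, metadata)

    # summaries --------------------------------------------------------------
    stages = {"all": uniques, "non_mm": non_mm, "non_mm_recurrent": recurrent}
    stage_dists = [asdict(d) for d in summ.stage_distributions(
        {k: v for k, v in stages.items() if v})]
    motif_summary = summ.splice_motif_summary(uniques)
    freq_hist = summ.frequency_histogram(uniques)
    cdf = summ.relative_expression_cdf(uniques)
    parents5 = {u.key.gene5 for u in uniques}
    parents3 = {u.key.gene3 for u in uniques}
    all_symbols = [g.symbol for g in annotation.genes]
    try:
        utr3 = summ.utr3_comparison(parents5, parents3, all_symbols,
                                    annotation)
        utr3_out = {k: v for k, v in utr3.items() if not k.startswith("lengths")}
    except ValueError as exc:
        utr3_out = {"error": str(exc)}
    try:
        chrom_corr = summ.chromosome_correlation(uniques, annotation)
    except ValueError as exc:
        chrom_corr = {"error": str(exc)}

    # profiling --------------------------------------------------------------
    chim_matrix = prof.chimera_matrix(recurrent, metadata.samples)
    embed_summary = prof.export_embedding_matrix(
        chim_matrix, outdir / "chimera_matrix.tsv")
    smc_out: dict = {}
    if cfg.expression is not None:
        expression = rio.read_expression(cfg.expression)
        parent_map = {str(u.key): u.key.gene_pair for u in recurrent}
        wanted = sorted({g for pair in parent_map.values() for g in pair})
        gm = prof.gene_matrix(expression, wanted, cfg.expression_cutoff)
        _, histogram = prof.smc_summary(chim_matrix, gm, parent_map)
        smc_out = histogram
    common = prof.common_chimeras(non_mm, metadata)
    specific = prof.tissue_specific(non_mm, metadata, recurrent=per_tissue)

    # peptides ---------------------------------------------------------------
    peptides = []
    for u in recurrent:
        peptides.extend(pep.junction_peptides(
            call_from_key(u.key), genome, annotation,
            flank=cfg.peptide_flank, min_side=cfg.min_side))
    pep.write_peptide_db(peptides, {}, outdir / "peptide_db.fa")
    psm_summary: dict = {}
    if cfg.psms is not None:
        psms = rio.read_psm_table(cfg.psms)
        _, _, psm_summary = pep.filter_psms(
            psms, peptides, q_max=cfg.q_max, min_side=cfg.min_side)

    # outputs ----------------------------------------------------------------
    rio.write_call_table(kept, outdir / "calls_filtered.tsv")
    manifest = {
        "parameters": cfg.parameter_dict(),
        "stage_order": ["score", "identity", "ratio", "dedupe_classify",
                        "non_mm", "recurrence"],
        "reports": [r.to_dict() for r in reports],
        "n_unique": len(uniques),
        "n_classification_failures": len(failed),
        "n_non_mm": len(non_mm),
        "n_recurrent": len(recurrent),
        "n_common": len(common),
        "tissue_specific_counts": {t: len(s) for t, s in specific.items()},
        "tissue_recurrent_counts": {t: len(s) for t, s in per_tissue.items()},
        "stage_distributions": stage_dists,
        "splice_motifs": motif_summary,
        "frequency_histogram": {str(k): v for k, v in freq_hist.items()},
        "utr3_comparison": utr3_out,
        "chromosome_correlation": chrom_corr,
        "embedding_export": embed_summary,
        "smc_histogram": smc_out,
        "n_chimeric_peptides": len(peptides),
        "psm_summary": psm_summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    cdf.to_csv(outdir / "relative_expression_cdf.tsv", sep="\t", index=False)
    return PipelineResult(
        uniques_all=uniques, uniques_non_mm=non_mm,
        uniques_recurrent=recurrent, reports=reports,
        tissue_recurrent=per_tissue, manifest=manifest,
    )
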