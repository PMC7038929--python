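"""Per-chimera classification.

Each chimera receives one label per classifier:

* junction class E/E, E/M, M/E or M/M by whether each breakpoint coincides
  with an annotated exon end or falls mid-exon;
* gene-pair class read-through / intra-others / inter-chromosomal from the
  parental genes' chromosomes, strands and proximity;
* frame class in-frame / frame-shift / NA from CDS reading-frame phases on
  both sides of the junction;
* canonical splice-motif flags (donor AG|GT, acceptor AG|G);
* an "eNeM" isoform name from the exon ordinals flanking the junction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    boundary_role,
    cds_phase,
    exon_index_of,
)
from .model import ChimeraCall, ChimeraLabels
from .sequence import tx_window

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationError",
    "PairClassConfig",
    "classify_junction",
    "classify_pair",
    "predict_frame",
    "splice_motifs",
    "isoform_name",
    "classify_call",
]


class ClassificationError(ValueError):
    """A call could not be classified (e.g. unknown gene symbol)."""


@dataclass(frozen=True)
class PairClassConfig:
    """Proximity rule for the read-through (cis-SAGe) class.

    Read-throughs arise from cis-splicing between neighboring same-strand
    genes; ``readthrough_max_gap`` bounds the intergenic distance (bp)
    between the 5' gene's end and the 3' gene's start in transcription
    direction.  Optionally require that no same-strand gene lies wholly
    between the pair.
    """

    readthrough_max_gap: int = 100_000
    require_no_intervening_same_strand_gene: bool = False

    def __post_init__(self) -> None:
        if self.readthrough_max_gap < 0:
            raise ValueError("readthrough_max_gap must be >= 0")


DEFAULT_PAIR_CONFIG = PairClassConfig()

_ROLE_CODE = {"exon_end": "E", "exon_middle": "M", "outside": "M"}


def _require_gene(annotation: GenomeAnnotation, symbol: str) -> GeneModel:
    gene = annotation.gene(symbol)
    if gene is None:
        raise ClassificationError(f"gene {symbol!r} absent from annotation")
    return gene


def classify_junction(call: ChimeraCall, annotation: GenomeAnnotation,
                      tolerance: int = 0) -> str:
    """E/E, E/M, M/E or M/M from the breakpoints' exon-boundary roles.

    Breakpoints outside any exon of the gene map to the conservative "M"
    side (the four-class scheme has no fifth category); such cases are
    logged for audit.
    """
    if call.missing_breakpoint:
        raise ClassificationError("call has no predicted breakpoints")
    gene5 = _require_gene(annotation, call.gene5)
    gene3 = _require_gene(annotation, call.gene3)
    role5 = boundary_role(gene5, call.pos5, "donor", tolerance)
    role3 = boundary_role(gene3, call.pos3, "acceptor", tolerance)
    for role, side in ((role5, "5'"), (role3, "3'")):
        if role == "outside":
            logger.info("%s: %s breakpoint outside gene; treated as M",
                        call.key, side)
    return _ROLE_CODE[role5] + _ROLE_CODE[role3]


def classify_pair(call: ChimeraCall, annotation: GenomeAnnotation,
                  cfg: PairClassConfig = DEFAULT_PAIR_CONFIG) -> str:
    """read_through / intra_other / inter_chromosomal for the gene pair."""
    gene5 = _require_gene(annotation, call.gene5)
    gene3 = _require_gene(annotation, call.gene3)
    if gene5.chrom != gene3.chrom:
        return "inter_chromosomal"
    if gene5.strand != gene3.strand:
        return "intra_other"
    s5, e5 = gene5.span
    s3, e3 = gene3.span
    if gene5.strand == "+":
        upstream_ordered = e5 <= s3
        gap = s3 - e5
        gap_interval = (e5, s3)
    else:
        upstream_ordered = e3 <= s5
        gap = s5 - e3
        gap_interval = (e3, s5)
    if not upstream_ordered:
        if max(s5, s3) < min(e5, e3):
            logger.warning("%s: overlapping gene spans; classified intra_other",
                           call.key)
        return "intra_other"
    if gap > cfg.readthrough_max_gap:
        return "intra_other"
    if cfg.require_no_intervening_same_strand_gene and gap > 0:
        lo, hi = gap_interval
        for g in annotation.genes_overlapping(gene5.chrom, lo, hi):
            gs, ge = g.span
            if (g.gene_id not in (gene5.gene_id, gene3.gene_id)
                    and g.strand == gene5.strand and lo <= gs and ge <= hi):
                return "intra_other"
    return "read_through"


def _cds_phases(gene: GeneModel, pos: int) -> set[int]:
    """Phases of ``pos`` over every coding transcript whose CDS contains it."""
    phases: set[int] = set()
    for tx in gene.coding_transcripts():
        lo, hi = tx.span
        if not lo + 1 <= pos <= hi:
            continue
        phase = cds_phase(tx, pos)
        if isinstance(phase, int):
            phases.add(phase)
    return phases


def predict_frame(call: ChimeraCall, annotation: GenomeAnnotation) -> str:
    """in_frame / frame_shift / na from CDS phases at the junction.

    The junction continues the codon walk when the phase following the last
    5' base equals the phase of the first 3' base.  Evaluated over all
    coding transcript pairs: in_frame if any pair is compatible,
    frame_shift if pairs exist but none is compatible, na if either side
    never falls in a CDS.
    """
    gene5 = _require_gene(annotation, call.gene5)
    gene3 = _require_gene(annotation, call.gene3)
    phases5 = _cds_phases(gene5, call.pos5)
    phases3 = _cds_phases(gene3, call.pos3)
    if not phases5 or not phases3:
        return "na"
    for p5 in phases5:
        if (p5 + 1) % 3 in phases3:
            return "in_frame"
    return "frame_shift"


def splice_motifs(call: ChimeraCall, genome: Mapping[str, str],
                  ) -> tuple[Optional[bool], Optional[bool]]:
    """Canonical splice-site motif flags at the junction.

    Donor (5' junction): the two transcript-strand bases ending at ``pos5``
    read AG and the next two read GT.  Acceptor (3' junction): the two
    bases immediately before ``pos3`` read AG and the base at ``pos3``
    reads G.  Minus-strand genes are evaluated on the reverse complement.
    Returns None for a side whose window runs off the contig edge.
    """
    donor: Optional[bool]
    acceptor: Optional[bool]
    last2 = tx_window(genome, call.chrom5, call.strand5, call.pos5, -1, 1)
    next2 = tx_window(genome, call.chrom5, call.strand5, call.pos5, 1, 3)
    if len(last2) < 2 or len(next2) < 2:
        donor = None
    else:
        donor = last2 == "AG" and next2 == "GT"
    before2 = tx_window(genome, call.chrom3, call.strand3, call.pos3, -2, 0)
    at1 = tx_window(genome, call.chrom3, call.strand3, call.pos3, 0, 1)
    if len(before2) < 2 or len(at1) < 1:
        acceptor = None
    else:
        acceptor = before2 == "AG" and at1 == "G"
    return donor, acceptor


def _pick_transcript(gene: GeneModel, pos: int, side: str,
                     ) -> Optional[TranscriptModel]:
    """Transcript whose exon boundary matches the breakpoint; longest on ties.

    Falls back to transcripts merely containing the position exonically when
    no boundary matches; None if the position is exonic in no transcript.
    """
    boundary_matches: list[TranscriptModel] = []
    exonic: list[TranscriptModel] = []
    for tx in gene.transcripts:
        if not tx.contains_exonic(pos):
            continue
        exonic.append(tx)
        single = GeneModel(gene.gene_id, gene.symbol, gene.chrom, gene.strand,
                           [tx])
        if boundary_role(single, pos, side) == "exon_end":
            boundary_matches.append(tx)
    pool = boundary_matches or exonic
    if not pool:
        return None
    return max(pool, key=lambda tx: (tx.spliced_length, tx.transcript_id))


def isoform_name(call: ChimeraCall, annotation: GenomeAnnotation,
                 ) -> Optional[str]:
    """eNeM isoform name, e.g. ``e14e2``; None for intronic breakpoints."""
    gene5 = _require_gene(annotation, call.gene5)
    gene3 = _require_gene(annotation, call.gene3)
    tx5 = _pick_transcript(gene5, call.pos5, "donor")
    tx3 = _pick_transcript(gene3, call.pos3, "acceptor")
    if tx5 is None or tx3 is None:
        return None
    return (f"e{exon_index_of(tx5, call.pos5)}"
            f"e{exon_index_of(tx3, call.pos3)}")


def classify_call(call: ChimeraCall, annotation: GenomeAnnotation,
                  genome: Optional[Mapping[str, str]] = None,
                  cfg: PairClassConfig = DEFAULT_PAIR_CONFIG,
                  tolerance: int = 0) -> ChimeraLabels:
    """Run every classifier on one call; motifs only when a genome is given."""
    donor = acceptor = None
    if genome is not None:
        donor, acceptor = splice_motifs(call, genome)
    return ChimeraLabels(
        junction_class=classify_junction(call, annotation, tolerance),
        pair_class=classify_pair(call, annotation, cfg),
        frame_class=predict_frame(call, annotation),
        donor_motif=donor,
        acceptor_motif=acceptor,
        isoform=isoform_name(call, annotation),
    )
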