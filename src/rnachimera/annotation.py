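"""Gene-model queries used by junction classification and peptide prediction.

All genomic intervals stored here are 0-based half-open on the forward
strand of the reference.  Public query functions accept and return 1-based
genomic coordinates (the convention of caller output and GTF), so callers of
this module never handle the internal convention directly.

Transcript orientation: "5'->3' in transcript orientation" means ascending
genomic coordinates for plus-strand transcripts and descending for minus.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "TranscriptModel",
    "GeneModel",
    "GenomeAnnotation",
    "boundary_role",
    "mrna_to_genomic",
    "genomic_to_mrna",
    "cds_phase",
    "utr3_length",
    "exon_index_of",
    "BoundaryRole",
]

Interval = tuple[int, int]  # 0-based half-open
BoundaryRole = Literal["exon_end", "exon_middle", "outside"]
Side = Literal["donor", "acceptor"]

NONCODING = "noncoding"


def _check_intervals(ivs: Iterable[Interval], what: str) -> list[Interval]:
    ivs = sorted(ivs)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{what} intervals overlap: {(s1, e1)} and {(s2, e2)}")
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty {what} interval {(s, e)}")
    return ivs


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, optional CDS.

    ``exons`` and ``cds`` are stored sorted by genomic start regardless of
    strand; use :meth:`exons_tx_order` for transcript orientation.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = _check_intervals(self.exons, "exon")
        self.cds = _check_intervals(self.cds, "CDS")
        exon_cover = set()
        for s, e in self.exons:
            exon_cover.update(range(s, e))
        for s, e in self.cds:
            if not set(range(s, e)) <= exon_cover:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS {(s, e)} not "
                    f"contained in exons"
                )

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_tx_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def cds_tx_order(self) -> list[Interval]:
        return self.cds if self.strand == "+" else self.cds[::-1]

    def contains_exonic(self, pos: int) -> bool:
        """True if 1-based ``pos`` falls within an exon of this transcript."""
        p = pos - 1
        return any(s <= p < e for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            if tx.chrom != self.chrom or tx.strand != self.strand:
                raise ValueError(
                    f"transcript {tx.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chromosome/strand"
                )

    @property
    def span(self) -> Interval:
        starts = [tx.span[0] for tx in self.transcripts]
        ends = [tx.span[1] for tx in self.transcripts]
        return (min(starts), max(ends))

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [tx for tx in self.transcripts if tx.coding]


class GenomeAnnotation:
    """Gene -> transcript -> exon/CDS model with indexed lookups."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        self._by_symbol: dict[str, GeneModel] = {}
        self._tx: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._by_id[g.gene_id] = g
            self._by_symbol.setdefault(g.symbol, g)
            for tx in g.transcripts:
                self._tx[tx.transcript_id] = tx
            s, e = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def gene(self, name: str) -> Optional[GeneModel]:
        """Look up by gene_id first, then by symbol."""
        return self._by_id.get(name) or self._by_symbol.get(name)

    def transcript(self, transcript_id: str) -> Optional[TranscriptModel]:
        return self._tx.get(transcript_id)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span intersects [start, end) (0-based half-open)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda g: g.span)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted((g for g in self.genes if g.chrom == chrom),
                      key=lambda g: g.span)


def _donor_end(strand: str, exon: Interval) -> int:
    """1-based genomic coordinate of the transcript-orientation 3'-most base."""
    s, e = exon
    return e if strand == "+" else s + 1


def _acceptor_end(strand: str, exon: Interval) -> int:
    """1-based genomic coordinate of the transcript-orientation 5'-most base."""
    s, e = exon
    return s + 1 if strand == "+" else e


def boundary_role(gene: GeneModel, genomic_pos: int, side: Side,
                  tolerance: int = 0) -> BoundaryRole:
    """Classify a breakpoint against the exon structure of a gene.

    On the donor side the qualifying end of an exon is its 3'-most base in
    transcript orientation; on the acceptor side, its 5'-most base.  A
    position matching a qualifying end of any exon of any transcript is
    ``exon_end`` (end dominates middle); a position inside some exon but not
    a qualifying end is ``exon_middle``; anything else is ``outside``.

    ``tolerance`` widens end matching to +/- that many bases (default exact).
    """
    if side not in ("donor", "acceptor"):
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")
    end_of = _donor_end if side == "donor" else _acceptor_end
    inside = False
    for tx in gene.transcripts:
        for exon in tx.exons:
            if abs(genomic_pos - end_of(gene.strand, exon)) <= tolerance:
                return "exon_end"
            if exon[0] + 1 <= genomic_pos <= exon[1]:
                inside = True
    return "exon_middle" if inside else "outside"


def mrna_to_genomic(tx: TranscriptModel, mrna_pos: int) -> int:
    """Map a 1-based position in the spliced mRNA to a 1-based genomic one."""
    if not 1 <= mrna_pos <= tx.spliced_length:
        raise ValueError(
            f"mRNA position {mrna_pos} outside transcript "
            f"{tx.transcript_id} (spliced length {tx.spliced_length})"
        )
    offset = mrna_pos - 1
    for s, e in tx.exons_tx_order():
        length = e - s
        if offset < length:
            if tx.strand == "+":
                return s + offset + 1
            return e - offset
        offset -= length
    raise AssertionError("unreachable: exon walk exhausted")


def genomic_to_mrna(tx: TranscriptModel, genomic_pos: int) -> int:
    """Inverse of :func:`mrna_to_genomic`; requires an exonic position."""
    p = genomic_pos - 1
    offset = 0
    for s, e in tx.exons_tx_order():
        if s <= p < e:
            within = (p - s) if tx.strand == "+" else (e - 1 - p)
            return offset + within + 1
        offset += e - s
    raise ValueError(
        f"genomic position {genomic_pos} is not exonic in transcript "
        f"{tx.transcript_id}"
    )


def cds_phase(tx: TranscriptModel, genomic_pos: int):
    """Reading-frame phase (0|1|2) of a genomic base, or ``"noncoding"``.

    Phase is the 0-based offset of the base within the spliced CDS, mod 3.
    UTR and intronic positions of a coding transcript, and any position of a
    noncoding transcript, return ``"noncoding"``.
    """
    span = tx.span
    if not span[0] + 1 <= genomic_pos <= span[1]:
        raise ValueError(
            f"position {genomic_pos} outside transcript {tx.transcript_id}"
        )
    if not tx.coding:
        return NONCODING
    p = genomic_pos - 1
    offset = 0
    for s, e in tx.cds_tx_order():
        if s <= p < e:
            within = (p - s) if tx.strand == "+" else (e - 1 - p)
            return (offset + within) % 3
        offset += e - s
    return NONCODING


def utr3_length(tx: TranscriptModel) -> Optional[int]:
    """Spliced length downstream of the annotated CDS end; None if noncoding."""
    if not tx.coding:
        return None
    last_cds = tx.cds_tx_order()[-1]
    last_base = _donor_end(tx.strand, last_cds)  # 3'-most CDS base, 1-based
    return tx.spliced_length - genomic_to_mrna(tx, last_base)


def gene_utr3_length(gene: GeneModel) -> Optional[int]:
    """Gene-level 3'UTR length: maximum over coding transcripts."""
    lengths = [utr3_length(tx) for tx in gene.coding_transcripts()]
    lengths = [x for x in lengths if x is not None]
    return max(lengths) if lengths else None


def exon_index_of(tx: TranscriptModel, genomic_pos: int) -> int:
    """1-based ordinal (transcript orientation) of the exon containing a base."""
    p = genomic_pos - 1
    for i, (s, e) in enumerate(tx.exons_tx_order(), start=1):
        if s <= p < e:
            return i
    raise ValueError(
        f"position {genomic_pos} is intronic or outside transcript "
        f"{tx.transcript_id}"
    )
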