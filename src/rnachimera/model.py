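"""Core domain types shared across the pipeline.

Conventions
-----------
* Breakpoints are stored 1-based, as emitted by fusion callers: ``pos5`` is
  the genomic coordinate of the last base of the 5' segment and ``pos3`` the
  genomic coordinate of the first base of the 3' segment.
* Internal genomic intervals (in :mod:`rnachimera.annotation`) are 0-based
  half-open; the adapters in :mod:`rnachimera.io` convert at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Optional

__all__ = [
    "ChimeraKey",
    "ChimeraCall",
    "ChimeraLabels",
    "UniqueChimera",
    "FilterReport",
    "FusionDbRecord",
    "PsmRecord",
    "JunctionSequence",
    "ChimericPeptide",
]

STRANDS = ("+", "-")

JUNCTION_CLASSES = ("EE", "EM", "ME", "MM")
PAIR_CLASSES = ("read_through", "intra_other", "inter_chromosomal")
FRAME_CLASSES = ("in_frame", "frame_shift", "na")


class ChimeraKey(NamedTuple):
    """Junction-resolution identity of a chimera (isoform level)."""

    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str

    def __str__(self) -> str:
        return (
            f"{self.gene5}>{self.gene3}"
            f"@{self.chrom5}:{self.pos5}:{self.strand5}"
            f"~{self.chrom3}:{self.pos3}:{self.strand3}"
        )

    @classmethod
    def parse(cls, text: str) -> "ChimeraKey":
        genes, _, loc = text.partition("@")
        gene5, _, gene3 = genes.partition(">")
        side5, _, side3 = loc.partition("~")
        c5, p5, s5 = side5.rsplit(":", 2)
        c3, p3, s3 = side3.rsplit(":", 2)
        return cls(gene5, gene3, c5, int(p5), s5, c3, int(p3), s3)

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class ChimeraCall:
    """One predicted chimera in one sample, as read from a caller table."""

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    junction_seq: str
    score: float
    chimera_expr: float
    gene5_expr: float
    gene3_expr: float
    tissue: str = ""
    missing_breakpoint: bool = False

    def __post_init__(self) -> None:
        if not self.missing_breakpoint:
            if self.pos5 < 1 or self.pos3 < 1:
                raise ValueError(
                    f"breakpoints must be positive 1-based coordinates, "
                    f"got pos5={self.pos5}, pos3={self.pos3}"
                )
            if self.strand5 not in STRANDS or self.strand3 not in STRANDS:
                raise ValueError(
                    f"strands must be '+' or '-', got "
                    f"{self.strand5!r}/{self.strand3!r}"
                )
        for name in ("chimera_expr", "gene5_expr", "gene3_expr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def key(self) -> ChimeraKey:
        return ChimeraKey(
            self.gene5, self.gene3,
            self.chrom5, self.pos5, self.strand5,
            self.chrom3, self.pos3, self.strand3,
        )

    def with_tissue(self, tissue: str) -> "ChimeraCall":
        return replace(self, tissue=tissue)


@dataclass
class ChimeraLabels:
    """One label per classifier for a single chimera key."""

    junction_class: Optional[str] = None
    pair_class: Optional[str] = None
    frame_class: Optional[str] = None
    donor_motif: Optional[bool] = None
    acceptor_motif: Optional[bool] = None
    isoform: Optional[str] = None

    def __post_init__(self) -> None:
        if self.junction_class is not None and self.junction_class not in JUNCTION_CLASSES:
            raise ValueError(f"unknown junction class {self.junction_class!r}")
        if self.pair_class is not None and self.pair_class not in PAIR_CLASSES:
            raise ValueError(f"unknown pair class {self.pair_class!r}")
        if self.frame_class is not None and self.frame_class not in FRAME_CLASSES:
            raise ValueError(f"unknown frame class {self.frame_class!r}")


@dataclass
class UniqueChimera:
    """A deduplicated chimera with its cross-sample support.

    ``frequency`` counts distinct supporting samples (not reads, not donors);
    ``tissue_counts`` maps tissue name to the number of distinct samples of
    that tissue supporting the chimera.
    """

    key: ChimeraKey
    sample_ids: frozenset[str]
    tissue_counts: dict[str, int]
    labels: ChimeraLabels = field(default_factory=ChimeraLabels)
    max_chimera_expr: float = 0.0
    max_ratio5: float = 0.0
    max_ratio3: float = 0.0

    @property
    def frequency(self) -> int:
        return len(self.sample_ids)

    @property
    def tissues(self) -> frozenset[str]:
        return frozenset(self.tissue_counts)


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage: kept + removed == input, always."""

    stage: str
    n_input: int
    n_removed: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input < 0 or self.n_removed < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_removed > self.n_input:
            raise ValueError(
                f"stage {self.stage!r}: removed {self.n_removed} exceeds "
                f"input {self.n_input}"
            )
        if self.reasons and sum(self.reasons.values()) != self.n_removed:
            raise ValueError(
                f"stage {self.stage!r}: removal reasons do not sum to "
                f"the removed count"
            )

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "input": self.n_input,
            "kept": self.n_kept,
            "removed": self.n_removed,
            "reasons": dict(self.reasons),
        }


@dataclass
class FusionDbRecord:
    """One entry from a cancer fusion database.

    mRNA breakpoints, when present, are 1-based positions within the spliced
    mRNA of the named transcript (the convention used by databases that
    record junctions against the parental transcript rather than the genome).
    """

    source: str
    gene5: str
    gene3: str
    tx5: Optional[str] = None
    tx3: Optional[str] = None
    mrna_pos5: Optional[int] = None
    mrna_pos3: Optional[int] = None

    @property
    def has_breakpoint(self) -> bool:
        return (
            self.tx5 is not None and self.tx3 is not None
            and self.mrna_pos5 is not None and self.mrna_pos3 is not None
        )

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class PsmRecord:
    """A peptide-spectrum match with its FDR-controlled confidence."""

    peptide: str
    q_value: float
    spectrum_id: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")


@dataclass
class JunctionSequence:
    """Assembled chimeric nucleotide sequence around a junction.

    ``junction_offset`` is the 0-based index of the first base contributed by
    the 3' gene, i.e. the length actually obtained for the upstream flank
    (it may be shorter than the requested flank near contig edges).
    """

    key: ChimeraKey
    sequence: str
    junction_offset: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.junction_offset < len(self.sequence):
            raise ValueError(
                "junction_offset must fall strictly inside the sequence"
            )


@dataclass
class ChimericPeptide:
    """A junction-spanning tryptic fragment from one translation frame."""

    key: ChimeraKey
    frame: int
    sequence: str
    left_len: int
    right_len: int

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if "*" in self.sequence:
            raise ValueError("chimeric peptide contains a stop symbol")
        if self.left_len < 0 or self.right_len < 0:
            raise ValueError("side lengths must be nonnegative")

    def fasta_header(self) -> str:
        return (
            f"chim|{self.key}|frame={self.frame}"
            f"|left={self.left_len}|right={self.right_len}"
        )

    @staticmethod
    def parse_header(header: str) -> tuple[ChimeraKey, int, int, int]:
        """Invert :meth:`fasta_header` (leading ``>`` optional)."""
        text = header.lstrip(">")
        fields = text.split("|")
        if len(fields) != 5 or fields[0] != "chim":
            raise ValueError(f"not a chimeric-peptide header: {header!r}")
        key = ChimeraKey.parse(fields[1])
        frame = int(fields[2].removeprefix("frame="))
        left = int(fields[3].removeprefix("left="))
        right = int(fields[4].removeprefix("right="))
        return key, frame, left, right
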