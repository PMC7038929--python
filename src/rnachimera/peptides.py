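"""Chimeric-peptide prediction.

From each chimera junction: assemble flanking nucleotide sequence (default
200 bp each side of the breakpoint), translate in three frames, digest in
silico with trypsin, and retain per frame the junction-spanning tryptic
fragment with at least two residues on each side of the junction.  The
resulting peptides form a search database (together with a reference
proteome); PSM tables from a spectral search engine are then filtered at
q < 0.05 and screened against the reference proteome by exact substring
matching of each junction half.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from Bio.Seq import Seq

from .annotation import GenomeAnnotation, TranscriptModel, genomic_to_mrna
from .model import ChimeraCall, ChimeraKey, ChimericPeptide, JunctionSequence, PsmRecord
from .sequence import downstream_flank, revcomp, upstream_flank

logger = logging.getLogger(__name__)

__all__ = [
    "build_junction_sequence",
    "FrameTranslation",
    "three_frame_translate",
    "tryptic_digest",
    "peptides_from_junction",
    "junction_peptides",
    "write_peptide_db",
    "read_peptide_db",
    "filter_psms",
    "side_match_screen",
]

VALID_BASES = set("ACGTN")


def spliced_sequence(genome: Mapping[str, str], tx: TranscriptModel) -> str:
    """Spliced (mRNA-sense) sequence of a transcript from the genome."""
    chunks = []
    seq = genome[tx.chrom]
    for s, e in tx.exons_tx_order():
        exon = seq[s:e]
        chunks.append(exon if tx.strand == "+" else revcomp(exon))
    return "".join(chunks).upper()


def _spliced_flanks(call: ChimeraCall, genome: Mapping[str, str],
                    annotation: GenomeAnnotation, flank: int,
                    ) -> Optional[tuple[str, str]]:
    from .classify import _pick_transcript, _require_gene

    gene5 = _require_gene(annotation, call.gene5)
    gene3 = _require_gene(annotation, call.gene3)
    tx5 = _pick_transcript(gene5, call.pos5, "donor")
    tx3 = _pick_transcript(gene3, call.pos3, "acceptor")
    if tx5 is None or tx3 is None:
        return None
    m5 = genomic_to_mrna(tx5, call.pos5)
    m3 = genomic_to_mrna(tx3, call.pos3)
    seq5 = spliced_sequence(genome, tx5)
    seq3 = spliced_sequence(genome, tx3)
    return seq5[max(m5 - flank, 0):m5], seq3[m3 - 1:m3 - 1 + flank]


def build_junction_sequence(call: ChimeraCall, genome: Mapping[str, str],
                            annotation: Optional[GenomeAnnotation] = None,
                            flank: int = 200, mode: str = "genomic",
                            ) -> JunctionSequence:
    """Assemble the chimeric nucleotide sequence around the junction.

    ``mode="genomic"`` (default) takes unspliced windows: ``flank`` bases
    ending at pos5 in the 5' gene's transcript orientation plus ``flank``
    bases starting at pos3 in the 3' gene's orientation.  ``mode="spliced"``
    walks exons of the best-matching transcripts instead, falling back to
    genomic windows when a breakpoint is not exonic.  Windows are truncated
    (never padded) at contig edges; ``junction_offset`` records the actual
    upstream length.
    """
    if mode not in ("genomic", "spliced"):
        raise ValueError(f"mode must be 'genomic' or 'spliced', got {mode!r}")
    upstream = downstream = None
    if mode == "spliced":
        if annotation is None:
            raise ValueError("spliced mode requires an annotation")
        flanks = _spliced_flanks(call, genome, annotation, flank)
        if flanks is not None:
            upstream, downstream = flanks
    if upstream is None:
        upstream = upstream_flank(genome, call.chrom5, call.strand5,
                                  call.pos5, flank)
        downstream = downstream_flank(genome, call.chrom3, call.strand3,
                                      call.pos3, flank)
    truncated = len(upstream) < flank or len(downstream) < flank
    return JunctionSequence(
        key=call.key,
        sequence=(upstream + downstream).upper(),
        junction_offset=len(upstream),
        truncated=truncated,
    )


@dataclass
class FrameTranslation:
    """One reading frame of a junction sequence.

    ``residues`` is the full translation including ``*`` stops; residue
    ``i`` is encoded by sequence bases ``[frame + 3i, frame + 3i + 3)``.
    ``junction_residue`` is the index of the residue whose codon straddles
    the junction boundary, or None when the boundary falls between codons.
    """

    frame: int
    residues: str
    junction_offset: int

    def codon_start(self, i: int) -> int:
        return self.frame + 3 * i

    @property
    def junction_residue(self) -> Optional[int]:
        b = self.junction_offset - self.frame
        if b <= 0 or b >= 3 * len(self.residues):
            return None
        return b // 3 if b % 3 else None

    @property
    def n_left_residues(self) -> int:
        """Residues whose codons lie entirely 5' of the junction boundary."""
        return max((self.junction_offset - self.frame) // 3, 0)


def three_frame_translate(js: JunctionSequence) -> list[FrameTranslation]:
    """Translate the chimeric sequence in frames 0, 1 and 2.

    Codons containing N translate to X; other non-ACGTN characters are
    rejected.  Stops are kept as ``*`` so callers can segment on them.
    """
    seq = js.sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"junction sequence contains invalid characters "
                         f"{sorted(bad)}")
    frames = []
    for f in range(3):
        sub = seq[f:]
        sub = sub[:len(sub) - len(sub) % 3]
        residues = ""
        for i in range(0, len(sub), 3):
            codon = sub[i:i + 3]
            residues += "X" if "N" in codon else str(Seq(codon).translate())
        frames.append(FrameTranslation(frame=f, residues=residues,
                                       junction_offset=js.junction_offset))
    return frames


def tryptic_digest(peptide: str, missed_cleavages: int = 0,
                   proline_rule: bool = True,
                   ) -> list[tuple[int, int, str]]:
    """In-silico trypsin digest: cleave C-terminal to K/R, not before P.

    Returns ``(start, end, fragment)`` with 0-based residue coordinates.
    With zero missed cleavages the fragments partition the input; with
    ``missed_cleavages`` up to 2, products spanning that many internal
    sites are appended as well.
    """
    if not 0 <= missed_cleavages <= 2:
        raise ValueError("missed_cleavages must be 0, 1 or 2")
    if not peptide:
        return []
    if "*" in peptide:
        raise ValueError("digest input contains a stop symbol")
    cuts = [0]
    for i, residue in enumerate(peptide[:-1]):
        if residue in "KR" and not (proline_rule and peptide[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(peptide))
    fragments = []
    for span in range(1, missed_cleavages + 2):
        for i in range(len(cuts) - span):
            s, e = cuts[i], cuts[i + span]
            fragments.append((s, e, peptide[s:e]))
    fragments.sort(key=lambda f: (f[0], f[1]))
    return fragments


def _frame_peptide(frame: FrameTranslation, min_side: int,
                   missed_cleavages: int, proline_rule: bool,
                   ) -> Optional[tuple[str, int, int]]:
    """Junction-spanning tryptic fragment of one frame, or None."""
    residues = frame.residues
    boundary = frame.n_left_residues  # residue index where the 3' side starts
    straddle = frame.junction_residue
    # locate the stop-free segment containing the junction
    seg_start = 0
    for i0, i1 in _segments(residues):
        if straddle is not None:
            covers = i0 <= straddle < i1
        else:
            covers = i0 < boundary < i1
        if covers:
            segment = residues[i0:i1]
            seg_start = i0
            break
    else:
        return None
    candidates = []
    for s, e, frag in tryptic_digest(segment, missed_cleavages, proline_rule):
        abs_s, abs_e = seg_start + s, seg_start + e
        left = max(min(abs_e, boundary) - abs_s, 0)
        if straddle is not None:
            right_start = straddle + 1
        else:
            right_start = boundary
        right = max(abs_e - max(abs_s, right_start), 0)
        if straddle is not None and not abs_s <= straddle < abs_e:
            continue
        if left >= min_side and right >= min_side:
            candidates.append((abs_e - abs_s, abs_s, frag, left, right))
    if not candidates:
        return None
    _, _, frag, left, right = min(candidates)
    return frag, left, right


def _segments(residues: str) -> list[tuple[int, int]]:
    """Maximal stop-free runs as (start, end) residue index pairs."""
    segments = []
    start = None
    for i, r in enumerate(residues):
        if r == "*":
            if start is not None:
                segments.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        segments.append((start, len(residues)))
    return segments


def peptides_from_junction(js: JunctionSequence, min_side: int = 2,
                           missed_cleavages: int = 0,
                           proline_rule: bool = True,
                           ) -> list[ChimericPeptide]:
    """Junction-spanning tryptic peptides of an assembled junction sequence.

    At most one peptide per translation frame: the tryptic fragment within
    the stop-free segment containing the junction that spans the junction
    with at least ``min_side`` residues strictly on each side.  Frames
    interrupted by a stop at the junction, or whose spanning fragment is
    too short on either side, contribute nothing.
    """
    peptides = []
    for frame in three_frame_translate(js):
        hit = _frame_peptide(frame, min_side, missed_cleavages, proline_rule)
        if hit is None:
            continue
        seq, left, right = hit
        peptides.append(ChimericPeptide(
            key=js.key, frame=frame.frame, sequence=seq,
            left_len=left, right_len=right,
        ))
    return peptides


def junction_peptides(call: ChimeraCall, genome: Mapping[str, str],
                      annotation: Optional[GenomeAnnotation] = None,
                      flank: int = 200, min_side: int = 2,
                      mode: str = "genomic", missed_cleavages: int = 0,
                      proline_rule: bool = True) -> list[ChimericPeptide]:
    """Predict junction-spanning tryptic peptides for one chimera.

    Assembles the junction sequence (see :func:`build_junction_sequence`)
    and applies :func:`peptides_from_junction`.
    """
    js = build_junction_sequence(call, genome, annotation, flank, mode)
    return peptides_from_junction(js, min_side, missed_cleavages,
                                  proline_rule)


# ---------------------------------------------------------------------------
# peptide database and PSM filtering
# ---------------------------------------------------------------------------

def write_peptide_db(peptides: Sequence[ChimericPeptide],
                     reference_proteins: Mapping[str, str], path) -> None:
    """FASTA search database: chimeric peptides then reference proteins.

    Chimeric headers follow ``>chim|<key>|frame=<f>|left=<n>|right=<m>``;
    record order is deterministic (sorted keys).
    """
    if not peptides:
        logger.warning("writing reference-only peptide database "
                       "(no chimeric peptides)")
    with open(path, "w") as fh:
        for pep in sorted(peptides,
                          key=lambda p: (str(p.key), p.frame)):
            fh.write(f">{pep.fasta_header()}\n{pep.sequence}\n")
        for name in sorted(reference_proteins):
            fh.write(f">{name}\n{reference_proteins[name]}\n")


def read_peptide_db(path) -> tuple[list[ChimericPeptide], dict[str, str]]:
    """Invert :func:`write_peptide_db`."""
    from .io import read_fasta

    chimeric: list[ChimericPeptide] = []
    reference: dict[str, str] = {}
    # re-read with full headers: read_fasta cuts at whitespace, which is
    # fine because our headers contain none
    for name, seq in read_fasta(path).items():
        if name.startswith("chim|"):
            key, frame, left, right = ChimericPeptide.parse_header(name)
            chimeric.append(ChimericPeptide(key, frame, seq, left, right))
        else:
            reference[name] = seq
    return chimeric, reference


def filter_psms(psms: Sequence[PsmRecord],
                peptide_db: Union[Sequence[ChimericPeptide], str],
                q_max: float = 0.05, min_side: int = 2,
                ) -> tuple[list[PsmRecord], set[str], dict]:
    """Accept chimeric PSMs at q < ``q_max`` with both junction sides long
    enough; returns (accepted PSMs, unique peptide sequences, summary).

    PSM peptides are matched to database entries by exact sequence; PSMs
    matching no chimeric entry count as non-chimeric and are excluded.
    The q threshold is strict (q equal to the cutoff is rejected).
    """
    if isinstance(peptide_db, (str, bytes)) or hasattr(peptide_db, "__fspath__"):
        peptide_db, _ = read_peptide_db(peptide_db)
    eligible: dict[str, list[ChimericPeptide]] = {}
    for pep in peptide_db:
        if pep.left_len >= min_side and pep.right_len >= min_side:
            eligible.setdefault(pep.sequence, []).append(pep)
    accepted = []
    reasons = {"q_too_high": 0, "non_chimeric": 0, "side_too_short": 0}
    all_chimeric_seqs = {p.sequence for p in peptide_db}
    for psm in psms:
        if psm.peptide not in all_chimeric_seqs:
            reasons["non_chimeric"] += 1
        elif not psm.q_value < q_max:
            reasons["q_too_high"] += 1
        elif psm.peptide not in eligible:
            reasons["side_too_short"] += 1
        else:
            accepted.append(psm)
    unique_peptides = {p.peptide for p in accepted}
    summary = {
        "n_psms_in": len(psms),
        "n_psms_accepted": len(accepted),
        "n_unique_peptides": len(unique_peptides),
        "rejected": reasons,
    }
    return accepted, unique_peptides, summary


def side_match_screen(peptides: Sequence[ChimericPeptide],
                      reference_proteome: Mapping[str, str],
                      ) -> dict[str, str]:
    """Screen peptide halves against a reference proteome.

    Each peptide is split at the junction boundary (a codon straddling the
    boundary belongs to neither half) and each half searched as an exact
    substring of any reference protein.  Labels: ``both_sides`` when both
    halves hit, ``one_side`` for exactly one, ``no_hit`` for none.  Peptides
    labelled no_hit or one_side are the candidates unlikely to derive from
    a regular transcript.
    """
    proteins = list(reference_proteome.values())

    def hits(fragment: str) -> bool:
        return bool(fragment) and any(fragment in p for p in proteins)

    labels: dict[str, str] = {}
    for pep in peptides:
        left = pep.sequence[:pep.left_len]
        right = pep.sequence[len(pep.sequence) - pep.right_len:]
        n = sum((hits(left), hits(right)))
        labels[pep.sequence] = ("both_sides", "one_side", "no_hit")[2 - n]
    return labels
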