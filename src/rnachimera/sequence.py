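"""Strand-aware genomic sequence windows.

A "transcript-orientation window" is addressed relative to a 1-based
anchor position: offset 0 is the anchor base itself, positive offsets move
downstream in transcript orientation (rightward for plus-strand genes,
leftward for minus-strand ones) and negative offsets move upstream.  Minus
strand windows are returned reverse-complemented, so callers always see
sequence as the transcript reads it.
"""
from __future__ import annotations

from typing import Mapping

from Bio.Seq import reverse_complement

__all__ = ["revcomp", "tx_window", "upstream_flank", "downstream_flank"]


def revcomp(seq: str) -> str:
    return str(reverse_complement(seq))


def tx_window(genome: Mapping[str, str], chrom: str, strand: str,
              pos: int, rel_start: int, rel_end: int) -> str:
    """Bases at transcript-orientation offsets [rel_start, rel_end) of ``pos``.

    The window is truncated (not padded) at contig edges; callers that need
    the full width should check the returned length.
    """
    if chrom not in genome:
        raise KeyError(f"unknown contig {chrom!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside contig {chrom} "
                         f"(length {len(seq)})")
    if rel_start >= rel_end:
        return ""
    p = pos - 1  # 0-based anchor
    if strand == "+":
        lo, hi = p + rel_start, p + rel_end
        return seq[max(lo, 0):min(hi, len(seq))]
    # minus strand: offset k maps to genomic index p - k
    lo, hi = p - (rel_end - 1), p - rel_start + 1
    return revcomp(seq[max(lo, 0):min(hi, len(seq))])


def upstream_flank(genome: Mapping[str, str], chrom: str, strand: str,
                   pos: int, n: int) -> str:
    """``n`` transcript-orientation bases ending at (and including) ``pos``."""
    return tx_window(genome, chrom, strand, pos, -(n - 1), 1)


def downstream_flank(genome: Mapping[str, str], chrom: str, strand: str,
                     pos: int, n: int) -> str:
    """``n`` transcript-orientation bases starting at (and including) ``pos``."""
    return tx_window(genome, chrom, strand, pos, 0, n)
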