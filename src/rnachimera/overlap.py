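"""Matching chimera sets against cancer fusion databases and using a
normal-tissue baseline to filter cancer call sets.

Gene-pair matching is ordered by default (the 5'/3' orientation of a fusion
is biologically meaningful); databases with unordered conventions can be
matched with ``ordered=False``.  Databases that record junctions against
the parental mRNA (COSMIC-style) are additionally matched at exact
genomic-breakpoint resolution after mRNA -> genomic conversion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import GenomeAnnotation, mrna_to_genomic
from .model import ChimeraKey, FusionDbRecord, UniqueChimera

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "match_gene_pairs",
    "match_breakpoints",
    "OverlapReport",
    "normal_filter",
    "three_way_partition",
    "percent",
]

GenePair = tuple[str, str]


def percent(numerator: int, denominator: int) -> float:
    """Percentage at one decimal, round-half-even (banker's rounding)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def normalize_symbol(symbol: str,
                     aliases: Optional[Mapping[str, str]] = None) -> str:
    """Uppercase a gene symbol and apply an optional alias table."""
    s = symbol.strip().upper()
    if aliases:
        s = aliases.get(s, s)
    return s


def _norm_pair(pair: GenePair, aliases) -> GenePair:
    return (normalize_symbol(pair[0], aliases),
            normalize_symbol(pair[1], aliases))


def match_gene_pairs(query: Iterable[GenePair],
                     db: Sequence[FusionDbRecord],
                     ordered: bool = True,
                     aliases: Optional[Mapping[str, str]] = None,
                     ) -> dict[GenePair, list[str]]:
    """Match query gene pairs against database records.

    Returns {query pair: sorted list of matching db sources}.  In ordered
    mode (default) (A,B) only matches a db record with gene5=A, gene3=B;
    unordered mode also accepts the swapped orientation.
    """
    index: dict[GenePair, set[str]] = {}
    for rec in db:
        pair = _norm_pair(rec.gene_pair, aliases)
        index.setdefault(pair, set()).add(rec.source)
        if not ordered:
            index.setdefault((pair[1], pair[0]), set()).add(rec.source)
    matches: dict[GenePair, list[str]] = {}
    for pair in query:
        sources = index.get(_norm_pair(pair, aliases))
        if sources:
            matches[pair] = sorted(sources)
    return matches


def match_breakpoints(query: Sequence[UniqueChimera],
                      db: Sequence[FusionDbRecord],
                      annotation: GenomeAnnotation,
                      aliases: Optional[Mapping[str, str]] = None,
                      ) -> tuple[list[tuple[ChimeraKey, FusionDbRecord]], int]:
    """Exact-coordinate matches between chimeras and breakpoint-bearing
    database records.

    Database mRNA breakpoints are converted to genomic coordinates through
    the named transcripts; a record matches when both converted coordinates
    equal the chimera key's breakpoints (and the gene pair agrees).  Records
    whose transcripts are absent from the annotation are skipped and
    counted.  Exact matches are by construction a subset of gene-pair
    matches.
    """
    by_pair: dict[GenePair, list[UniqueChimera]] = {}
    for u in query:
        by_pair.setdefault(_norm_pair(u.key.gene_pair, aliases), []).append(u)
    matches: list[tuple[ChimeraKey, FusionDbRecord]] = []
    skipped = 0
    for rec in db:
        if not rec.has_breakpoint:
            continue
        tx5 = annotation.transcript(rec.tx5)
        tx3 = annotation.transcript(rec.tx3)
        if tx5 is None or tx3 is None:
            skipped += 1
            continue
        try:
            g5 = mrna_to_genomic(tx5, rec.mrna_pos5)
            g3 = mrna_to_genomic(tx3, rec.mrna_pos3)
        except ValueError:
            skipped += 1
            continue
        for u in by_pair.get(_norm_pair(rec.gene_pair, aliases), ()):
            if (u.key.chrom5 == tx5.chrom and u.key.pos5 == g5
                    and u.key.chrom3 == tx3.chrom and u.key.pos3 == g3):
                matches.append((u.key, rec))
    if skipped:
        logger.info("match_breakpoints: skipped %d records with transcripts "
                    "absent from the annotation", skipped)
    return matches, skipped


@dataclass
class OverlapReport:
    """Result of filtering a cancer set against a control set."""

    n_cancer: int
    n_eliminated: int
    eliminated_pct: float
    retained: set = field(repr=False, default_factory=set)
    eliminated: set = field(repr=False, default_factory=set)

    def to_dict(self) -> dict:
        return {
            "cancer": self.n_cancer,
            "eliminated": self.n_eliminated,
            "retained": self.n_cancer - self.n_eliminated,
            "eliminated_pct": self.eliminated_pct,
        }


def normal_filter(cancer: set, control: set) -> tuple[set, set, OverlapReport]:
    """Remove from a cancer call set everything present in a normal-tissue
    control set; reports the eliminated fraction.

    Both sets must be at the same resolution (gene pairs by default).
    """
    if not cancer:
        raise ValueError("empty cancer set")
    eliminated = cancer & control
    retained = cancer - control
    report = OverlapReport(
        n_cancer=len(cancer),
        n_eliminated=len(eliminated),
        eliminated_pct=percent(len(eliminated), len(cancer)),
        retained=retained,
        eliminated=eliminated,
    )
    return retained, eliminated, report


def three_way_partition(cancer: set, matched_normal: set, baseline: set,
                        ) -> dict:
    """Partition a cancer set by membership in the matched-normal and
    baseline control sets.

    The four cells (cancer-only; in both controls; matched-normal only;
    baseline only) sum to the cancer set size.  The matched-normal-only
    cell is the fraction a matched control removes that a population
    baseline would not.
    """
    in_matched = cancer & matched_normal
    in_baseline = cancer & baseline
    both = in_matched & in_baseline
    matched_only = in_matched - baseline
    baseline_only = in_baseline - matched_normal
    cancer_only = cancer - matched_normal - baseline
    counts = {
        "cancer_only": len(cancer_only),
        "matched_and_baseline": len(both),
        "matched_normal_only": len(matched_only),
        "baseline_only": len(baseline_only),
    }
    assert sum(counts.values()) == len(cancer)
    pct = {f"{k}_pct": percent(v, len(cancer)) for k, v in counts.items()}
    return {**counts, **pct, "n_cancer": len(cancer)}
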