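"""The staged filtering ladder for chimera call sets.

Stages mirror the post-detection pipeline: prediction-score cutoff,
identity-versus-reference-transcriptome screen, chimera/parent expression
ratio, deduplication to unique chimeras, M/M removal, and global plus
tissue-aware recurrence.  Every stage returns ``(kept, removed, report)``
with ``kept + removed == input`` guaranteed by :class:`FilterReport`.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .io import SampleMetadata
from .model import ChimeraCall, ChimeraKey, FilterReport, UniqueChimera

__all__ = [
    "score_filter",
    "IdentityAligner",
    "identity_filter",
    "expression_ratios",
    "ratio_filter",
    "dedupe",
    "remove_mm",
    "global_recurrence",
    "tissue_threshold",
    "tissue_recurrent",
]


# ---------------------------------------------------------------------------
# score filter
# ---------------------------------------------------------------------------

def score_filter(calls: Sequence[ChimeraCall], min_score: float = 0.6,
                 ) -> tuple[list[ChimeraCall], list[ChimeraCall], FilterReport]:
    """Discard calls with score < ``min_score`` or without breakpoints."""
    kept, removed = [], []
    reasons: Counter = Counter()
    for call in calls:
        if call.missing_breakpoint:
            removed.append(call)
            reasons["missing_breakpoint"] += 1
        elif call.score < min_score:
            removed.append(call)
            reasons["low_score"] += 1
        else:
            kept.append(call)
    report = FilterReport("score", len(calls), len(removed), dict(reasons))
    return kept, removed, report


# ---------------------------------------------------------------------------
# identity filter
# ---------------------------------------------------------------------------

class IdentityAligner:
    """Detects junction sequences explainable by one reference transcript.

    Exact k-mer seeds (default k=11) locate candidate transcripts and
    diagonals; each seeded window is then aligned locally (match +1,
    mismatch -1, gap -2) and a junction sequence is flagged when some
    single transcript yields an alignment with identity >= ``min_identity``
    (matches / alignment columns) spanning the junction midpoint with at
    least ``min_flank`` aligned query bases on each side.

    The identity requirement is applied both to the alignment as a whole
    and to each side of the junction midpoint separately (per-side
    denominators include gap columns).  The per-side check is what makes
    the screen specific: a genuine chimeric junction
    has one flank matching its parent transcript perfectly, and under local
    alignment that perfect run can subsidize a low-quality gapped extension
    across the junction that still clears the overall cutoff, whereas a
    junction truly explainable by one transcript matches well on both
    sides.
    """

    def __init__(self, reference: Mapping[str, str], k: int = 11,
                 min_identity: float = 0.90, min_flank: int = 10,
                 window_margin: int = 25):
        if not reference:
            raise ValueError("empty reference transcriptome")
        self.reference = {name: seq.upper() for name, seq in reference.items()}
        self.k = k
        self.min_identity = min_identity
        self.min_flank = min_flank
        self.window_margin = window_margin
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i:i + k]].append((name, i))
        self._aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-1,
            open_gap_score=-2, extend_gap_score=-2,
        )

    def _windows(self, query: str) -> Iterable[tuple[str, int, int]]:
        """Candidate (transcript, window_start, window_end) per seed diagonal."""
        seen: set[tuple[str, int]] = set()
        for qpos in range(len(query) - self.k + 1):
            for name, tpos in self._index.get(query[qpos:qpos + self.k], ()):
                diag = (tpos - qpos) // max(self.window_margin, 1)
                if (name, diag) in seen:
                    continue
                seen.add((name, diag))
                start = max(tpos - qpos - self.window_margin, 0)
                end = min(tpos - qpos + len(query) + self.window_margin,
                          len(self.reference[name]))
                yield name, start, end

    def explained_by_reference(self, junction_seq: str) -> bool:
        """True when the junction is explainable by a single transcript."""
        query = junction_seq.upper()
        mid = len(query) // 2
        for name, start, end in self._windows(query):
            window = self.reference[name][start:end]
            alignments = self._aligner.align(window, query)
            if len(alignments) == 0:
                continue
            best = alignments[0]
            counts = best.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            if counts.identities / columns < self.min_identity:
                continue
            aligned = {"L": 0, "R": 0}
            total = {"L": 0, "R": 0}
            matches = {"L": 0, "R": 0}
            qpos = int(best.aligned[1][0][0])
            for tc, qc in zip(best[0], best[1]):
                side = "L" if qpos < mid else "R"
                total[side] += 1
                if tc != "-" and qc != "-":
                    aligned[side] += 1
                    matches[side] += tc == qc
                if qc != "-":
                    qpos += 1
            if any(aligned[s] < self.min_flank for s in "LR"):
                continue
            if all(matches[s] / total[s] >= self.min_identity for s in "LR"):
                return True
        return False


def identity_filter(calls: Sequence[ChimeraCall],
                    reference: Mapping[str, str],
                    min_identity: float = 0.90, min_flank: int = 10,
                    k: int = 11,
                    ) -> tuple[list[ChimeraCall], list[ChimeraCall], FilterReport]:
    """Remove calls whose junction sequence matches one reference transcript."""
    aligner = IdentityAligner(reference, k=k, min_identity=min_identity,
                              min_flank=min_flank)
    kept, removed = [], []
    for call in calls:
        if aligner.explained_by_reference(call.junction_seq):
            removed.append(call)
        else:
            kept.append(call)
    report = FilterReport("identity", len(calls), len(removed),
                          {"reference_match": len(removed)} if removed else {})
    return kept, removed, report


# ---------------------------------------------------------------------------
# expression-ratio filter
# ---------------------------------------------------------------------------

def expression_ratios(call: ChimeraCall) -> tuple[float, float]:
    """(chimera/5'-parent, chimera/3'-parent) expression ratios.

    A zero-expression parent gives +inf when the chimera is expressed and
    0 when it is not (0/0 treated as no evidence of excess).
    """
    def ratio(parent: float) -> float:
        if parent > 0:
            return call.chimera_expr / parent
        return math.inf if call.chimera_expr > 0 else 0.0

    return ratio(call.gene5_expr), ratio(call.gene3_expr)


RATIO_MODES = ("either", "both", "five_prime", "three_prime")


def ratio_filter(calls: Sequence[ChimeraCall], mode: str = "either",
                 ) -> tuple[list[ChimeraCall], list[ChimeraCall], FilterReport]:
    """Remove calls whose chimera/parent expression ratio exceeds 1.

    The boundary is strict: a ratio of exactly 1 is not "exceeded" and the
    call is kept.  ``mode`` selects which parent(s) trigger removal.
    """
    if mode not in RATIO_MODES:
        raise ValueError(f"mode must be one of {RATIO_MODES}, got {mode!r}")
    kept, removed = [], []
    reasons: Counter = Counter()
    for call in calls:
        r5, r3 = expression_ratios(call)
        if mode == "either":
            exceed = r5 > 1 or r3 > 1
        elif mode == "both":
            exceed = r5 > 1 and r3 > 1
        elif mode == "five_prime":
            exceed = r5 > 1
        else:
            exceed = r3 > 1
        if exceed:
            removed.append(call)
            reasons["ratio_exceeds_1"] += 1
        else:
            kept.append(call)
    report = FilterReport("ratio", len(calls), len(removed), dict(reasons))
    return kept, removed, report


# ---------------------------------------------------------------------------
# deduplication and recurrence
# ---------------------------------------------------------------------------

def dedupe(calls: Sequence[ChimeraCall],
           metadata: Optional[SampleMetadata] = None,
           ) -> list[UniqueChimera]:
    """Collapse calls to unique chimeras at junction (isoform) resolution.

    Frequency counts distinct supporting samples.  Tissue is taken from the
    call itself or looked up in ``metadata`` when provided.  Expression
    summaries keep the per-key maxima used by downstream reporting.
    """
    groups: dict[ChimeraKey, list[ChimeraCall]] = defaultdict(list)
    for call in calls:
        groups[call.key].append(call)
    uniques: list[UniqueChimera] = []
    for key in sorted(groups):
        members = groups[key]
        samples: set[str] = set()
        tissue_samples: dict[str, set[str]] = defaultdict(set)
        max_expr = 0.0
        max_r5 = max_r3 = 0.0
        for call in members:
            tissue = call.tissue
            if not tissue and metadata is not None:
                tissue = metadata.tissue_of(call.sample_id)
            if call.sample_id not in samples:
                samples.add(call.sample_id)
                if tissue:
                    tissue_samples[tissue].add(call.sample_id)
            max_expr = max(max_expr, call.chimera_expr)
            r5, r3 = expression_ratios(call)
            max_r5, max_r3 = max(max_r5, r5), max(max_r3, r3)
        uniques.append(UniqueChimera(
            key=key,
            sample_ids=frozenset(samples),
            tissue_counts={t: len(s) for t, s in sorted(tissue_samples.items())},
            max_chimera_expr=max_expr,
            max_ratio5=max_r5,
            max_ratio3=max_r3,
        ))
    return uniques


def remove_mm(uniques: Sequence[UniqueChimera],
              ) -> tuple[list[UniqueChimera], list[UniqueChimera], FilterReport]:
    """Eliminate M/M chimeras (low validation rates; likely artifacts)."""
    kept, removed = [], []
    for u in uniques:
        if u.labels.junction_class is None:
            raise ValueError(f"{u.key}: junction class not assigned")
        (removed if u.labels.junction_class == "MM" else kept).append(u)
    report = FilterReport("non_mm", len(uniques), len(removed),
                          {"mm_junction": len(removed)} if removed else {})
    return kept, removed, report


def global_recurrence(uniques: Sequence[UniqueChimera],
                      min_frequency: int = 5,
                      ) -> tuple[list[UniqueChimera], list[UniqueChimera],
                                 FilterReport]:
    """Keep chimeras detected in at least ``min_frequency`` distinct samples."""
    kept = [u for u in uniques if u.frequency >= min_frequency]
    removed = [u for u in uniques if u.frequency < min_frequency]
    report = FilterReport("recurrent", len(uniques), len(removed),
                          {"low_frequency": len(removed)} if removed else {})
    return kept, removed, report


def tissue_threshold(n_samples: int) -> int:
    """Per-tissue recurrence threshold as a function of tissue sample count.

    2 for tissues of 100 or fewer samples, 3 for 300 or fewer, 5 above 300.
    """
    if n_samples <= 100:
        return 2
    if n_samples <= 300:
        return 3
    return 5


def tissue_recurrent(uniques: Sequence[UniqueChimera],
                     metadata: SampleMetadata,
                     ) -> dict[str, set[ChimeraKey]]:
    """Per-tissue recurrent chimera sets under size-dependent thresholds."""
    counts = metadata.tissue_sample_counts()
    result: dict[str, set[ChimeraKey]] = {t: set() for t in counts}
    for u in uniques:
        for tissue, n in u.tissue_counts.items():
            if tissue not in counts:
                raise ValueError(
                    f"{u.key}: tissue {tissue!r} absent from metadata")
            if n >= tissue_threshold(counts[tissue]):
                result[tissue].add(u.key)
    return result
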