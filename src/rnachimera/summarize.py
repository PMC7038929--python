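"""Descriptive statistics over classified chimera sets.

Covers the figure-level summaries of a chimera landscape study: class
distributions across the three filter stages, canonical splice-motif
percentages per junction class, the sample-frequency histogram, the
relative-expression CDF against both parents, 3'UTR length comparisons
(Mann-Whitney U), the chromosome-level correlation between annotated and
chimera-forming gene counts, and FASTA export of breakpoint flank windows
for downstream motif discovery.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, gene_utr3_length
from .model import UniqueChimera
from .sequence import tx_window

__all__ = [
    "StageDistribution",
    "stage_distributions",
    "splice_motif_summary",
    "frequency_histogram",
    "relative_expression_cdf",
    "rank_sum_test",
    "utr3_comparison",
    "chromosome_correlation",
    "flank_windows",
]


@dataclass
class StageDistribution:
    """Normalized class proportions of one filter stage."""

    stage: str
    junction: dict[str, float]
    pair: dict[str, float]
    frame: dict[str, float]

    def __post_init__(self) -> None:
        for name, dist in (("junction", self.junction), ("pair", self.pair),
                           ("frame", self.frame)):
            if dist:
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"stage {self.stage!r}: {name} proportions sum to "
                        f"{total}, not 1")
                if any(v < 0 for v in dist.values()):
                    raise ValueError(f"negative proportion in {name}")


def _proportions(labels: Iterable[Optional[str]]) -> dict[str, float]:
    counts = Counter(x for x in labels if x is not None)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}


def stage_distributions(stages: Mapping[str, Sequence[UniqueChimera]],
                        ) -> list[StageDistribution]:
    """Class proportions per filter stage, e.g. for stages named
    ``all``, ``non_mm``, ``non_mm_recurrent``."""
    out = []
    for stage, uniques in stages.items():
        if not uniques:
            raise ValueError(f"stage {stage!r} is empty")
        out.append(StageDistribution(
            stage=stage,
            junction=_proportions(u.labels.junction_class for u in uniques),
            pair=_proportions(u.labels.pair_class for u in uniques),
            frame=_proportions(u.labels.frame_class for u in uniques),
        ))
    return out


def splice_motif_summary(uniques: Sequence[UniqueChimera],
                         ) -> dict[str, dict[str, float]]:
    """Per-junction-class percentages of canonical donor (AG|GT) and
    acceptor (AG|G) motifs.

    Chimeras whose motif flag is undefined (contig-edge windows) are
    excluded from the corresponding denominator; junction classes with no
    members are absent from the result rather than reported as 0%.
    """
    result: dict[str, dict[str, float]] = {}
    by_class: dict[str, list[UniqueChimera]] = {}
    for u in uniques:
        jc = u.labels.junction_class
        if jc is not None:
            by_class.setdefault(jc, []).append(u)
    for jc, members in sorted(by_class.items()):
        donor_flags = [u.labels.donor_motif for u in members
                       if u.labels.donor_motif is not None]
        acceptor_flags = [u.labels.acceptor_motif for u in members
                          if u.labels.acceptor_motif is not None]
        entry: dict[str, float] = {"n": len(members)}
        if donor_flags:
            entry["donor_pct"] = 100.0 * sum(donor_flags) / len(donor_flags)
        if acceptor_flags:
            entry["acceptor_pct"] = (100.0 * sum(acceptor_flags)
                                     / len(acceptor_flags))
        result[jc] = entry
    return result


def frequency_histogram(uniques: Sequence[UniqueChimera]) -> dict[int, int]:
    """Exact histogram of sample frequencies."""
    return dict(sorted(Counter(u.frequency for u in uniques).items()))


def relative_expression_cdf(uniques: Sequence[UniqueChimera],
                            grid: Optional[Sequence[float]] = None,
                            ) -> pd.DataFrame:
    """Empirical CDF of the chimera/parent expression ratio on a fixed grid.

    Ratios are summarized per unique chimera as the maximum per-sample
    ratio against each parent.  The CDF at x is the fraction of chimeras
    with ratio <= x; with ratios capped by the ratio filter at 1, the CDF
    reaches 1 at the end of the default grid (0 to 1, step 0.05).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    r5 = np.array([u.max_ratio5 for u in uniques], dtype=float)
    r3 = np.array([u.max_ratio3 for u in uniques], dtype=float)
    if r5.size == 0:
        raise ValueError("no chimeras to summarize")
    cdf5 = [(r5 <= x).mean() for x in grid]
    cdf3 = [(r3 <= x).mean() for x in grid]
    return pd.DataFrame({"ratio": grid, "cdf5": cdf5, "cdf3": cdf3})


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration is used for small samples (combined n at or below
    ``exact_max_n``, no ties); otherwise the normal approximation with
    continuity and tie corrections.  Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size + y.size <= exact_max_n and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def utr3_comparison(parental5: Iterable[str], parental3: Iterable[str],
                    all_genes: Iterable[str],
                    annotation: GenomeAnnotation) -> dict:
    """Compare 3'UTR lengths of parental genes against the annotation-wide
    background, and 5' against 3' parents.

    Gene-level 3'UTR length is the maximum over coding transcripts;
    noncoding genes are excluded.  Returns the three length vectors and
    two-sided rank-sum results for (parental union vs all) and (5' vs 3').
    """
    def lengths(symbols: Iterable[str]) -> list[int]:
        out = []
        for s in symbols:
            gene = annotation.gene(s)
            if gene is None:
                continue
            val = gene_utr3_length(gene)
            if val is not None:
                out.append(val)
        return out

    p5 = set(parental5)
    p3 = set(parental3)
    len5, len3 = lengths(p5), lengths(p3)
    len_par = lengths(p5 | p3)
    len_all = lengths(all_genes)
    u_pa, p_pa = rank_sum_test(len_par, len_all)
    u_53, p_53 = rank_sum_test(len5, len3)
    return {
        "lengths_5prime": len5,
        "lengths_3prime": len3,
        "lengths_all": len_all,
        "parental_vs_all": {"U": u_pa, "p": p_pa},
        "five_vs_three": {"U": u_53, "p": p_53},
    }


def chromosome_correlation(uniques: Sequence[UniqueChimera],
                           annotation: GenomeAnnotation) -> dict:
    """Correlation between annotated-gene and chimera-parent counts per
    chromosome (Pearson).

    Returns the per-chromosome count pairs plus r; with constant counts on
    either axis the correlation is undefined and flagged.
    """
    chroms = annotation.chromosomes
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes")
    parent_genes: set[str] = set()
    for u in uniques:
        parent_genes.add(u.key.gene5)
        parent_genes.add(u.key.gene3)
    gene_counts, parent_counts = [], []
    for chrom in chroms:
        genes = annotation.genes_on(chrom)
        gene_counts.append(len(genes))
        parent_counts.append(sum(1 for g in genes
                                 if g.symbol in parent_genes
                                 or g.gene_id in parent_genes))
    gene_counts = np.array(gene_counts)
    parent_counts = np.array(parent_counts)
    undefined = gene_counts.std() == 0 or parent_counts.std() == 0
    result = {
        "chromosomes": chroms,
        "annotated_genes": gene_counts.tolist(),
        "chimera_parent_genes": parent_counts.tolist(),
        "undefined": bool(undefined),
    }
    if undefined:
        result["pearson_r"] = float("nan")
    else:
        r, p = stats.pearsonr(gene_counts, parent_counts)
        result["pearson_r"] = float(r)
        result["pearson_p"] = float(p)
    return result


#: window role -> (side, relative interval in transcript orientation)
_FLANK_ROLES = ("five_upstream", "five_downstream",
                "three_upstream", "three_downstream")


def flank_windows(uniques: Sequence[UniqueChimera],
                  genome: Mapping[str, str], width: int = 200,
                  ) -> dict[str, list[tuple[str, str]]]:
    """Breakpoint flank windows for motif discovery, one FASTA-ready list
    per role.

    For the 5' gene, "upstream" is the ``width`` transcript-orientation
    bases ending at pos5 (inclusive) and "downstream" the ``width`` bases
    after it; for the 3' gene, "upstream" ends just before pos3 and
    "downstream" starts at pos3.  Contig-edge truncation is flagged in the
    record id.
    """
    out: dict[str, list[tuple[str, str]]] = {r: [] for r in _FLANK_ROLES}
    for u in sorted(uniques, key=lambda u: str(u.key)):
        k = u.key
        windows = {
            "five_upstream": tx_window(genome, k.chrom5, k.strand5, k.pos5,
                                       -(width - 1), 1),
            "five_downstream": tx_window(genome, k.chrom5, k.strand5, k.pos5,
                                         1, width + 1),
            "three_upstream": tx_window(genome, k.chrom3, k.strand3, k.pos3,
                                        -width, 0),
            "three_downstream": tx_window(genome, k.chrom3, k.strand3, k.pos3,
                                          0, width),
        }
        for role, seq in windows.items():
            suffix = "|truncated" if len(seq) < width else ""
            out[role].append((f"{k}|{role}{suffix}", seq))
    return out
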