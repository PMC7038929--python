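"""Binary presence/absence profiling of chimeras and parental genes.

A presence matrix is a samples x features pandas DataFrame of {0,1} with
deterministic (sorted) row and column order, so exports are reproducible
byte-for-byte.  Chimera profiles are compared with parental-gene expression
profiles via the Simple Matching Coefficient (SMC), the fraction of samples
on which two binary profiles agree.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SampleMetadata
from .model import ChimeraKey, UniqueChimera

logger = logging.getLogger(__name__)

__all__ = [
    "chimera_matrix",
    "gene_matrix",
    "smc",
    "smc_summary",
    "common_chimeras",
    "tissue_specific",
    "export_embedding_matrix",
]

#: SMC histogram bin edges: "dissimilar" [0, 0.25), middling, "high" [0.6, 1].
DEFAULT_SMC_BINS = (0.0, 0.25, 0.6, 1.0)


def _check_binary(matrix: pd.DataFrame, name: str) -> None:
    values = matrix.to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError(f"{name} is not strictly binary")


def chimera_matrix(uniques: Sequence[UniqueChimera],
                   samples: Iterable[str]) -> pd.DataFrame:
    """Samples x chimeras binary matrix; 1 iff the chimera was called there."""
    rows = sorted(samples)
    cols = sorted(str(u.key) for u in uniques)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate chimera keys in unique set")
    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int8)
    for u in uniques:
        present = [s for s in u.sample_ids if s in matrix.index]
        matrix.loc[present, str(u.key)] = 1
    matrix.index.name = "sample_id"
    return matrix


def gene_matrix(expression: pd.DataFrame, genes: Iterable[str],
                cutoff: float = 0.04) -> pd.DataFrame:
    """Binarize a gene x sample FPKM table at ``>= cutoff`` (default 0.04,
    the lowest chimera expression observed in the recurrent set and hence
    the level at which a chimera itself counts as present).

    Returns samples x genes with sorted ids.
    """
    wanted = sorted(set(genes))
    missing = [g for g in wanted if g not in expression.index]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing}")
    binary = (expression.loc[wanted] >= cutoff).astype(np.int8)
    matrix = binary.T.sort_index()
    matrix = matrix[wanted]
    matrix.index.name = "sample_id"
    return matrix


def smc(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Simple Matching Coefficient: fraction of positions where a == b.

    1 means identical profiles, 0 means complementary; equals
    1 - normalized Hamming distance.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"SMC needs equal-length vectors, got shapes "
                         f"{a.shape} and {b.shape}")
    if a.size == 0:
        raise ValueError("SMC undefined for empty vectors")
    return float(np.mean(a == b))


def smc_summary(chim_matrix: pd.DataFrame, gene_m: pd.DataFrame,
                parents: Mapping[str, tuple[str, str]],
                bins: Sequence[float] = DEFAULT_SMC_BINS,
                ) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Per-chimera SMC against both parents' binary expression profiles.

    ``parents`` maps each chimera column of ``chim_matrix`` to its
    (5' gene, 3' gene); chimeras whose parents are missing from ``gene_m``
    are skipped with a warning.  Returns the per-chimera (smc5, smc3) table
    and per-side histograms over ``bins`` (last bin closed on the right).
    """
    _check_binary(chim_matrix, "chimera matrix")
    _check_binary(gene_m, "gene matrix")
    if list(chim_matrix.index) != list(gene_m.index):
        gene_m = gene_m.reindex(chim_matrix.index)
        if gene_m.isna().any().any():
            raise ValueError("matrices do not share sample rows")
    records = []
    for feature in chim_matrix.columns:
        if feature not in parents:
            logger.warning("no parent mapping for %s; skipped", feature)
            continue
        g5, g3 = parents[feature]
        if g5 not in gene_m.columns or g3 not in gene_m.columns:
            logger.warning("parent gene missing from gene matrix for %s; "
                           "skipped", feature)
            continue
        profile = chim_matrix[feature].to_numpy()
        records.append({
            "chimera": feature,
            "smc5": smc(profile, gene_m[g5].to_numpy()),
            "smc3": smc(profile, gene_m[g3].to_numpy()),
        })
    table = pd.DataFrame(records, columns=["chimera", "smc5", "smc3"])
    table = table.set_index("chimera")
    edges = np.asarray(bins, dtype=float)
    histogram: dict[str, dict[str, int]] = {}
    for side in ("smc5", "smc3"):
        values = table[side].to_numpy() if len(table) else np.empty(0)
        counts, _ = np.histogram(values, bins=edges)
        labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 2)]
        labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
        histogram[side] = dict(zip(labels, counts.tolist()))
    return table, histogram


def common_chimeras(uniques: Sequence[UniqueChimera],
                    metadata: SampleMetadata) -> set[ChimeraKey]:
    """Chimeras detected in every tissue of the cohort."""
    all_tissues = set(metadata.tissues)
    return {u.key for u in uniques if set(u.tissue_counts) == all_tissues}


def tissue_specific(uniques: Sequence[UniqueChimera],
                    metadata: SampleMetadata,
                    recurrent: Optional[Mapping[str, set[ChimeraKey]]] = None,
                    strict: bool = True) -> dict[str, set[ChimeraKey]]:
    """Per-tissue sets of tissue-specific recurrent chimeras.

    A chimera is specific to tissue T when it is recurrent in T (under the
    per-tissue thresholds) and — in the default strict mode — detected in
    zero samples of any other tissue.  The relaxed mode only requires that
    T be the sole tissue in which the chimera is recurrent.
    """
    from .filters import tissue_recurrent

    if recurrent is None:
        recurrent = tissue_recurrent(uniques, metadata)
    by_key = {u.key: u for u in uniques}
    result: dict[str, set[ChimeraKey]] = {t: set() for t in recurrent}
    for tissue, keys in recurrent.items():
        for key in keys:
            u = by_key[key]
            if strict:
                elsewhere = sum(n for t, n in u.tissue_counts.items()
                                if t != tissue)
                if elsewhere == 0:
                    result[tissue].add(key)
            else:
                others = [t for t, ks in recurrent.items()
                          if t != tissue and key in ks]
                if not others:
                    result[tissue].add(key)
    return result


def export_embedding_matrix(matrix: pd.DataFrame, path) -> dict:
    """Write a presence matrix as TSV suitable for any embedding tool.

    Columns are emitted in lexicographic order with the sample id first;
    repeated exports of the same matrix are byte-identical.  Returns a
    small summary including the number of duplicated rows (embedding tools
    may reject matrices with many identical rows).
    """
    _check_binary(matrix, "matrix")
    ordered = matrix.sort_index()[sorted(matrix.columns)]
    ordered.to_csv(path, sep="\t", index_label="sample_id")
    n_dup_rows = int(ordered.duplicated().sum())
    n_dup_cols = int(ordered.T.duplicated().sum())
    return {
        "n_samples": int(ordered.shape[0]),
        "n_features": int(ordered.shape[1]),
        "duplicate_rows": n_dup_rows,
        "duplicate_columns": n_dup_cols,
    }
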