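"""Shared fixtures: toy gene models, a toy genome, and simulated cohorts."""
from __future__ import annotations

import numpy as np
import pytest

from rnachimera.annotation import GeneModel, GenomeAnnotation, TranscriptModel
from rnachimera import simulate as sim


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n).tolist())


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    return {"chr1": _random_seq(rng, 2000), "chr2": _random_seq(rng, 1500)}


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two genes on chr1 (one per strand) and one on chr2.

    Intervals are 0-based half-open.  geneA (+): exons [100,200) and
    [300,400) with CDS [130,200)+[300,370); geneB (-): exons [500,600) and
    [700,800) with CDS [530,600)+[700,760) -- in transcript orientation the
    genomically-last exon comes first.
    """
    gene_a = GeneModel(
        gene_id="GA", symbol="GENEA", chrom="chr1", strand="+",
        transcripts=[TranscriptModel(
            transcript_id="GA.t1", chrom="chr1", strand="+",
            exons=[(100, 200), (300, 400)],
            cds=[(130, 200), (300, 370)])],
    )
    gene_b = GeneModel(
        gene_id="GB", symbol="GENEB", chrom="chr1", strand="-",
        transcripts=[TranscriptModel(
            transcript_id="GB.t1", chrom="chr1", strand="-",
            exons=[(500, 600), (700, 800)],
            cds=[(530, 600), (700, 760)])],
    )
    gene_c = GeneModel(
        gene_id="GC", symbol="GENEC", chrom="chr2", strand="+",
        transcripts=[TranscriptModel(
            transcript_id="GC.t1", chrom="chr2", strand="+",
            exons=[(50, 170), (250, 400), (500, 620)],
            cds=[(100, 170), (250, 400), (500, 560)])],
    )
    return GenomeAnnotation([gene_a, gene_b, gene_c])


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with its universe and planted truth."""
    cfg = sim.preset("small", seed=11)
    universe, cohort = sim.simulate_cohort(cfg)
    return universe, cohort


@pytest.fixture(scope="session")
def paper_cohort():
    """The paper-shaped cohort used by end-to-end recovery checks."""
    cfg = sim.preset("paper-shaped", seed=7)
    universe, cohort = sim.simulate_cohort(cfg)
    return universe, cohort
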