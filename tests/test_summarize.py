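"""Descriptive statistics: stage distributions, motif percentages,
frequency histograms, CDFs, rank-sum tests, chromosome correlation."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from rnachimera.annotation import GeneModel, GenomeAnnotation, TranscriptModel
from rnachimera.model import ChimeraKey, ChimeraLabels, UniqueChimera
from rnachimera.summarize import (
    chromosome_correlation,
    flank_windows,
    frequency_histogram,
    rank_sum_test,
    relative_expression_cdf,
    splice_motif_summary,
    stage_distributions,
    utr3_comparison,
)


def _unique(pos5, junction_class="EE", pair_class="read_through",
            frame_class="in_frame", donor=None, acceptor=None,
            samples=1, r5=0.0, r3=0.0, gene5="A", gene3="B",
            strand5="+", strand3="-", chrom5="chr1", chrom3="chr2",
            pos3=900):
    return UniqueChimera(
        key=ChimeraKey(gene5, gene3, chrom5, pos5, strand5,
                       chrom3, pos3, strand3),
        sample_ids=frozenset(f"s{pos5}.{i}" for i in range(samples)),
        tissue_counts={},
        labels=ChimeraLabels(junction_class=junction_class,
                             pair_class=pair_class, frame_class=frame_class,
                             donor_motif=donor, acceptor_motif=acceptor),
        max_ratio5=r5, max_ratio3=r3,
    )


class TestStageDistributions:
    def test_proportions_are_counts_over_total(self):
        uniques = ([_unique(i, junction_class="EE") for i in range(4)]
                   + [_unique(100 + i, junction_class="MM")
                      for i in range(16)])
        [dist] = stage_distributions({"all": uniques})
        assert dist.junction == {"EE": 0.2, "MM": 0.8}

    def test_single_class_stage(self):
        [dist] = stage_distributions({"all": [_unique(1)]})
        assert dist.junction == {"EE": 1.0}

    def test_empty_stage_raises(self):
        with pytest.raises(ValueError):
            stage_distributions({"all": []})

    def test_ee_and_read_through_enrichment_across_planted_stages(self):
        """The generator plants higher recurrence for E/E and read-through
        chimeras, so their proportions rise monotonically along the
        all -> non-M/M -> recurrent ladder (checked on a cohort large
        enough for the recurrent stage to be well populated)."""
        from rnachimera import simulate as sim

        cfg = sim.SimConfig(seed=7, n_chromosomes=6, genes_per_chromosome=20,
                            n_true_chimeras=1000, n_decoys=0, n_low_score=0,
                            n_missing_breakpoint=0, n_ratio_violators=0)
        _, cohort = sim.simulate_cohort(cfg)
        records = cohort.truth.of_kind("true")
        def frac(recs, get):
            return sum(1 for r in recs if get(r)) / len(recs)
        all_recs = records
        non_mm = [r for r in records if r.junction_class != "MM"]
        recurrent = [r for r in non_mm if r.frequency >= 5]
        ee = [frac(s, lambda r: r.junction_class == "EE")
              for s in (all_recs, non_mm, recurrent)]
        rt = [frac(s, lambda r: r.pair_class == "read_through")
              for s in (all_recs, non_mm, recurrent)]
        assert ee[0] <= ee[1] <= ee[2] and ee[2] > ee[0]
        assert rt[0] <= rt[2] and rt[2] > rt[0]


class TestSpliceMotifSummary:
    def test_percentages_exclude_undefined_and_absent_classes(self):
        uniques = [
            _unique(1, junction_class="EE", donor=True, acceptor=False),
            _unique(2, junction_class="EE", donor=False, acceptor=False),
            _unique(3, junction_class="EE", donor=None, acceptor=True),
            _unique(4, junction_class="MM", donor=False, acceptor=False),
        ]
        summary = splice_motif_summary(uniques)
        assert summary["EE"]["donor_pct"] == pytest.approx(50.0)
        assert summary["EE"]["acceptor_pct"] == pytest.approx(100 / 3)
        assert "EM" not in summary

    def test_planted_motif_rates_recovered(self, paper_cohort):
        universe, cohort = paper_cohort
        records = cohort.truth.of_kind("true")
        mm = [r for r in records if r.junction_class == "MM"]
        ee = [r for r in records if r.junction_class == "EE"]
        if len(mm) >= 10 and len(ee) >= 2:
            mm_rate = sum(r.donor_motif for r in mm) / len(mm)
            ee_rate = sum(r.donor_motif for r in ee) / len(ee)
            assert mm_rate <= ee_rate


class TestFrequencyHistogram:
    def test_counting(self):
        uniques = [_unique(1, samples=1), _unique(2, samples=1),
                   _unique(3, samples=2), _unique(4, samples=5)]
        assert frequency_histogram(uniques) == {1: 2, 2: 1, 5: 1}

    def test_empty_and_conservation(self):
        assert frequency_histogram([]) == {}
        uniques = [_unique(i, samples=1 + i % 3) for i in range(20)]
        hist = frequency_histogram(uniques)
        assert sum(hist.values()) == 20


class TestRelativeExpressionCdf:
    def test_point_mass_jumps_at_half(self):
        uniques = [_unique(i, r5=0.5, r3=0.5) for i in range(10)]
        cdf = relative_expression_cdf(uniques)
        below = cdf[cdf.ratio < 0.5]
        at = cdf[cdf.ratio >= 0.5]
        assert (below.cdf5 == 0).all() and (at.cdf5 == 1).all()

    def test_planted_half_at_or_above_fifty_percent(self):
        uniques = ([_unique(i, r5=0.25) for i in range(50)]
                   + [_unique(100 + i, r5=0.75) for i in range(50)])
        cdf = relative_expression_cdf(uniques)
        just_below = cdf[np.isclose(cdf.ratio, 0.45)].cdf5.iloc[0]
        assert just_below == pytest.approx(0.5)

    def test_monotone_and_ends_at_one(self):
        rng = np.random.default_rng(2)
        uniques = [_unique(i, r5=float(r), r3=float(r))
                   for i, r in enumerate(rng.uniform(0, 1, 200))]
        cdf = relative_expression_cdf(uniques)
        assert (np.diff(cdf.cdf5) >= 0).all()
        assert cdf.cdf5.iloc[-1] == 1.0
        # grid evaluation agrees with a brute-force empirical CDF
        ratios = np.array([u.max_ratio5 for u in uniques])
        for _, row in cdf.iterrows():
            assert row.cdf5 == pytest.approx((ratios <= row.ratio).mean())


def _exact_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by enumeration over all labelings."""
    pooled = list(x) + list(y)
    n = len(x)
    def u_of(group):
        rest = list(pooled)
        g = list(group)
        for v in g:
            rest.remove(v)
        return sum(1 for a in g for b in rest if a > b)
    u_obs = u_of(x)
    nm = len(x) * len(y)
    u_min = min(u_obs, nm - u_obs)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        u = u_of([pooled[i] for i in combo])
        if u <= u_min or u >= nm - u_min:
            extreme += 1
    return extreme / total


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = rank_sum_test(x, x)
        assert p > 0.99

    def test_small_samples_match_exact_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            nx, ny = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = pooled[:nx], pooled[nx:]
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(_exact_mwu_p(x, y), abs=1e-9)

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])


def _utr_annotation():
    """Genes whose 3'UTR lengths are fully controlled."""
    genes = []
    lengths = {"LONG1": 300, "LONG2": 280, "LONG3": 320, "SH1": 30,
               "SH2": 40, "SH3": 20, "SH4": 35, "SH5": 25}
    start = 0
    for name, utr in lengths.items():
        total = 600
        genes.append(GeneModel(
            gene_id=name, symbol=name, chrom="chr1", strand="+",
            transcripts=[TranscriptModel(
                f"{name}.t", "chr1", "+",
                exons=[(start, start + total)],
                cds=[(start + 30, start + total - utr)])],
        ))
        start += total + 100
    return GenomeAnnotation(genes), lengths


class TestUtr3Comparison:
    def test_vectors_and_identical_groups(self):
        ann, lengths = _utr_annotation()
        out = utr3_comparison(["LONG1", "LONG2"], ["LONG1", "LONG2"],
                              list(lengths), ann)
        assert sorted(out["lengths_5prime"]) == [280, 300]
        assert out["five_vs_three"]["p"] > 0.99

    def test_longer_parental_utrs_detected(self):
        ann, lengths = _utr_annotation()
        out = utr3_comparison(
            ["LONG1", "LONG2"], ["LONG3", "LONG2"],
            ["SH1", "SH2", "SH3", "SH4", "SH5"], ann)
        assert out["parental_vs_all"]["p"] < 0.2  # tiny n, direction only
        assert min(out["lengths_5prime"]) > max(out["lengths_all"])


def _corr_annotation(counts):
    genes = []
    n = 0
    for ci, k in enumerate(counts):
        for gi in range(k):
            n += 1
            start = gi * 500
            genes.append(GeneModel(
                gene_id=f"g{n}", symbol=f"g{n}", chrom=f"chr{ci + 1}",
                strand="+",
                transcripts=[TranscriptModel(
                    f"g{n}.t", f"chr{ci + 1}", "+",
                    exons=[(start, start + 300)])],
            ))
    return GenomeAnnotation(genes)


class TestChromosomeCorrelation:
    def test_proportional_counts_give_r_one(self):
        ann = _corr_annotation([2, 3, 4])
        uniques = []
        for i, g in enumerate(ann.genes):  # every gene is a parent
            uniques.append(_unique(10 + i, gene5=g.symbol, gene3=g.symbol,
                                   chrom5=g.chrom, chrom3=g.chrom))
        out = chromosome_correlation(uniques, ann)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_uniform_parent_sampling_correlates(self):
        rng = np.random.default_rng(3)
        counts = [5, 10, 20, 40, 25]
        ann = _corr_annotation(counts)
        symbols = [g.symbol for g in ann.genes]
        uniques = []
        for i in range(500):
            g5, g3 = rng.choice(symbols, size=2, replace=False)
            uniques.append(_unique(1000 + i, gene5=str(g5), gene3=str(g3)))
        out = chromosome_correlation(uniques, ann)
        assert out["pearson_r"] > 0.9

    def test_constant_counts_flagged_undefined(self):
        ann = _corr_annotation([3, 3, 3])
        uniques = [_unique(10, gene5="g1", gene3="g4")]
        out = chromosome_correlation(uniques, ann)
        assert out["undefined"] and np.isnan(out["pearson_r"])

    def test_too_few_chromosomes_raise(self):
        ann = _corr_annotation([3, 3])
        with pytest.raises(ValueError):
            chromosome_correlation([_unique(10)], ann)


class TestFlankWindows:
    def test_four_records_per_chimera_with_slice_oracle(self, toy_genome):
        rng = np.random.default_rng(4)
        uniques = []
        for i in range(100):
            pos5 = int(rng.integers(300, 1500))
            pos3 = int(rng.integers(300, 1200))
            strand5 = "+" if rng.random() < 0.5 else "-"
            uniques.append(_unique(pos5, pos3=pos3, strand5=strand5,
                                   strand3="+", chrom5="chr1", chrom3="chr2"))
        out = flank_windows(uniques, toy_genome, width=50)
        assert set(out) == {"five_upstream", "five_downstream",
                            "three_upstream", "three_downstream"}
        assert all(len(v) == len(uniques) for v in out.values())
        from Bio.Seq import Seq
        by_key = {str(u.key): u for u in uniques}
        for rid, seq in out["five_upstream"]:
            u = by_key[rid.split("|")[0]]
            k = u.key
            if k.strand5 == "+":
                want = toy_genome["chr1"][k.pos5 - 50:k.pos5]
            else:
                want = str(Seq(
                    toy_genome["chr1"][k.pos5 - 1:k.pos5 + 49]
                ).reverse_complement())
            assert seq == want
        for rid, seq in out["three_downstream"]:
            u = by_key[rid.split("|")[0]]
            want = toy_genome["chr2"][u.key.pos3 - 1:u.key.pos3 + 49]
            assert seq == want

    def test_truncation_flagged_at_contig_edge(self, toy_genome):
        u = _unique(5, pos3=700, chrom5="chr1", chrom3="chr2", strand3="+")
        out = flank_windows([u], toy_genome, width=50)
        rid, seq = out["five_upstream"][0]
        assert "truncated" in rid and len(seq) == 5
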