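"""Per-chimera classification: junction classes, pair classes, frames,
splice motifs and isoform naming."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from rnachimera.annotation import GeneModel, GenomeAnnotation, TranscriptModel
from rnachimera.classify import (
    ClassificationError,
    PairClassConfig,
    classify_junction,
    classify_pair,
    isoform_name,
    predict_frame,
    splice_motifs,
)
from rnachimera.model import ChimeraCall


def _call(gene5="GENEA", gene3="GENEB", pos5=200, pos3=701,
          chrom5="chr1", chrom3="chr1", strand5="+", strand3="-"):
    return ChimeraCall(
        sample_id="s", gene5=gene5, gene3=gene3,
        chrom5=chrom5, pos5=pos5, strand5=strand5,
        chrom3=chrom3, pos3=pos3, strand3=strand3,
        junction_seq="ACGT" * 10, score=0.9,
        chimera_expr=1.0, gene5_expr=2.0, gene3_expr=2.0,
    )


def _gene(name, chrom, strand, exons, cds=()):
    return GeneModel(
        gene_id=name, symbol=name, chrom=chrom, strand=strand,
        transcripts=[TranscriptModel(f"{name}.t1", chrom, strand,
                                     list(exons), list(cds))],
    )


class TestClassifyJunction:
    def test_end_end_is_ee(self, toy_annotation):
        # GENEA donor end 200 (+); GENEB acceptor end 800 (-)
        call = _call(pos5=200, pos3=800)
        assert classify_junction(call, toy_annotation) == "EE"

    def test_end_middle_is_em(self, toy_annotation):
        call = _call(pos5=200, pos3=750)
        assert classify_junction(call, toy_annotation) == "EM"

    def test_middle_combinations(self, toy_annotation):
        assert classify_junction(_call(pos5=150, pos3=800),
                                 toy_annotation) == "ME"
        assert classify_junction(_call(pos5=150, pos3=750),
                                 toy_annotation) == "MM"

    def test_outside_maps_to_conservative_m(self, toy_annotation):
        call = _call(pos5=250, pos3=800)  # intronic in GENEA
        assert classify_junction(call, toy_annotation) == "ME"

    def test_unknown_gene_raises_classification_error(self, toy_annotation):
        with pytest.raises(ClassificationError, match="NOPE"):
            classify_junction(_call(gene5="NOPE"), toy_annotation)

    def test_exhaustive_grid_matches_brute_force_oracle(self):
        """Every (pos5, pos3) pair over a 2-exon x 2-exon toy locus gets the
        class a direct recomputation from raw exon lists predicts."""
        g5 = _gene("P", "chr1", "+", [(10, 30), (50, 80)])
        g3 = _gene("Q", "chr1", "-", [(110, 140), (160, 190)])
        ann = GenomeAnnotation([g5, g3])

        def oracle(pos5, pos3):
            donor_ends = {30, 80}
            inside5 = 11 <= pos5 <= 30 or 51 <= pos5 <= 80
            acceptor_ends = {140, 190}  # minus strand: 5'-most = interval end
            inside3 = 111 <= pos3 <= 140 or 161 <= pos3 <= 190
            c5 = "E" if pos5 in donor_ends else "M"
            c3 = "E" if pos3 in acceptor_ends else "M"
            return c5 + c3

        for pos5 in range(5, 95):
            for pos3 in range(105, 200):
                got = classify_junction(_call(gene5="P", gene3="Q",
                                              pos5=pos5, pos3=pos3,
                                              strand3="-"), ann)
                assert got == oracle(pos5, pos3), (pos5, pos3)


class TestClassifyPair:
    ann = GenomeAnnotation([
        _gene("UP", "chr1", "+", [(1000, 1500), (2000, 2500)]),
        _gene("DOWN", "chr1", "+", [(7000, 7400), (8000, 8500)]),
        _gene("FAR", "chr1", "+", [(300_000, 301_000)]),
        _gene("REV", "chr1", "-", [(12_000, 13_000)]),
        _gene("BETWEEN", "chr1", "+", [(4000, 4800)]),
        _gene("ELSEWHERE", "chr7", "+", [(100, 900)]),
    ])

    def test_different_chromosomes_are_inter(self):
        call = _call(gene5="UP", gene3="ELSEWHERE", pos5=1500, pos3=101,
                     chrom3="chr7", strand3="+")
        assert classify_pair(call, self.ann) == "inter_chromosomal"

    def test_adjacent_same_strand_pair_is_read_through(self):
        call = _call(gene5="UP", gene3="DOWN", pos5=2500, pos3=7001,
                     strand3="+")
        assert classify_pair(call, self.ann) == "read_through"
        # ordering and gap verified directly from the spans
        up, down = self.ann.gene("UP"), self.ann.gene("DOWN")
        assert up.span[1] <= down.span[0]
        assert down.span[0] - up.span[1] <= 100_000

    def test_opposite_strands_are_intra_other(self):
        call = _call(gene5="UP", gene3="REV", pos5=2500, pos3=12_500)
        assert classify_pair(call, self.ann) == "intra_other"

    def test_wrong_transcription_order_is_intra_other(self):
        call = _call(gene5="DOWN", gene3="UP", pos5=8500, pos3=1001,
                     strand3="+")
        assert classify_pair(call, self.ann) == "intra_other"

    def test_gap_beyond_threshold_is_intra_other(self):
        call = _call(gene5="UP", gene3="FAR", pos5=2500, pos3=300_001,
                     strand3="+")
        assert classify_pair(call, self.ann) == "intra_other"
        wide = PairClassConfig(readthrough_max_gap=500_000)
        assert classify_pair(call, self.ann, wide) == "read_through"

    def test_intervening_gene_check(self):
        call = _call(gene5="UP", gene3="DOWN", pos5=2500, pos3=7001,
                     strand3="+")
        strict = PairClassConfig(require_no_intervening_same_strand_gene=True)
        assert classify_pair(call, self.ann, strict) == "intra_other"


def _frame_fixture():
    """Two plus-strand single-exon genes whose CDSs are codon repeats:
    X encodes poly-D (GAT), Y encodes poly-A (GCT).  A fused CDS stays
    in frame exactly when the downstream translation is still poly-A."""
    rng = np.random.default_rng(0)
    pad = lambda n: "".join(rng.choice(list("ACGT"), size=n).tolist())
    chr1 = pad(60) + "GAT" * 60 + pad(60)
    chr2 = pad(60) + "GCT" * 60 + pad(60)
    genome = {"chr1": chr1, "chr2": chr2}
    gx = _gene("X", "chr1", "+", [(0, 300)], cds=[(60, 240)])
    gy = _gene("Y", "chr2", "+", [(0, 300)], cds=[(60, 240)])
    return genome, GenomeAnnotation([gx, gy])


class TestPredictFrame:
    @pytest.mark.parametrize("r5,s3", [(3, 0), (3, 3), (4, 1), (5, 2),
                                       (3, 1), (3, 2), (4, 0), (7, 5)])
    def test_codon_walk_oracle(self, r5, s3):
        """r5 = 5'-CDS bases retained, s3 = 3'-CDS bases skipped; the fused
        CDS is translated and the call is in-frame iff the poly-A tail of
        the 3' gene survives intact."""
        genome, ann = _frame_fixture()
        pos5 = 60 + r5            # 1-based last retained base of X CDS
        pos3 = 61 + s3            # 1-based first retained base of Y CDS
        call = _call(gene5="X", gene3="Y", pos5=pos5, pos3=pos3,
                     chrom5="chr1", chrom3="chr2", strand5="+", strand3="+")
        fused = (genome["chr1"][60:60 + r5]
                 + genome["chr2"][60 + s3:240])
        fused = fused[:len(fused) - len(fused) % 3]
        protein = str(Seq(fused).translate())
        oracle = "in_frame" if protein.endswith("A" * 10) else "frame_shift"
        assert predict_frame(call, ann) == oracle

    def test_utr_breakpoint_is_na(self):
        genome, ann = _frame_fixture()
        call = _call(gene5="X", gene3="Y", pos5=30, pos3=100,
                     chrom5="chr1", chrom3="chr2", strand5="+", strand3="+")
        assert predict_frame(call, ann) == "na"


class TestSpliceMotifs:
    def test_plus_strand_donor_and_acceptor(self):
        #            123456789012
        genome = {"c": "CCCCAGGTCCCC"}
        donor, _ = splice_motifs(_call(chrom5="c", pos5=6, strand5="+",
                                       chrom3="c", pos3=7, strand3="+"),
                                 genome)
        assert donor is True
        _, acceptor = splice_motifs(_call(chrom5="c", pos5=6, strand5="+",
                                          chrom3="c", pos3=7, strand3="+"),
                                    genome)
        assert acceptor is True  # AG before pos 7, G at pos 7

    def test_minus_strand_reads_reverse_complement(self):
        plus = "CCCCAGGTCCCC"
        minus_chrom = str(Seq(plus).reverse_complement())
        genome = {"c": minus_chrom}
        pos5 = len(plus) - 6 + 1  # mirror of plus-strand position 6
        donor, _ = splice_motifs(_call(chrom5="c", pos5=pos5, strand5="-",
                                       chrom3="c", pos3=pos5, strand3="-"),
                                 genome)
        assert donor is True

    def test_contig_edge_gives_undefined(self):
        genome = {"c": "AGGTCC"}
        donor, acceptor = splice_motifs(
            _call(chrom5="c", pos5=1, strand5="+",
                  chrom3="c", pos3=1, strand3="+"), genome)
        assert donor is None and acceptor is None

    def test_agrees_with_string_slicing_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        n_checked = 0
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=40).tolist())
            pos = int(rng.integers(5, 36))
            strand = "+" if rng.random() < 0.5 else "-"
            genome = {"c": seq}
            call = _call(chrom5="c", pos5=pos, strand5=strand,
                         chrom3="c", pos3=pos, strand3=strand)
            donor, acceptor = splice_motifs(call, genome)
            oriented = seq if strand == "+" else str(
                Seq(seq).reverse_complement())
            p = pos - 1 if strand == "+" else len(seq) - pos
            want_donor = (oriented[p - 1:p + 1] == "AG"
                          and oriented[p + 1:p + 3] == "GT")
            want_acceptor = (oriented[p - 2:p] == "AG"
                             and oriented[p] == "G")
            assert donor == want_donor and acceptor == want_acceptor
            n_checked += 1
        assert n_checked == 1000


class TestIsoformName:
    def _many_exon_annotation(self):
        exons5 = [(i * 100, i * 100 + 50) for i in range(16)]
        exons3 = [(i * 100, i * 100 + 50) for i in range(4)]
        g5 = _gene("BCRISH", "chr1", "+", exons5)
        g3 = _gene("ABLISH", "chr2", "+", exons3)
        return GenomeAnnotation([g5, g3])

    def test_e14e2_on_synthetic_many_exon_fixture(self):
        ann = self._many_exon_annotation()
        # donor end of exon 14 (0-based index 13): interval (1300, 1350)
        call = _call(gene5="BCRISH", gene3="ABLISH", pos5=1350, pos3=101,
                     chrom3="chr2", strand3="+")
        assert isoform_name(call, ann) == "e14e2"

    def test_first_exons(self):
        ann = self._many_exon_annotation()
        call = _call(gene5="BCRISH", gene3="ABLISH", pos5=50, pos3=101,
                     chrom3="chr2", strand3="+")
        assert isoform_name(call, ann) == "e1e2"

    def test_intronic_breakpoint_is_unnamed(self):
        ann = self._many_exon_annotation()
        call = _call(gene5="BCRISH", gene3="ABLISH", pos5=60, pos3=101,
                     chrom3="chr2", strand3="+")
        assert isoform_name(call, ann) is None

    def test_tie_break_prefers_longest_transcript_deterministically(self):
        # both transcripts share the donor end at 200 but differ in exon count
        t_long = TranscriptModel("tL", "chr1", "+",
                                 exons=[(0, 50), (100, 200), (300, 400)])
        t_short = TranscriptModel("tS", "chr1", "+", exons=[(100, 200)])
        g5 = GeneModel("G5", "G5", "chr1", "+", [t_long, t_short])
        g3 = _gene("G3", "chr2", "+", [(0, 50), (100, 160)])
        ann = GenomeAnnotation([g5, g3])
        call = _call(gene5="G5", gene3="G3", pos5=200, pos3=101,
                     chrom3="chr2", strand3="+")
        for _ in range(5):
            assert isoform_name(call, ann) == "e2e2"
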