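"""Chimeric-peptide prediction: junction assembly, translation, digestion,
junction-spanning retention, database and PSM handling."""
from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from rnachimera.model import ChimeraCall, ChimeraKey, ChimericPeptide, JunctionSequence, PsmRecord
from rnachimera.peptides import (
    build_junction_sequence,
    filter_psms,
    junction_peptides,
    peptides_from_junction,
    read_peptide_db,
    side_match_screen,
    three_frame_translate,
    tryptic_digest,
    write_peptide_db,
)
from rnachimera.simulate import simulate_psms

KEY = ChimeraKey("A", "B", "chr1", 500, "+", "chr2", 900, "-")


def _call(pos5=500, pos3=300, strand5="+", strand3="+",
          chrom5="chr1", chrom3="chr2"):
    return ChimeraCall(
        sample_id="s", gene5="A", gene3="B", chrom5=chrom5, pos5=pos5,
        strand5=strand5, chrom3=chrom3, pos3=pos3, strand3=strand3,
        junction_seq="ACGT" * 10, score=0.9,
        chimera_expr=1.0, gene5_expr=2.0, gene3_expr=2.0,
    )


def _random_genome(seed=0, n1=2000, n2=2000):
    rng = np.random.default_rng(seed)
    mk = lambda n: "".join(rng.choice(list("ACGT"), size=n).tolist())
    return {"chr1": mk(n1), "chr2": mk(n2)}


class TestBuildJunctionSequence:
    def test_full_flanks(self):
        genome = _random_genome()
        js = build_junction_sequence(_call(), genome, flank=200)
        assert len(js.sequence) == 400 and js.junction_offset == 200
        assert not js.truncated
        assert js.sequence[:200] == genome["chr1"][300:500]
        assert js.sequence[200:] == genome["chr2"][299:499]

    def test_truncated_near_contig_start(self):
        genome = _random_genome()
        js = build_junction_sequence(_call(pos5=50), genome, flank=200)
        assert js.junction_offset == 50 and len(js.sequence) == 250
        assert js.truncated

    def test_minus_strand_upstream_is_reverse_complement(self):
        genome = _random_genome()
        js = build_junction_sequence(_call(strand5="-"), genome, flank=100)
        window = genome["chr1"][499:599]  # bases pos5 .. pos5+99
        assert js.sequence[:100] == str(Seq(window).reverse_complement())

    def test_off_contig_raises(self):
        genome = _random_genome()
        with pytest.raises((KeyError, ValueError)):
            build_junction_sequence(_call(pos5=99999), genome)


class TestThreeFrameTranslate:
    def test_standard_code(self):
        js = JunctionSequence(KEY, "ATGGCC", 3)
        frames = three_frame_translate(js)
        assert len(frames) == 3
        assert frames[0].residues == "MA"

    def test_internal_stop_splits_segments(self):
        js = JunctionSequence(KEY, "ATGTAAATG", 3)
        frames = three_frame_translate(js)
        assert frames[0].residues == "M*M"

    def test_n_codon_is_x_and_bad_chars_raise(self):
        assert three_frame_translate(
            JunctionSequence(KEY, "ATGANC", 3))[0].residues == "MX"
        with pytest.raises(ValueError):
            three_frame_translate(JunctionSequence(KEY, "ATGQQQ", 3))


class TestTrypticDigest:
    @pytest.mark.parametrize("peptide,expected", [
        ("MKRPASK", ["MK", "RPASK"]),   # cut after K2; R3 shielded by P
        ("AAAA", ["AAAA"]),
        ("AKRC", ["AK", "R", "C"]),
    ])
    def test_rule_enumeration(self, peptide, expected):
        assert [f for _, _, f in tryptic_digest(peptide)] == expected

    def test_empty_input(self):
        assert tryptic_digest("") == []

    def test_partition_property_on_random_peptides(self):
        rng = np.random.default_rng(1)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(300):
            pep = "".join(rng.choice(alphabet,
                                     size=int(rng.integers(1, 60))).tolist())
            frags = tryptic_digest(pep)
            assert "".join(f for _, _, f in frags) == pep
            # coordinates tile the input
            assert frags[0][0] == 0 and frags[-1][1] == len(pep)
            for (s1, e1, _), (s2, e2, _) in zip(frags, frags[1:]):
                assert e1 == s2

    def test_missed_cleavages_add_merged_products(self):
        frags = {f for _, _, f in tryptic_digest("AKRC", missed_cleavages=1)}
        assert frags == {"AK", "R", "C", "AKR", "RC"}


def _codons(residues: str) -> str:
    table = {"R": "CGT", "T": "ACC", "L": "CTG", "I": "ATT", "K": "AAA",
             "P": "CCG", "A": "GCC", "G": "GGT", "E": "GAA", "S": "TCT",
             "M": "ATG", "*": "TAA", "D": "GAT", "V": "GTT"}
    return "".join(table[r] for r in residues)


def _oracle_peptides(js: JunctionSequence, min_side: int = 2,
                     ) -> dict[int, tuple[str, int, int]]:
    """Independent full enumeration: all frames x all tryptic fragments,
    with explicit codon-coordinate span checks."""
    out = {}
    seq = js.sequence
    b = js.junction_offset
    for f in range(3):
        sub = seq[f:]
        sub = sub[:len(sub) - len(sub) % 3]
        residues = ""
        for i in range(0, len(sub), 3):
            codon = sub[i:i + 3]
            residues += "X" if "N" in codon else str(Seq(codon).translate())
        # enumerate maximal tryptic fragments inside stop-free segments
        candidates = []
        for seg_start, seg in _oracle_segments(residues):
            cuts = [0]
            for i in range(len(seg) - 1):
                if seg[i] in "KR" and seg[i + 1] != "P":
                    cuts.append(i + 1)
            cuts.append(len(seg))
            for s, e in zip(cuts, cuts[1:]):
                abs_s, abs_e = seg_start + s, seg_start + e
                left = sum(1 for r in range(abs_s, abs_e)
                           if f + 3 * r + 3 <= b)
                right = sum(1 for r in range(abs_s, abs_e)
                            if f + 3 * r >= b)
                covers = f + 3 * abs_s < b < f + 3 * abs_e
                if covers and left >= min_side and right >= min_side:
                    candidates.append((seg[s:e], left, right))
        if candidates:
            assert len(candidates) == 1  # fragments are disjoint
            out[f] = candidates[0]
    return out


def _oracle_segments(residues: str):
    start = 0
    for i, r in enumerate(residues + "*"):
        if r == "*":
            if i > start:
                yield start, residues[start:i]
            start = i + 1


class TestJunctionPeptides:
    def test_at_most_one_peptide_per_frame(self):
        genome = _random_genome(7)
        peptides = junction_peptides(_call(), genome, flank=60)
        assert len(peptides) <= 3
        frames = [p.frame for p in peptides]
        assert len(set(frames)) == len(frames)

    def test_explicit_spanning_fragment(self):
        # R | TLIK PAGER | K ... : the K-P bond is shielded, so the
        # junction-spanning tryptic fragment is TLIKPAGER (left 4, right 5)
        upstream = _codons("SSRTLIK")
        downstream = _codons("PAGERKAA")
        js = JunctionSequence(KEY, upstream + downstream, len(upstream))
        got = {p.frame: p for p in peptides_from_junction(js)}
        assert got[0].sequence == "TLIKPAGER"
        assert (got[0].left_len, got[0].right_len) == (4, 5)

    def test_stop_just_after_junction_kills_frame(self):
        upstream = _codons("SSRTLIK")
        downstream = _codons("P*GERKAA")
        js = JunctionSequence(KEY, upstream + downstream, len(upstream))
        assert 0 not in {p.frame for p in peptides_from_junction(js)}

    def test_side_minimum_enforced(self):
        upstream = _codons("SSRK")       # only 1 residue after the R cut
        downstream = _codons("PAGERKAA")
        js = JunctionSequence(KEY, upstream + downstream, len(upstream))
        assert 0 not in {p.frame for p in peptides_from_junction(js)}

    def test_matches_enumeration_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n5 = int(rng.integers(9, 90))
            n3 = int(rng.integers(9, 90))
            seq = "".join(rng.choice(list("ACGT"), size=n5 + n3).tolist())
            js = JunctionSequence(ChimeraKey("A", "B", "c", 1, "+",
                                            "d", 1, "+"), seq, n5)
            got = {p.frame: (p.sequence, p.left_len, p.right_len)
                   for p in peptides_from_junction(js)}
            assert got == _oracle_peptides(js)

    def test_retained_peptides_never_contain_stops(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=120).tolist())
            js = JunctionSequence(KEY, seq, 60)
            for p in peptides_from_junction(js):
                assert "*" not in p.sequence
                assert p.left_len >= 2 and p.right_len >= 2


class TestPeptideDb:
    peptides = [
        ChimericPeptide(KEY, 0, "TLIKPAGER", 4, 5),
        ChimericPeptide(KEY, 2, "AAGGKK", 2, 3),
    ]
    reference = {"P1": "MSSRTLIKAAAA", "P2": "MAAAPAGERAAA", "P3": "MVVVV"}

    def test_round_trip_and_header_grammar(self, tmp_path):
        path = tmp_path / "db.fa"
        write_peptide_db(self.peptides, self.reference, path)
        chimeric, reference = read_peptide_db(path)
        assert sorted(p.sequence for p in chimeric) == ["AAGGKK", "TLIKPAGER"]
        assert reference == self.reference
        key, frame, left, right = ChimericPeptide.parse_header(
            self.peptides[0].fasta_header())
        assert key == KEY and (frame, left, right) == (0, 4, 5)

    def test_empty_peptides_gives_reference_only(self, tmp_path):
        path = tmp_path / "db.fa"
        write_peptide_db([], self.reference, path)
        chimeric, reference = read_peptide_db(path)
        assert not chimeric and len(reference) == 3


class TestFilterPsms:
    peptides = [ChimericPeptide(KEY, 0, "TLIKPAGER", 4, 5),
                ChimericPeptide(KEY, 1, "WWAGGK", 1, 4)]

    def test_q_threshold_is_strict(self):
        psms = [PsmRecord("TLIKPAGER", 0.05, "s1"),
                PsmRecord("TLIKPAGER", 0.01, "s2")]
        accepted, uniques, summary = filter_psms(psms, self.peptides)
        assert [p.spectrum_id for p in accepted] == ["s2"]
        assert uniques == {"TLIKPAGER"}
        assert summary["rejected"]["q_too_high"] == 1

    def test_side_minimum_and_non_chimeric_rejection(self):
        psms = [PsmRecord("WWAGGK", 0.01, "s1"),     # left side too short
                PsmRecord("UNKNOWNPEP", 0.01, "s2")]
        accepted, _, summary = filter_psms(psms, self.peptides)
        assert not accepted
        assert summary["rejected"]["side_too_short"] == 1
        assert summary["rejected"]["non_chimeric"] == 1

    def test_planted_psm_multiplicity_recovered(self):
        """25 confident PSMs over 15 unique peptides come back as exactly
        (25, 15) after filtering."""
        rng = np.random.default_rng(0)
        db = []
        for i in range(20):
            seq = "".join(rng.choice(list("ACDEFGHILMNQSTVWY"),
                                     size=9).tolist())
            db.append(ChimericPeptide(
                ChimeraKey("A", "B", "c", 10 + i, "+", "d", 20, "+"),
                0, seq, 4, 5))
        psms = simulate_psms(db, seed=1, n_true_psms=25, n_true_peptides=15,
                             n_borderline=4, n_background=0)
        accepted, uniques, summary = filter_psms(psms, db)
        assert summary["n_psms_accepted"] == 25
        assert summary["n_unique_peptides"] == 15
        assert len(uniques) == 15


class TestSideMatchScreen:
    def test_labels(self):
        reference = {"P1": "MMMTLIKZZZ", "P2": "QQQPAGERQQ"}
        both = ChimericPeptide(KEY, 0, "TLIKZZZ", 4, 3)
        reference["P3"] = "AATLIKZZZAA"  # contiguous full peptide
        one = ChimericPeptide(KEY, 0, "TLIKWWWW", 4, 4)
        none = ChimericPeptide(KEY, 0, "YYYYXXXX", 4, 4)
        labels = side_match_screen([both, one, none], reference)
        assert labels["TLIKZZZ"] == "both_sides"
        assert labels["TLIKWWWW"] == "one_side"
        assert labels["YYYYXXXX"] == "no_hit"
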