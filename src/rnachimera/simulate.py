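"""Synthetic cohort generator with planted ground truth.

Builds a self-contained toy universe — genome, gene annotation,
transcriptome, proteome — and a chimera call cohort whose junction classes,
gene-pair classes, frame classes, splice-motif flags, decoy status,
expression ratios and per-tissue recurrence are all planted by
construction, so every pipeline stage can be validated against a truth
table without any external data.

The generator plants unambiguous cases: exon-end breakpoints are real
annotated ends, mid-exon breakpoints sit strictly inside exons away from
any annotated end, decoy junction sequences are verbatim copies of
reference transcript windows, and true junction sequences join flanks of
two different genes so no single reference transcript explains them.

Default cohort shape mirrors a large multi-tissue survey scaled to desk
size: four tissues whose sample counts (50, 150, 350, 20) exercise every
recurrence-threshold regime, junction classes dominated by M/M and pairs
by inter-chromosomal events, and recurrence enriched for E/E and
read-through chimeras.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    cds_phase,
    exon_index_of,
)
from .filters import tissue_threshold
from .io import SampleMetadata
from .model import ChimeraCall, ChimeraKey, ChimericPeptide, PsmRecord
from .sequence import downstream_flank, upstream_flank

__all__ = [
    "SimConfig",
    "PlantedChimera",
    "TruthTable",
    "Universe",
    "SimulatedCohort",
    "make_universe",
    "simulate_calls",
    "simulate_cohort",
    "simulate_psms",
    "write_cohort",
    "preset",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Mixture dictionaries must sum to 1; ``samples_per_tissue`` default
    (50, 150, 350, 20) hits the <=100, <=300 and >300 per-tissue recurrence
    regimes.  ``motif_rates`` gives per-junction-class (donor, acceptor)
    canonical splice-motif probabilities, by default mirroring the observed
    ordering EE >> EM/ME >> MM.
    """

    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 12
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (90, 240)
    intron_length: tuple[int, int] = (100, 400)
    intergenic_gap: tuple[int, int] = (1500, 6000)
    chromosome_length: Optional[int] = None
    samples_per_tissue: tuple[int, ...] = (50, 150, 350, 20)
    n_true_chimeras: int = 120
    n_decoys: int = 20
    n_low_score: int = 12
    n_missing_breakpoint: int = 5
    n_ratio_violators: int = 12
    junction_mix: dict = field(default_factory=lambda: {
        "EE": 0.04, "EM": 0.14, "ME": 0.14, "MM": 0.68})
    pair_mix: dict = field(default_factory=lambda: {
        "read_through": 0.04, "intra_other": 0.16, "inter_chromosomal": 0.80})
    frame_mix: dict = field(default_factory=lambda: {
        "in_frame": 0.25, "frame_shift": 0.35, "na": 0.40})
    motif_rates: dict = field(default_factory=lambda: {
        "EE": (0.42, 0.425), "EM": (0.155, 0.10),
        "ME": (0.06, 0.348), "MM": (0.017, 0.094)})
    junction_flank: int = 60
    p_common: float = 0.05
    p_tissue_specific: float = 0.12
    mean_extra_freq: float = 0.8
    mean_extra_freq_boosted: float = 3.5
    expr_presence: float = 0.95
    adversarial: bool = False

    def __post_init__(self) -> None:
        for name in ("junction_mix", "pair_mix", "frame_mix"):
            mix = getattr(self, name)
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative proportions")
        for name in ("n_true_chimeras", "genes_per_chromosome",
                     "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.samples_per_tissue) < 1:
            raise ValueError("every tissue needs at least one sample")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(len(self.samples_per_tissue))]


def preset(name: str, seed: int = 0) -> SimConfig:
    """Named study shapes: ``small`` (fast unit-test scale) and
    ``paper-shaped`` (the default multi-tissue cohort)."""
    if name == "small":
        return SimConfig(
            seed=seed, n_chromosomes=2, genes_per_chromosome=8,
            samples_per_tissue=(15, 8), n_true_chimeras=24,
            n_decoys=6, n_low_score=5, n_missing_breakpoint=3,
            n_ratio_violators=5,
        )
    if name in ("paper-shaped", "paper_shaped"):
        return SimConfig(seed=seed)
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# universe
# ---------------------------------------------------------------------------

@dataclass
class Universe:
    """The toy reference: genome, annotation and derived sequence sets.

    The genome is mutable until :func:`simulate_calls` has planted its
    motif edits; ``transcriptome``/``proteome`` always reflect the current
    genome state.
    """

    config: SimConfig
    annotation: GenomeAnnotation
    readthrough_pairs: list[tuple[str, str]]
    _arrays: dict[str, np.ndarray]

    @property
    def genome(self) -> dict[str, str]:
        return {c: "".join(arr.tolist()) for c, arr in self._arrays.items()}

    def transcriptome(self) -> dict[str, str]:
        genome = self.genome
        out = {}
        for gene in self.annotation.genes:
            for tx in gene.transcripts:
                chunks = []
                for s, e in tx.exons_tx_order():
                    exon = genome[tx.chrom][s:e]
                    if tx.strand == "-":
                        exon = str(Seq(exon).reverse_complement())
                    chunks.append(exon)
                out[tx.transcript_id] = "".join(chunks)
        return out

    def proteome(self) -> dict[str, str]:
        genome = self.genome
        out = {}
        for gene in self.annotation.genes:
            for tx in gene.transcripts:
                if not tx.coding:
                    continue
                chunks = []
                for s, e in tx.cds_tx_order():
                    part = genome[tx.chrom][s:e]
                    if tx.strand == "-":
                        part = str(Seq(part).reverse_complement())
                    chunks.append(part)
                cds = "".join(chunks)
                protein = str(Seq(cds).translate()).rstrip("*")
                # motif edits planted near breakpoints can turn a codon
                # into a stop; keep the longest intact segment
                if "*" in protein:
                    protein = max(protein.split("*"), key=len)
                out[tx.transcript_id] = protein
        return out

    def edit(self, chrom: str, strand: str, pos: int, rel_start: int,
             text: str) -> None:
        """Write transcript-orientation bases at offsets from a 1-based pos."""
        arr = self._arrays[chrom]
        for i, base in enumerate(text):
            offset = rel_start + i
            idx = pos - 1 + offset if strand == "+" else pos - 1 - offset
            arr[idx] = base if strand == "+" else _COMPLEMENT[base]


_STOPS = {"TAA", "TAG", "TGA"}


def _scrub_cds_stops(arr: np.ndarray, genes: Sequence[GeneModel]) -> None:
    """Rewrite in-frame stop codons inside CDS to sense codons (T->C at the
    codon start: TAA->CAA, TAG->CAG, TGA->CGA), so every annotated CDS
    translates to an intact protein as a real one would."""
    for gene in genes:
        for tx in gene.transcripts:
            if not tx.coding:
                continue
            # genomic indices of CDS bases in transcript order
            indices: list[int] = []
            for s, e in tx.cds_tx_order():
                block = range(s, e) if tx.strand == "+" else range(e - 1, s - 1, -1)
                indices.extend(block)
            for i in range(0, len(indices) - 2, 3):
                codon_idx = indices[i:i + 3]
                codon = "".join(
                    arr[j] if tx.strand == "+" else _COMPLEMENT[arr[j]]
                    for j in codon_idx)
                if codon in _STOPS:
                    j = codon_idx[0]
                    arr[j] = "C" if tx.strand == "+" else _COMPLEMENT["C"]


def make_universe(cfg: SimConfig) -> Universe:
    """Lay out genes on random chromosomes; reserve read-through pairs.

    Each gene carries one transcript whose first and last exons are UTRs
    and whose internal exons form the CDS (3'-trimmed to a codon multiple).
    Adjacent plus-strand gene pairs at regular indices are reserved as
    read-through (cis-SAGe) donors/acceptors, their intergenic gaps within
    the default proximity rule.
    """
    rng = np.random.default_rng(cfg.seed)
    lo_ex, hi_ex = cfg.exons_per_gene
    if lo_ex < 3:
        raise ValueError("genes need at least 3 exons (UTR/CDS/UTR layout)")
    genes: list[GeneModel] = []
    readthrough: list[tuple[str, str]] = []
    arrays: dict[str, np.ndarray] = {}
    gene_no = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_genes = cfg.genes_per_chromosome
        # reserve adjacent pairs (0,1), (4,5), (8,9), ... as plus-strand
        reserved: dict[int, str] = {}
        for start in range(0, n_genes - 1, 4):
            reserved[start] = "+"
            reserved[start + 1] = "+"
        cursor = int(rng.integers(*cfg.intergenic_gap))
        chrom_genes: list[GeneModel] = []
        for gi in range(n_genes):
            strand = reserved.get(gi) or rng.choice(["+", "-"])
            n_exons = int(rng.integers(lo_ex, hi_ex + 1))
            exons: list[tuple[int, int]] = []
            pos = cursor
            for xi in range(n_exons):
                length = int(rng.integers(*cfg.exon_length))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(*cfg.intron_length))
            gene_no += 1
            gene_id = f"G{gene_no:04d}"
            tx_exons = exons if strand == "+" else exons[::-1]
            cds_tx = tx_exons[1:-1]
            cds_len = sum(e - s for s, e in cds_tx)
            rem = cds_len % 3
            if rem:
                s, e = cds_tx[-1]
                cds_tx = cds_tx[:-1] + ([(s, e - rem)] if strand == "+"
                                        else [(s + rem, e)])
            tx = TranscriptModel(
                transcript_id=f"{gene_id}.t1", chrom=chrom, strand=strand,
                exons=exons, cds=sorted(cds_tx),
            )
            transcripts = [tx]
            if cfg.adversarial and rng.random() < 0.3 and n_exons > 3:
                # an isoform that skips one internal exon, creating
                # positions that are exon ends in one transcript only
                skip = int(rng.integers(1, n_exons - 1))
                alt_exons = [x for i, x in enumerate(exons) if i != skip]
                transcripts.append(TranscriptModel(
                    transcript_id=f"{gene_id}.t2", chrom=chrom,
                    strand=strand, exons=alt_exons,
                ))
            chrom_genes.append(GeneModel(
                gene_id=gene_id, symbol=f"GENE{gene_no:04d}", chrom=chrom,
                strand=strand, transcripts=transcripts,
            ))
            cursor = exons[-1][1] + int(rng.integers(*cfg.intergenic_gap))
        for start in range(0, n_genes - 1, 4):
            readthrough.append((chrom_genes[start].gene_id,
                                chrom_genes[start + 1].gene_id))
        length = cursor + 2000
        if cfg.chromosome_length is not None:
            if cursor > cfg.chromosome_length:
                raise ValueError(
                    f"{chrom}: layout needs {cursor} bp but "
                    f"chromosome_length={cfg.chromosome_length}")
            length = cfg.chromosome_length
        arrays[chrom] = rng.choice(np.array(list("ACGT")), size=length)
        genes.extend(chrom_genes)
        _scrub_cds_stops(arrays[chrom], chrom_genes)
    return Universe(
        config=cfg,
        annotation=GenomeAnnotation(genes),
        readthrough_pairs=readthrough,
        _arrays=arrays,
    )


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class PlantedChimera:
    """Ground truth for one planted record (unique key resolution)."""

    key: ChimeraKey
    kind: str  # true | decoy | low_score | missing_breakpoint | ratio_violation
    junction_class: Optional[str] = None
    pair_class: Optional[str] = None
    frame_class: Optional[str] = None
    donor_motif: Optional[bool] = None
    acceptor_motif: Optional[bool] = None
    isoform: Optional[str] = None
    tissue_counts: dict = field(default_factory=dict)
    expected_fate: str = "kept"
    expected_recurrent: bool = False
    expected_tissue_recurrent: dict = field(default_factory=dict)
    expected_common: bool = False
    expected_specific_tissue: Optional[str] = None

    @property
    def frequency(self) -> int:
        return sum(self.tissue_counts.values())


@dataclass
class TruthTable:
    records: list[PlantedChimera]

    def by_key(self) -> dict[ChimeraKey, PlantedChimera]:
        return {r.key: r for r in self.records}

    def of_kind(self, kind: str) -> list[PlantedChimera]:
        return [r for r in self.records if r.kind == kind]

    def to_json(self, path) -> None:
        payload = []
        for r in self.records:
            d = asdict(r)
            d["key"] = str(r.key)
            payload.append(d)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        records = []
        for d in payload:
            d["key"] = ChimeraKey.parse(d["key"])
            records.append(PlantedChimera(**d))
        return cls(records)


# ---------------------------------------------------------------------------
# breakpoint planting
# ---------------------------------------------------------------------------

class _Planter:
    """Chooses breakpoints realizing planted classes without ambiguity."""

    #: keep planted positions (and their 4-5 bp motif-edit windows) apart
    MIN_SPACING = 6

    def __init__(self, universe: Universe, rng: np.random.Generator):
        self.universe = universe
        self.rng = rng
        self.annotation = universe.annotation
        # (chrom, pos, side) -> planted motif flag, for reuse consistency
        self.flag_registry: dict[tuple[str, int, str], bool] = {}
        self.positions: dict[str, set[int]] = {}
        self.used_keys: set[tuple] = set()

    # -- position bookkeeping ------------------------------------------------

    def _too_close(self, chrom: str, pos: int) -> bool:
        taken = self.positions.get(chrom, ())
        return any(abs(pos - p) < self.MIN_SPACING for p in taken)

    def _register(self, chrom: str, pos: int) -> None:
        self.positions.setdefault(chrom, set()).add(pos)

    # -- candidate selection -------------------------------------------------

    def _tx(self, gene: GeneModel) -> TranscriptModel:
        return gene.transcripts[0]

    def _end_candidates(self, gene: GeneModel, side: str,
                        ) -> list[tuple[int, object]]:
        """(pos, phase) for every exon end of the primary transcript."""
        tx = self._tx(gene)
        out = []
        for s, e in tx.exons:
            if side == "donor":
                pos = e if gene.strand == "+" else s + 1
            else:
                pos = s + 1 if gene.strand == "+" else e
            out.append((pos, cds_phase(tx, pos)))
        return out

    def _pick_end(self, gene: GeneModel, side: str, need) -> Optional[int]:
        candidates = [
            (pos, phase) for pos, phase in self._end_candidates(gene, side)
            if self._matches(phase, need)
        ]
        self.rng.shuffle(candidates)
        for pos, _ in candidates:
            key = (gene.chrom, pos, side)
            if key in self.flag_registry or not self._too_close(gene.chrom, pos):
                return pos
        return None

    def _pick_mid(self, gene: GeneModel, side: str, need) -> Optional[int]:
        """A position strictly inside an exon, away from all exon ends."""
        tx = self._tx(gene)
        regions: list[tuple[int, int]] = []  # 1-based inclusive candidate spans
        if need == "noncoding" or need == "any":
            for s, e in tx.exons:
                if e - s > 2 * self.MIN_SPACING:
                    regions.append((s + 1 + self.MIN_SPACING,
                                    e - self.MIN_SPACING))
        if need != "noncoding":
            for s, e in tx.cds:
                if e - s > 2 * self.MIN_SPACING:
                    regions.append((s + 1 + self.MIN_SPACING,
                                    e - self.MIN_SPACING))
        self.rng.shuffle(regions)
        for lo, hi in regions:
            for _ in range(12):
                pos = int(self.rng.integers(lo, hi + 1))
                phase = cds_phase(tx, pos)
                if not self._matches(phase, need):
                    continue
                # middle by construction only if not an annotated end of
                # any transcript of the gene
                if self._is_any_end(gene, pos, side):
                    continue
                if self._too_close(gene.chrom, pos):
                    continue
                return pos
        return None

    @staticmethod
    def _matches(phase, need) -> bool:
        if need == "any":
            return True
        if need == "noncoding":
            return phase == "noncoding"
        if need == "any_cds":
            return isinstance(phase, int)
        return phase == need  # exact phase 0|1|2

    @staticmethod
    def _is_any_end(gene: GeneModel, pos: int, side: str) -> bool:
        for tx in gene.transcripts:
            for s, e in tx.exons:
                if side == "donor":
                    end = e if gene.strand == "+" else s + 1
                else:
                    end = s + 1 if gene.strand == "+" else e
                if pos == end:
                    return True
        return False

    def _pick_pos(self, gene: GeneModel, side: str, klass: str, need,
                  ) -> Optional[int]:
        if klass == "E":
            return self._pick_end(gene, side, need)
        return self._pick_mid(gene, side, need)

    # -- gene-pair selection -------------------------------------------------

    def _pick_pair(self, pair_class: str) -> tuple[GeneModel, GeneModel]:
        ann = self.annotation
        rng = self.rng
        if pair_class == "read_through":
            g5_id, g3_id = self.universe.readthrough_pairs[
                int(rng.integers(len(self.universe.readthrough_pairs)))]
            return ann.gene(g5_id), ann.gene(g3_id)
        if pair_class == "inter_chromosomal":
            chroms = ann.chromosomes
            if len(chroms) < 2:
                raise ValueError("inter-chromosomal pairs need >= 2 contigs")
            c5, c3 = rng.choice(chroms, size=2, replace=False)
            pool5, pool3 = ann.genes_on(str(c5)), ann.genes_on(str(c3))
            return (pool5[int(rng.integers(len(pool5)))],
                    pool3[int(rng.integers(len(pool3)))])
        # intra_other: same chromosome, opposite strands (never satisfies
        # the read-through ordering rule)
        eligible = [c for c in ann.chromosomes
                    if len({g.strand for g in ann.genes_on(c)}) == 2]
        if not eligible:
            raise ValueError("no chromosome carries both strands for "
                             "intra_other pairs")
        chrom = str(rng.choice(eligible))
        genes = ann.genes_on(chrom)
        plus = [g for g in genes if g.strand == "+"]
        minus = [g for g in genes if g.strand == "-"]
        g_plus = plus[int(rng.integers(len(plus)))]
        g_minus = minus[int(rng.integers(len(minus)))]
        if rng.random() < 0.5:
            return g_plus, g_minus
        return g_minus, g_plus

    # -- the planting entry point --------------------------------------------

    def plant(self, junction_class: str, pair_class: str, frame_class: str,
              motif_rates: Mapping[str, tuple[float, float]],
              ) -> Optional[dict]:
        """Choose breakpoints for one chimera; None when this attempt failed
        (caller retries with a fresh gene pair)."""
        g5, g3 = self._pick_pair(pair_class)
        k5, k3 = junction_class[0], junction_class[1]
        if frame_class == "na":
            nc_side = int(self.rng.integers(2))
            need5 = "noncoding" if nc_side == 0 else "any"
            need3 = "noncoding" if nc_side == 1 else "any"
            pos5 = self._pick_pos(g5, "donor", k5, need5)
            pos3 = self._pick_pos(g3, "acceptor", k3, need3)
            # "any" may have landed both sides in CDS; reject that case
            if pos5 is not None and pos3 is not None:
                ph5 = cds_phase(self._tx(g5), pos5)
                ph3 = cds_phase(self._tx(g3), pos3)
                if isinstance(ph5, int) and isinstance(ph3, int):
                    return None
        else:
            pos5 = self._pick_pos(g5, "donor", k5, "any_cds")
            if pos5 is None:
                return None
            p5 = cds_phase(self._tx(g5), pos5)
            want = (p5 + 1) % 3
            if frame_class == "frame_shift":
                want = int(self.rng.choice([(want + 1) % 3, (want + 2) % 3]))
            pos3 = self._pick_pos(g3, "acceptor", k3, want)
        if pos5 is None or pos3 is None:
            return None
        key_tuple = (g5.gene_id, pos5, g3.gene_id, pos3)
        if key_tuple in self.used_keys:
            return None
        # motif flags: reuse the registered decision at shared exon ends
        rate_d, rate_a = motif_rates.get(junction_class, (0.0, 0.0))
        donor_key = (g5.chrom, pos5, "donor")
        acceptor_key = (g3.chrom, pos3, "acceptor")
        donor_flag = self.flag_registry.get(donor_key)
        if donor_flag is None:
            donor_flag = bool(self.rng.random() < rate_d)
            self._apply_donor_edit(g5, pos5, donor_flag)
            self.flag_registry[donor_key] = donor_flag
            self._register(g5.chrom, pos5)
        acceptor_flag = self.flag_registry.get(acceptor_key)
        if acceptor_flag is None:
            acceptor_flag = bool(self.rng.random() < rate_a)
            self._apply_acceptor_edit(g3, pos3, acceptor_flag)
            self.flag_registry[acceptor_key] = acceptor_flag
            self._register(g3.chrom, pos3)
        self.used_keys.add(key_tuple)
        tx5, tx3 = self._tx(g5), self._tx(g3)
        isoform = None
        if tx5.contains_exonic(pos5) and tx3.contains_exonic(pos3):
            isoform = (f"e{exon_index_of(tx5, pos5)}"
                       f"e{exon_index_of(tx3, pos3)}")
        return {
            "gene5": g5, "gene3": g3, "pos5": pos5, "pos3": pos3,
            "donor_motif": donor_flag, "acceptor_motif": acceptor_flag,
            "isoform": isoform,
        }

    def plant_plain(self) -> Optional[dict]:
        """Breakpoints for auxiliary records (decoys, score/ratio planting):
        mid-exon positions on an inter-chromosomal pair."""
        g5, g3 = self._pick_pair("inter_chromosomal")
        pos5 = self._pick_mid(g5, "donor", "any")
        pos3 = self._pick_mid(g3, "acceptor", "any")
        if pos5 is None or pos3 is None:
            return None
        key_tuple = (g5.gene_id, pos5, g3.gene_id, pos3)
        if key_tuple in self.used_keys:
            return None
        self.used_keys.add(key_tuple)
        self._register(g5.chrom, pos5)
        self._register(g3.chrom, pos3)
        return {"gene5": g5, "gene3": g3, "pos5": pos5, "pos3": pos3}

    # -- genome edits ----------------------------------------------------------

    def _apply_donor_edit(self, gene: GeneModel, pos: int, flag: bool) -> None:
        if flag:
            self.universe.edit(gene.chrom, gene.strand, pos, -1, "AG")
            self.universe.edit(gene.chrom, gene.strand, pos, 1, "GT")
        else:
            # breaking the GT half suffices to make the motif absent
            self.universe.edit(gene.chrom, gene.strand, pos, 1, "CA")

    def _apply_acceptor_edit(self, gene: GeneModel, pos: int, flag: bool) -> None:
        if flag:
            self.universe.edit(gene.chrom, gene.strand, pos, -2, "AG")
            self.universe.edit(gene.chrom, gene.strand, pos, 0, "G")
        else:
            self.universe.edit(gene.chrom, gene.strand, pos, -2, "CC")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    calls: list[ChimeraCall]
    metadata: SampleMetadata
    expression: "object"  # pandas DataFrame (genes x samples)
    truth: TruthTable


def _plan_recurrence(rng: np.random.Generator, cfg: SimConfig,
                     junction_class: str, pair_class: str,
                     ) -> tuple[dict[str, int], str]:
    """Per-tissue planted sample counts and the plan kind."""
    tissues = cfg.tissues
    sizes = dict(zip(tissues, cfg.samples_per_tissue))
    u = rng.random()
    if u < cfg.p_common:
        counts = {t: min(tissue_threshold(sizes[t]) + int(rng.integers(0, 3)),
                         sizes[t]) for t in tissues}
        return counts, "common"
    if u < cfg.p_common + cfg.p_tissue_specific:
        t = tissues[int(rng.integers(len(tissues)))]
        n = min(tissue_threshold(sizes[t]) + int(rng.integers(0, 3)), sizes[t])
        return {t: n}, "specific"
    boosted = junction_class == "EE" or pair_class == "read_through"
    mean = cfg.mean_extra_freq_boosted if boosted else cfg.mean_extra_freq
    total = 1 + int(rng.poisson(mean))
    weights = np.array(cfg.samples_per_tissue, dtype=float)
    weights /= weights.sum()
    draws = rng.multinomial(total, weights)
    counts = {}
    for t, c in zip(tissues, draws):
        c = min(int(c), sizes[t])
        if c:
            counts[t] = c
    if not counts:
        t = tissues[int(rng.integers(len(tissues)))]
        counts[t] = 1
    return counts, "background"


def _expression_triplet(rng: np.random.Generator, violate: bool,
                        ) -> tuple[float, float, float]:
    """(chimera, gene5, gene3) read-count expressions; ``violate`` forces a
    chimera/parent ratio above 1."""
    parent5 = float(np.round(np.exp(rng.normal(3.0, 0.6)), 3))
    if violate:
        r5 = rng.uniform(1.2, 3.0)
    else:
        r5 = rng.uniform(0.02, 0.95)
    chimera = float(np.round(r5 * parent5, 3))
    r3 = rng.uniform(0.02, 0.95)
    parent3 = float(np.round(max(chimera / r3, chimera + 0.002), 3))
    return max(chimera, 0.001), parent5, parent3


def simulate_calls(cfg: SimConfig, universe: Universe) -> SimulatedCohort:
    """Plant the cohort: breakpoints, motif edits, scores, expression,
    per-tissue sample support and the truth table.

    This finalizes the universe's genome (splice-motif edits), so the
    reference transcriptome used by the identity filter must be taken from
    the universe *after* this call.
    """
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    planter = _Planter(universe, rng)
    tissues = cfg.tissues

    # sample universe
    samples: dict[str, list[str]] = {}
    meta_records = []
    idx = 0
    for t, n in zip(tissues, cfg.samples_per_tissue):
        names = []
        for i in range(n):
            sid = f"{t}.S{i + 1:03d}"
            names.append(sid)
            meta_records.append((sid, t, f"D{idx // 2:04d}"))
            idx += 1
        samples[t] = names
    metadata = SampleMetadata(meta_records)

    jclasses = list(cfg.junction_mix)
    pclasses = list(cfg.pair_mix)
    fclasses = list(cfg.frame_mix)
    records: list[PlantedChimera] = []
    placements: dict[ChimeraKey, dict] = {}

    for _ in range(cfg.n_true_chimeras):
        jc = str(rng.choice(jclasses, p=[cfg.junction_mix[c] for c in jclasses]))
        pc = str(rng.choice(pclasses, p=[cfg.pair_mix[c] for c in pclasses]))
        fc = str(rng.choice(fclasses, p=[cfg.frame_mix[c] for c in fclasses]))
        placement = None
        for _attempt in range(300):
            placement = planter.plant(jc, pc, fc, cfg.motif_rates)
            if placement is not None:
                break
        if placement is None:
            raise ValueError(
                f"class mix infeasible with this universe: could not plant "
                f"(junction={jc}, pair={pc}, frame={fc})")
        g5, g3 = placement["gene5"], placement["gene3"]
        key = ChimeraKey(g5.symbol, g3.symbol, g5.chrom, placement["pos5"],
                         g5.strand, g3.chrom, placement["pos3"], g3.strand)
        counts, _plan = _plan_recurrence(rng, cfg, jc, pc)
        records.append(PlantedChimera(
            key=key, kind="true", junction_class=jc, pair_class=pc,
            frame_class=fc, donor_motif=placement["donor_motif"],
            acceptor_motif=placement["acceptor_motif"],
            isoform=placement["isoform"],
            tissue_counts=counts, expected_fate="kept",
        ))
        placements[key] = placement

    def plant_aux(kind: str, n: int, fate: str) -> None:
        for _ in range(n):
            placement = None
            for _attempt in range(300):
                placement = planter.plant_plain()
                if placement is not None:
                    break
            if placement is None:
                raise ValueError(f"could not place auxiliary {kind} record")
            g5, g3 = placement["gene5"], placement["gene3"]
            key = ChimeraKey(g5.symbol, g3.symbol, g5.chrom,
                             placement["pos5"], g5.strand,
                             g3.chrom, placement["pos3"], g3.strand)
            t = tissues[int(rng.integers(len(tissues)))]
            records.append(PlantedChimera(
                key=key, kind=kind, tissue_counts={t: 1},
                expected_fate=fate,
            ))
            placements[key] = placement

    plant_aux("decoy", cfg.n_decoys, "removed_identity")
    plant_aux("low_score", cfg.n_low_score, "removed_low_score")
    plant_aux("missing_breakpoint", cfg.n_missing_breakpoint,
              "removed_missing_breakpoint")
    plant_aux("ratio_violation", cfg.n_ratio_violators, "removed_ratio")

    # genome is final now; derive sequences
    genome = universe.genome
    transcriptome = universe.transcriptome()
    long_txs = [t for t, s in sorted(transcriptome.items())
                if len(s) >= 2 * cfg.junction_flank + 10]
    if not long_txs:
        raise ValueError("no transcript long enough to source decoy junctions")

    sizes = dict(zip(tissues, cfg.samples_per_tissue))
    flank = cfg.junction_flank
    calls: list[ChimeraCall] = []
    for rec in records:
        k = rec.key
        if rec.kind == "decoy":
            tx = long_txs[int(rng.integers(len(long_txs)))]
            seq = transcriptome[tx]
            start = int(rng.integers(0, len(seq) - 2 * flank + 1))
            junction_seq = seq[start:start + 2 * flank]
        else:
            junction_seq = (
                upstream_flank(genome, k.chrom5, k.strand5, k.pos5, flank)
                + downstream_flank(genome, k.chrom3, k.strand3, k.pos3, flank))
        # fill recurrence-derived expectations
        rec.expected_recurrent = (rec.kind == "true"
                                  and rec.frequency >= 5)
        rec.expected_tissue_recurrent = {
            t: rec.tissue_counts.get(t, 0) >= tissue_threshold(sizes[t])
            for t in tissues} if rec.kind == "true" else {}
        rec.expected_common = (rec.kind == "true"
                               and set(rec.tissue_counts) == set(tissues))
        if rec.kind == "true":
            rec_tissues = [t for t, flag in rec.expected_tissue_recurrent.items()
                           if flag]
            if (len(rec_tissues) == 1
                    and set(rec.tissue_counts) == {rec_tissues[0]}):
                rec.expected_specific_tissue = rec_tissues[0]
        for tissue, count in sorted(rec.tissue_counts.items()):
            chosen = rng.choice(samples[tissue], size=count, replace=False)
            for sid in sorted(chosen):
                missing = rec.kind == "missing_breakpoint"
                if rec.kind == "low_score":
                    score = float(np.round(rng.uniform(0.0, 0.599), 4))
                else:
                    score = float(np.round(rng.uniform(0.6, 0.9999), 4))
                chim, e5, e3 = _expression_triplet(
                    rng, violate=rec.kind == "ratio_violation")
                calls.append(ChimeraCall(
                    sample_id=str(sid), tissue=tissue,
                    gene5=k.gene5, gene3=k.gene3,
                    chrom5=k.chrom5, pos5=0 if missing else k.pos5,
                    strand5=k.strand5,
                    chrom3=k.chrom3, pos3=0 if missing else k.pos3,
                    strand3=k.strand3,
                    junction_seq=junction_seq, score=score,
                    chimera_expr=chim, gene5_expr=e5, gene3_expr=e3,
                    missing_breakpoint=missing,
                ))
    calls.sort(key=lambda c: (c.sample_id, str(c.key)))

    expression = _expression_matrix(rng, cfg, universe, records, metadata)
    return SimulatedCohort(calls=calls, metadata=metadata,
                           expression=expression, truth=TruthTable(records))


def _expression_matrix(rng, cfg: SimConfig, universe: Universe,
                       records: Sequence[PlantedChimera],
                       metadata: SampleMetadata):
    """FPKM table for all genes: parental genes of planted chimeras are
    expressed (>= 0.04) in most samples, everything else at random."""
    import pandas as pd

    parents = set()
    for rec in records:
        if rec.kind == "true":
            parents.update(rec.key.gene_pair)
    genes = sorted(g.symbol for g in universe.annotation.genes)
    cols = sorted(metadata.samples)
    values = np.zeros((len(genes), len(cols)))
    for i, gene in enumerate(genes):
        presence = cfg.expr_presence if gene in parents else 0.5
        present = rng.random(len(cols)) < presence
        fpkm = np.round(0.04 + np.exp(rng.normal(1.0, 0.8, len(cols))), 3)
        low = np.round(rng.uniform(0.0, 0.039, len(cols)), 3)
        values[i] = np.where(present, fpkm, low)
    return pd.DataFrame(values, index=genes, columns=cols)


def simulate_cohort(cfg: SimConfig) -> tuple[Universe, SimulatedCohort]:
    """Build the universe and the cohort in one deterministic step."""
    universe = make_universe(cfg)
    cohort = simulate_calls(cfg, universe)
    return universe, cohort


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

def simulate_psms(peptide_db: Sequence[ChimericPeptide], seed: int = 0,
                  n_true_psms: int = 25, n_true_peptides: int = 15,
                  n_borderline: int = 5, n_background: int = 10,
                  reference_proteome: Optional[Mapping[str, str]] = None,
                  min_side: int = 2, q_max: float = 0.05,
                  ) -> list[PsmRecord]:
    """Synthetic PSM table over a peptide database.

    Plants ``n_true_psms`` confident chimeric PSMs collapsing onto
    ``n_true_peptides`` distinct peptides (multiplicity > 1 overall), some
    borderline chimeric PSMs at q above the cutoff, and background PSMs
    drawn from reference-proteome tryptic fragments.
    """
    from .peptides import tryptic_digest

    rng = np.random.default_rng(seed)
    eligible = sorted({p.sequence for p in peptide_db
                       if p.left_len >= min_side and p.right_len >= min_side})
    if not eligible:
        raise ValueError("peptide database has no eligible chimeric entries")
    n_pep = min(n_true_peptides, len(eligible))
    chosen = list(rng.choice(eligible, size=n_pep, replace=False))
    psms: list[PsmRecord] = []
    spectrum = 0

    def add(peptide: str, q: float) -> None:
        nonlocal spectrum
        spectrum += 1
        psms.append(PsmRecord(
            peptide=peptide, q_value=float(np.round(q, 5)),
            spectrum_id=f"spec{spectrum:05d}",
            sample_id=f"MS{spectrum % 10 + 1:02d}",
        ))

    # every chosen peptide gets one PSM; extras distributed at random
    for pep in chosen:
        add(pep, rng.uniform(0.0005, q_max * 0.9))
    for _ in range(max(n_true_psms - n_pep, 0)):
        add(str(rng.choice(chosen)), rng.uniform(0.0005, q_max * 0.9))
    for _ in range(n_borderline):
        add(str(rng.choice(eligible)), rng.uniform(q_max, 0.5))
    if reference_proteome:
        fragments = []
        for seq in sorted(reference_proteome.values()):
            fragments.extend(f for _, _, f in tryptic_digest(seq)
                             if len(f) >= 7)
        for _ in range(n_background if fragments else 0):
            add(str(rng.choice(fragments)), rng.uniform(0.0005, q_max * 0.9))
    return psms


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(universe: Universe, cohort: SimulatedCohort,
                 outdir: Union[str, Path]) -> dict[str, Path]:
    """Write every cohort artifact in its standard format."""
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "transcriptome": outdir / "transcriptome.fa",
        "proteome": outdir / "proteome.fa",
        "calls": outdir / "calls.tsv",
        "metadata": outdir / "metadata.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    rio.write_fasta(universe.genome, paths["genome"])
    rio.write_gtf(universe.annotation, paths["gtf"])
    rio.write_fasta(universe.transcriptome(), paths["transcriptome"])
    rio.write_fasta(universe.proteome(), paths["proteome"])
    rio.write_call_table(cohort.calls, paths["calls"])
    rio.write_metadata(cohort.metadata, paths["metadata"])
    rio.write_expression(cohort.expression, paths["expression"])
    cohort.truth.to_json(paths["truth"])
    return paths
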