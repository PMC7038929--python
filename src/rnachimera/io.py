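"""Readers and writers for all external file formats.

External files keep their native conventions (GTF 1-based inclusive, call
tables 1-based breakpoints); everything is converted to the internal model
at this boundary.  Every writer has a matching reader and the pair round
trips field-for-field.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, GenomeAnnotation, TranscriptModel
from .model import ChimeraCall, FusionDbRecord, PsmRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DialectError",
    "RowParseError",
    "CallTableDialect",
    "DEFAULT_DIALECT",
    "SampleMetadata",
    "read_call_table",
    "write_call_table",
    "read_gtf",
    "read_fasta",
    "write_fasta",
    "read_fusion_db",
    "write_fusion_db",
    "read_expression",
    "write_expression",
    "read_psm_table",
    "write_psm_table",
    "read_metadata",
    "write_metadata",
]

PathLike = Union[str, Path]


class DialectError(ValueError):
    """The file does not match the declared column dialect."""


class RowParseError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


#: Semantic fields every call-table dialect must map.
REQUIRED_CALL_FIELDS = (
    "sample_id", "gene5", "gene3",
    "chrom5", "pos5", "strand5",
    "chrom3", "pos3", "strand3",
    "junction_seq", "score",
    "chimera_expr", "gene5_expr", "gene3_expr",
)

#: Values in a breakpoint column treated as "no predicted breakpoint".
MISSING_TOKENS = {"", "na", "nan", "none", ".", "-"}


@dataclass(frozen=True)
class CallTableDialect:
    """Maps semantic call-table fields to source column names."""

    column_map: Mapping[str, str]
    has_header: bool = True

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_CALL_FIELDS if f not in self.column_map]
        if missing:
            raise DialectError(
                f"dialect does not map required fields: {', '.join(missing)}"
            )
        cols = list(self.column_map.values())
        if len(set(cols)) != len(cols):
            raise DialectError("dialect maps two fields to the same column")


#: Default column names follow the EricScript-style table layout.
DEFAULT_DIALECT = CallTableDialect(column_map={
    "sample_id": "Sample",
    "gene5": "GeneName1",
    "gene3": "GeneName2",
    "chrom5": "chr1",
    "pos5": "Breakpoint1",
    "strand5": "strand1",
    "chrom3": "chr2",
    "pos3": "Breakpoint2",
    "strand3": "strand2",
    "score": "EricScore",
    "junction_seq": "JunctionSequence",
    "gene5_expr": "GeneExpr1",
    "gene3_expr": "GeneExpr2",
    "chimera_expr": "GeneExpr_Fused",
})


@dataclass
class SampleMetadata:
    """Sample -> tissue -> donor mapping for a cohort."""

    records: list[tuple[str, str, str]]  # (sample_id, tissue, donor_id)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")

    @property
    def samples(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def tissues(self) -> list[str]:
        return sorted({r[1] for r in self.records})

    def tissue_of(self, sample_id: str) -> str:
        try:
            return self._tissue_map[sample_id]
        except AttributeError:
            self._tissue_map = {s: t for s, t, _ in self.records}
            return self._tissue_map[sample_id]

    def tissue_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, tissue, _ in self.records:
            counts[tissue] = counts.get(tissue, 0) + 1
        return counts

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s, t, _ in self.records if t == tissue]


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

def read_call_table(path: PathLike,
                    dialect: CallTableDialect = DEFAULT_DIALECT,
                    ) -> list[ChimeraCall]:
    """Read a fusion call table into :class:`ChimeraCall` records.

    Rows whose breakpoint fields are empty/NA come back with
    ``missing_breakpoint=True`` (and positions set to 0) rather than being
    dropped, so that the score filter can discard and account for them.
    Non-numeric garbage in a position column raises :class:`RowParseError`
    with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str,
                     header=0 if dialect.has_header else None)
    if not dialect.has_header:
        df.columns = [str(c) for c in range(df.shape[1])]
    for semantic, column in dialect.column_map.items():
        if column not in df.columns:
            raise DialectError(
                f"{path.name}: required column {column!r} "
                f"(field {semantic!r}) is missing"
            )
    calls: list[ChimeraCall] = []
    header_offset = 2 if dialect.has_header else 1
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + header_offset
        get = lambda f: row[df.columns.get_loc(dialect.column_map[f])]

        def parse_pos(fieldname: str) -> Optional[int]:
            raw = get(fieldname)
            text = "" if raw is None or pd.isna(raw) else str(raw).strip()
            if text.lower() in MISSING_TOKENS:
                return None
            try:
                value = int(float(text)) if "." in text else int(text)
            except ValueError:
                raise RowParseError(
                    f"non-integer {fieldname} value {text!r}", line
                ) from None
            if value < 1:
                raise RowParseError(
                    f"{fieldname} must be a positive 1-based coordinate, "
                    f"got {value}", line
                )
            return value

        def parse_float(fieldname: str) -> float:
            raw = get(fieldname)
            text = "" if raw is None or pd.isna(raw) else str(raw).strip()
            if text.lower() in MISSING_TOKENS:
                return 0.0
            try:
                return float(text)
            except ValueError:
                raise RowParseError(
                    f"non-numeric {fieldname} value {text!r}", line
                ) from None

        pos5, pos3 = parse_pos("pos5"), parse_pos("pos3")
        missing = pos5 is None or pos3 is None
        calls.append(ChimeraCall(
            sample_id=str(get("sample_id")),
            gene5=str(get("gene5")),
            gene3=str(get("gene3")),
            chrom5=str(get("chrom5")),
            pos5=pos5 or 0,
            strand5=str(get("strand5")),
            chrom3=str(get("chrom3")),
            pos3=pos3 or 0,
            strand3=str(get("strand3")),
            junction_seq=str(get("junction_seq")),
            score=parse_float("score"),
            chimera_expr=parse_float("chimera_expr"),
            gene5_expr=parse_float("gene5_expr"),
            gene3_expr=parse_float("gene3_expr"),
            missing_breakpoint=missing,
        ))
    return calls


def write_call_table(calls: Sequence[ChimeraCall], path: PathLike,
                     dialect: CallTableDialect = DEFAULT_DIALECT) -> None:
    rows = []
    for c in calls:
        row = {}
        for semantic, column in dialect.column_map.items():
            value = getattr(c, semantic)
            if semantic in ("pos5", "pos3") and c.missing_breakpoint:
                value = ""
            row[column] = value
        rows.append(row)
    columns = [dialect.column_map[f] for f in REQUIRED_CALL_FIELDS]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: PathLike) -> GenomeAnnotation:
    """Read an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Exon features are mandatory; CDS features mark transcripts coding.
    GTF 1-based inclusive coordinates become internal 0-based half-open.
    Duplicate exon lines are deduplicated (with a logged warning count).
    """
    import gffutils

    path = Path(path)
    with open(path) as fh:
        has_content = any(line.strip() and not line.startswith("#")
                          for line in fh)
    if not has_content:
        return GenomeAnnotation([])

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene_id, chrom, strand)
    gene_symbols: dict[str, str] = {}
    duplicates = 0
    for feature in db.all_features():
        gene_id = (feature.attributes.get("gene_id") or [None])[0]
        if gene_id is None:
            raise ValueError(
                f"{feature.featuretype} feature at {feature.seqid}:"
                f"{feature.start} lacks gene_id")
        name = feature.attributes.get("gene_name")
        if name:
            gene_symbols.setdefault(gene_id, name[0])
        if feature.featuretype == "gene":
            continue
        if feature.featuretype not in ("transcript", "exon", "CDS"):
            continue
        tx_id = (feature.attributes.get("transcript_id") or [None])[0]
        if tx_id is None:
            raise ValueError(
                f"{feature.featuretype} feature at {feature.seqid}:"
                f"{feature.start} lacks transcript_id")
        tx_meta.setdefault(tx_id, (gene_id, feature.seqid, feature.strand))
        if feature.featuretype == "transcript":
            continue
        interval = (feature.start - 1, feature.end)
        bucket = exons if feature.featuretype == "exon" else cds
        existing = bucket.setdefault(tx_id, [])
        if interval in existing:
            duplicates += 1
        else:
            existing.append(interval)
    if duplicates:
        logger.warning("read_gtf(%s): deduplicated %d duplicate feature lines",
                       path.name, duplicates)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_info: dict[str, tuple[str, str]] = {}
    for tx_id, (gene_id, chrom, strand) in tx_meta.items():
        if tx_id not in exons:
            raise ValueError(f"transcript {tx_id} has no exon features")
        model = TranscriptModel(
            transcript_id=tx_id, chrom=chrom, strand=strand,
            exons=exons[tx_id], cds=cds.get(tx_id, []),
        )
        genes.setdefault(gene_id, []).append(model)
        gene_info[gene_id] = (chrom, strand)

    gene_models = [
        GeneModel(
            gene_id=gid,
            symbol=gene_symbols.get(gid, gid),
            chrom=gene_info[gid][0],
            strand=gene_info[gid][1],
            transcripts=sorted(txs, key=lambda t: t.transcript_id),
        )
        for gid, txs in sorted(genes.items())
    ]
    return GenomeAnnotation(gene_models)


def write_gtf(annotation: GenomeAnnotation, path: PathLike,
              source: str = "rnachimera") -> None:
    """Write a GenomeAnnotation back out as Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for gene in annotation.genes:
            s, e = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}";'
            fh.write("\t".join([
                gene.chrom, source, "gene", str(s + 1), str(e),
                ".", gene.strand, ".", attrs]) + "\n")
            for tx in gene.transcripts:
                ts, te = tx.span
                tattrs = (f'gene_id "{gene.gene_id}"; '
                          f'transcript_id "{tx.transcript_id}"; '
                          f'gene_name "{gene.symbol}";')
                fh.write("\t".join([
                    gene.chrom, source, "transcript", str(ts + 1), str(te),
                    ".", gene.strand, ".", tattrs]) + "\n")
                for xs, xe in tx.exons:
                    fh.write("\t".join([
                        gene.chrom, source, "exon", str(xs + 1), str(xe),
                        ".", gene.strand, ".", tattrs]) + "\n")
                for cs, ce in tx.cds:
                    fh.write("\t".join([
                        gene.chrom, source, "CDS", str(cs + 1), str(ce),
                        ".", gene.strand, "0", tattrs]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """FASTA -> {id: uppercased sequence}; ids cut at first whitespace."""
    store: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in store:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        store[record.id] = str(record.seq).upper()
    return store


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: PathLike, width: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# fusion databases
# ---------------------------------------------------------------------------

FUSION_DB_COLUMNS = ["gene5", "gene3", "transcript5", "transcript3",
                     "mrna_breakpoint5", "mrna_breakpoint3"]


def read_fusion_db(path: PathLike, kind: str = "generic") -> list[FusionDbRecord]:
    """Read a cancer fusion-database TSV.

    ``kind`` labels provenance (cosmic, mitelman, ticdb, generic).  Records
    with both transcripts and both mRNA breakpoints present report
    ``has_breakpoint=True`` (COSMIC-style); gene-pair-only records
    (Mitelman/TICdb-style) report False.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FUSION_DB_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise DialectError(f"fusion db missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        def opt(col: str) -> Optional[str]:
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or pd.isna(v) or str(v).strip().lower() in MISSING_TOKENS:
                return None
            return str(v).strip()

        def opt_int(col: str) -> Optional[int]:
            v = opt(col)
            if v is None:
                return None
            try:
                return int(v)
            except ValueError:
                raise RowParseError(
                    f"non-integer {col} value {v!r}", int(idx) + 2
                ) from None

        records.append(FusionDbRecord(
            source=kind,
            gene5=str(row["gene5"]), gene3=str(row["gene3"]),
            tx5=opt("transcript5"), tx3=opt("transcript3"),
            mrna_pos5=opt_int("mrna_breakpoint5"),
            mrna_pos3=opt_int("mrna_breakpoint3"),
        ))
    return records


def write_fusion_db(records: Sequence[FusionDbRecord], path: PathLike) -> None:
    rows = [{
        "gene5": r.gene5, "gene3": r.gene3,
        "transcript5": r.tx5 or "", "transcript3": r.tx3 or "",
        "mrna_breakpoint5": "" if r.mrna_pos5 is None else r.mrna_pos5,
        "mrna_breakpoint3": "" if r.mrna_pos3 is None else r.mrna_pos3,
    } for r in records]
    pd.DataFrame(rows, columns=FUSION_DB_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices, PSM tables, sample metadata
# ---------------------------------------------------------------------------

def read_expression(path: PathLike) -> pd.DataFrame:
    """Gene x sample FPKM matrix; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.dtypes.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise RowParseError(
            f"non-numeric expression values in columns {list(bad)}", 2)
    df.index = df.index.astype(str)
    return df


def write_expression(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


PSM_COLUMNS = ["peptide", "q_value", "spectrum_id", "sample_id"]


def read_psm_table(path: PathLike) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PSM_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise DialectError(f"PSM table missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            q = float(row["q_value"])
        except (TypeError, ValueError):
            raise RowParseError(
                f"non-numeric q_value {row['q_value']!r}", int(idx) + 2
            ) from None
        records.append(PsmRecord(
            peptide=str(row["peptide"]),
            q_value=q,
            spectrum_id=str(row["spectrum_id"]),
            sample_id=str(row.get("sample_id", "") or ""),
        ))
    return records


def write_psm_table(records: Sequence[PsmRecord], path: PathLike) -> None:
    rows = [{"peptide": r.peptide, "q_value": r.q_value,
             "spectrum_id": r.spectrum_id, "sample_id": r.sample_id}
            for r in records]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path: PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "tissue", "donor_id"):
        if col not in df.columns:
            raise DialectError(f"metadata missing column {col!r}")
    return SampleMetadata(records=[
        (str(r.sample_id), str(r.tissue), str(r.donor_id))
        for r in df.itertuples(index=False)
    ])


def write_metadata(metadata: SampleMetadata, path: PathLike) -> None:
    pd.DataFrame(metadata.records,
                 columns=["sample_id", "tissue", "donor_id"]
                 ).to_csv(path, sep="\t", index=False)
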