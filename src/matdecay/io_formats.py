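"""Readers, writers and core containers for the pipeline's external formats.

All genomic coordinates are 0-based half-open internally; GFF3's 1-based
closed intervals are converted at the parse/serialize boundary only.
Sequences are normalized to the DNA alphabet (U -> T, upper case) at parse
time so that small RNAs (reported as RNA) and genomic/transcript sequence
(DNA) live in one alphabet. ``N`` never matches anything downstream.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "StageExpressionMatrix",
    "SequenceSet",
    "GeneModel",
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models_gff3",
    "read_tsv",
    "write_tsv",
    "reverse_complement",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement on the internal {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# StageExpressionMatrix
# ---------------------------------------------------------------------------


class StageExpressionMatrix:
    """Genes x developmental stages on the linear FPKM scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one numeric column per stage,
        in stage order (e.g. MII, 2C, 4C). All entries must be >= 0.
    condition
        Free-text label for the series, e.g. ``control``, ``knockdown``
        or ``DRB``.
    """

    def __init__(self, values: pd.DataFrame, condition: str = "control"):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if len(values.columns) == 0:
            raise FormatError("no stage columns")
        if values.columns.has_duplicates:
            raise FormatError("duplicate stage names")
        vals = values.to_numpy(dtype=float, copy=False)
        if vals.size and not np.all(np.isfinite(vals)):
            raise FormatError("non-finite expression values")
        if vals.size and (vals < 0).any():
            raise FormatError("negative FPKM values")
        self.values = values.astype(float)
        self.condition = condition

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def require_stages(self, stages: Iterable[str]) -> None:
        missing = [s for s in stages if s not in self.values.columns]
        if missing:
            raise FormatError(
                f"stage(s) {missing} absent from {self.condition} matrix "
                f"(has {self.stage_names})"
            )

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(FPKM + pseudocount), the scale all decay rules operate on."""
        return np.log2(self.values + pseudocount)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StageExpressionMatrix)
            and self.condition == other.condition
            and self.values.equals(other.values)
        )


def read_expression_table(
    path: str | os.PathLike | io.TextIOBase,
    stage_columns: Sequence[str] | None = None,
    condition: str = "control",
    gene_column: str | None = None,
) -> StageExpressionMatrix:
    """Read a TSV with one row per gene into a :class:`StageExpressionMatrix`.

    The first column is taken as the gene id unless ``gene_column`` names
    one. ``stage_columns`` restricts and orders the stage columns; by
    default every non-id column is used in file order. Lines starting with
    ``#`` are comments.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"no records in expression table {path!r}") from None
    if df.empty and df.columns.size == 0:
        raise FormatError(f"no records in expression table {path!r}")
    id_col = gene_column if gene_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise FormatError(f"gene id column {id_col!r} missing")
    if stage_columns is None:
        stage_columns = [c for c in df.columns if c != id_col]
    missing = [c for c in stage_columns if c not in df.columns]
    if missing:
        raise FormatError(f"missing stage column(s): {missing}")
    sub = df[list(stage_columns)]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        rows = numeric.isna().any(axis=1).to_numpy().nonzero()[0]
        raise FormatError(
            f"non-numeric expression value(s) at data row(s) {rows[:5].tolist()}"
        )
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id(s): {sorted(set(dup))[:5]}")
    numeric.index = pd.Index(df[id_col].astype(str), name="gene_id")
    return StageExpressionMatrix(numeric, condition=condition)


def write_expression_table(
    matrix: StageExpressionMatrix,
    path: str | os.PathLike,
    header_comments: Mapping[str, object] | None = None,
) -> None:
    """Write a matrix as TSV; floats use repr precision so reads round-trip."""
    with open(path, "w") as fh:
        _write_comment_header(fh, header_comments)
        matrix.values.rename_axis("gene_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# SequenceSet
# ---------------------------------------------------------------------------


@dataclass
class SequenceSet:
    """An ordered id -> sequence mapping over {A,C,G,T,N}.

    ``kind`` records what the sequences are (transcript, lncRNA, smallRNA,
    promoter); small-RNA sets admit lengths 15-35 at parse, stricter length
    filtering happens downstream.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    kind: str = "transcript"

    def __post_init__(self):
        for sid, seq in self.sequences.items():
            self._validate(sid, seq)

    def _validate(self, sid: str, seq: str) -> None:
        if not seq:
            raise FormatError(f"empty sequence for id {sid!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(f"invalid characters {sorted(bad)} in {sid!r}")
        if self.kind == "smallRNA" and not (15 <= len(seq) <= 35):
            raise FormatError(
                f"smallRNA {sid!r} length {len(seq)} outside admissible 15-35 nt"
            )

    def add(self, sid: str, seq: str) -> None:
        if sid in self.sequences:
            raise FormatError(f"duplicate sequence id {sid!r}")
        seq = normalize_sequence(seq)
        self._validate(sid, seq)
        self.sequences[sid] = seq

    def ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        keep = set(ids)
        return SequenceSet(
            {k: v for k, v in self.sequences.items() if k in keep}, kind=self.kind
        )

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def items(self):
        return self.sequences.items()


def normalize_sequence(seq: str) -> str:
    """Upper-case and map U->T (RNA input is stored on the DNA alphabet)."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike, kind: str = "transcript") -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`; ids are cut at first whitespace."""
    out = SequenceSet({}, kind=kind)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        out.add(rec.id, str(rec.seq))
        n += 1
    if n == 0:
        raise FormatError(f"no FASTA records in {path!r}")
    return out


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene locus in internal 0-based half-open coordinates.

    The TSS is the span start on the + strand and ``span_end - 1`` on the
    - strand. ``cds`` intervals (optional) distinguish coding from UTR
    exonic sequence for context annotation.
    """

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"unknown strand {self.strand!r} for gene {self.gene_id!r}"
            )
        s, e = self.span
        if not (0 <= s < e):
            raise FormatError(f"invalid span {self.span} for {self.gene_id!r}")
        self.exons = sorted(self.exons)
        for (a, b) in self.exons:
            if a < s or b > e:
                raise FormatError(
                    f"exon [{a},{b}) outside gene span {self.span} for {self.gene_id!r}"
                )
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise FormatError(f"overlapping exons in {self.gene_id!r}")
        self.cds = sorted(self.cds)

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b < c:
                out.append((b, c))
        return out


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from GFF3 (by content/extension) or BED.

    GFF3 gene features with child exon/CDS features become one
    :class:`GeneModel` each; a BED line becomes an intronless gene whose
    span is the BED interval (BED is already 0-based half-open).
    """
    path = str(path)
    if path.endswith((".bed", ".bed.gz")):
        return _read_bed(path)
    return _read_gff3(path)


def _read_bed(path: str) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i + 1}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"bed_{i + 1}"
            strand = parts[5] if len(parts) > 5 else "+"
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    span=(start, end),
                    exons=[(start, end)],
                )
            )
    return models


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        # GFF3 is 1-based closed; internal is 0-based half-open.
        span = (gene.start - 1, gene.end)
        exons = [
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        ]
        cds = [(f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                span=span,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gene_models_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Serialize gene models back to GFF3 (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            s, e = gm.span
            fh.write(
                f"{gm.chrom}\tmatdecay\tgene\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID={gm.gene_id}\n"
            )
            for i, (a, b) in enumerate(gm.exons, 1):
                fh.write(
                    f"{gm.chrom}\tmatdecay\texon\t{a + 1}\t{b}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                )
            for i, (a, b) in enumerate(gm.cds, 1):
                fh.write(
                    f"{gm.chrom}\tmatdecay\tCDS\t{a + 1}\t{b}\t.\t{gm.strand}\t0\t"
                    f"ID={gm.gene_id}.cds{i};Parent={gm.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Generic TSV plumbing
# ---------------------------------------------------------------------------


def _write_comment_header(fh, comments: Mapping[str, object] | None) -> None:
    if comments:
        for key, val in comments.items():
            fh.write(f"# {key}={val}\n")


def write_tsv(
    df: pd.DataFrame,
    path: str | os.PathLike,
    header_comments: Mapping[str, object] | None = None,
    float_format: str | None = None,
) -> None:
    """Write a DataFrame as TSV with an optional ``# key=value`` header."""
    with open(path, "w") as fh:
        _write_comment_header(fh, header_comments)
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
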