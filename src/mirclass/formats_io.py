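"""Readers and writers for every external representation the pipeline touches.

Sequences arrive as FASTA (miRBase dialect: the first whitespace-delimited
header token is the miRNA id; T is silently normalized to U since DNA-style
FASTA is common for miRNA).  Gene-target and pathway annotations are
tab-separated tables with a mandatory header, mirroring the shape of batch
exports from target-prediction and functional-annotation services.  Feature
tables are exported as CSV and as ARFF (the native format of the WEKA
workbench); both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    KIND_DESCRIPTOR,
    KIND_GENE,
    KIND_PATHWAY,
    LABEL_RANDOM,
    LABEL_SELECTED,
    LABEL_UNLABELED,
    AnnotationSet,
    FeatureTable,
    MiRNARecord,
    PathwayRecord,
    SchemaError,
    TargetRecord,
)

GENE_PREFIX = "gene_"
PATHWAY_PREFIX = "pw_"
CLASS_ATTR = "class"


class FastaParseError(ValueError):
    """Structural FASTA problem; the message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[MiRNARecord]:
    """Read a miRNA FASTA file into records, in file order.

    Sequences are uppercased and T is mapped to U; records come back
    unlabeled.  Malformed headers and empty sequences raise
    :class:`FastaParseError` naming the line; characters outside ACGU(T)
    raise an alphabet error naming the record id.
    """
    path = Path(path)
    header_lines: list[int] = []
    first_content: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if first_content is None:
                first_content = lineno
                if not stripped.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header, "
                        f"got {stripped[:30]!r}"
                    )
            if stripped.startswith(">"):
                header_lines.append(lineno)
                if stripped == ">":
                    raise FastaParseError(f"{path}: line {lineno}: empty FASTA header")
    records: list[MiRNARecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines[i]
        if len(rec.seq) == 0:
            raise FastaParseError(
                f"{path}: line {lineno}: record {rec.id!r} has an empty sequence"
            )
        if rec.id in seen:
            raise FastaParseError(
                f"{path}: line {lineno}: duplicate miRNA id {rec.id!r}"
            )
        seen.add(rec.id)
        records.append(
            MiRNARecord(mirna_id=rec.id, sequence=_normalize_sequence(str(rec.seq)))
        )
    return records


def write_fasta(records: list[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.mirna_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# annotation tables (TSV)

TARGET_COLUMNS = ("mirna_id", "gene", "score")
PATHWAY_COLUMNS = ("mirna_id", "pathway_id", "p_value")


def _read_tsv(path: str | Path, columns: tuple[str, ...], numeric_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    values = pd.to_numeric(df[numeric_col], errors="coerce")
    bad = df.index[values.isna()]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ValueError(
            f"{path}: line {bad[0] + 2}: cannot parse {numeric_col} value "
            f"{df.loc[bad[0], numeric_col]!r}"
        )
    df[numeric_col] = values
    return df


def read_annotations(targets_path: str | Path, pathways_path: str | Path) -> AnnotationSet:
    """Read gene-target and pathway tables into an :class:`AnnotationSet`.

    Duplicate (miRNA, gene) rows keep the maximum score; duplicate
    (miRNA, pathway) rows keep the minimum p-value.  First-appearance order
    is preserved.
    """
    tdf = _read_tsv(targets_path, TARGET_COLUMNS, "score")
    tdf = (
        tdf.groupby(["mirna_id", "gene"], sort=False, as_index=False)
        .agg(score=("score", "max"))
    )
    pdf = _read_tsv(pathways_path, PATHWAY_COLUMNS, "p_value")
    pdf = (
        pdf.groupby(["mirna_id", "pathway_id"], sort=False, as_index=False)
        .agg(p_value=("p_value", "min"))
    )
    targets = [
        TargetRecord(r.mirna_id, r.gene, float(r.score)) for r in tdf.itertuples()
    ]
    pathways = [
        PathwayRecord(r.mirna_id, r.pathway_id, float(r.p_value))
        for r in pdf.itertuples()
    ]
    return AnnotationSet(targets=targets, pathways=pathways)


def write_annotations(ann: AnnotationSet, targets_path: str | Path, pathways_path: str | Path) -> None:
    with open(targets_path, "w") as fh:
        fh.write("\t".join(TARGET_COLUMNS) + "\n")
        for t in ann.targets:
            fh.write(f"{t.mirna_id}\t{t.gene}\t{t.score}\n")
    with open(pathways_path, "w") as fh:
        fh.write("\t".join(PATHWAY_COLUMNS) + "\n")
        for p in ann.pathways:
            fh.write(f"{p.mirna_id}\t{p.pathway_id}\t{p.p_value}\n")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna_id", "label"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return dict(zip(df["mirna_id"], df["label"]))


def write_labels(records: list[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tlabel\n")
        for rec in records:
            fh.write(f"{rec.mirna_id}\t{rec.label}\n")


def apply_labels(records: list[MiRNARecord], labels: dict[str, str]) -> list[MiRNARecord]:
    return [
        MiRNARecord(r.mirna_id, r.sequence, labels.get(r.mirna_id, LABEL_UNLABELED))
        for r in records
    ]


# ---------------------------------------------------------------------------
# ARFF

def _is_nominal(name: str, kind: str) -> bool:
    # one-hot columns: gene/pathway indicators and tetramer presence flags
    return kind in (KIND_GENE, KIND_PATHWAY) or name.startswith("motif_")


def _quote(name: str) -> str:
    return f"'{name}'" if any(c in name for c in " ,{}%") else name


def write_arff(table: FeatureTable, path: str | Path, relation: str = "mirna_cohort") -> None:
    """Write a feature table as an ARFF document.

    Numeric descriptors become numeric attributes, one-hot columns become
    nominal {0,1} attributes, and the class attribute {selected,random} comes
    last.  ``read_arff`` reproduces the table exactly.
    """
    if table.n_rows < 1 or table.n_features < 1:
        raise ValueError("cannot write an empty feature table")
    lines = [f"@relation {relation}", ""]
    for name, kind in zip(table.feature_names, table.column_kinds):
        if _is_nominal(name, kind):
            lines.append(f"@attribute {_quote(name)} {{0,1}}")
        else:
            lines.append(f"@attribute {_quote(name)} numeric")
    lines.append(f"@attribute {CLASS_ATTR} {{{LABEL_SELECTED},{LABEL_RANDOM}}}")
    lines.append("")
    lines.append("@data")
    for i in range(table.n_rows):
        cells = []
        for j, (name, kind) in enumerate(zip(table.feature_names, table.column_kinds)):
            v = table.matrix[i, j]
            cells.append(str(int(v)) if _is_nominal(name, kind) else repr(float(v)))
        cells.append(table.labels[i])
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _kind_from_name(name: str) -> str:
    if name.startswith(GENE_PREFIX):
        return KIND_GENE
    if name.startswith(PATHWAY_PREFIX):
        return KIND_PATHWAY
    return KIND_DESCRIPTOR


def read_arff(path: str | Path) -> FeatureTable:
    """Read back an ARFF document written by :func:`write_arff`."""
    names: list[str] = []
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            rest = line.split(None, 1)[1]
            attr = rest.split(None, 1)[0].strip("'")
            names.append(attr)
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            cells = line.split(",")
            if len(cells) != len(names):
                raise ValueError(f"{path}: data row has {len(cells)} cells, "
                                 f"expected {len(names)}")
            rows.append([float(c) for c in cells[:-1]])
            labels.append(cells[-1])
    if not names or names[-1] != CLASS_ATTR:
        raise ValueError(f"{path}: class attribute must be last")
    feature_names = names[:-1]
    return FeatureTable(
        row_ids=[f"row{i}" for i in range(len(rows))],
        feature_names=feature_names,
        matrix=np.array(rows, dtype=float),
        labels=labels,
        column_kinds=[_kind_from_name(n) for n in feature_names],
    )


# ---------------------------------------------------------------------------
# CSV feature table


def write_table_csv(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.matrix, columns=table.feature_names, index=table.row_ids)
    df.index.name = "mirna_id"
    df[CLASS_ATTR] = table.labels
    df.to_csv(path)


def read_table_csv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="mirna_id")
    labels = df.pop(CLASS_ATTR).tolist()
    names = df.columns.tolist()
    return FeatureTable(
        row_ids=[str(i) for i in df.index],
        feature_names=names,
        matrix=df.to_numpy(dtype=float),
        labels=labels,
        column_kinds=[_kind_from_name(n) for n in names],
    )


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
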