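"""Tab-delimited readers and writers for all pipeline artifacts.

Formats (all UTF-8, tab-delimited, one header row):

* expression matrix — first column ``probe_id``, remaining columns one per
  sample id, cells are log2 intensities;
* annotation — columns probe_id, entry_id, gene_symbol, chrom_class, chrom,
  start, stop, feature_class, ensembl_id (empty start/stop for unmapped);
* sample table — sample_id, sex, tissue;
* escapee list — one gene symbol per line, ``#`` comments allowed;
* branch table — gene_key, branch.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .model import (
    ANNOTATION_COLUMNS,
    AnnotationTable,
    BranchTable,
    EscapeeList,
    ExpressionMatrix,
    SampleTable,
)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a probes x samples log2 matrix, preserving row/column order.

    Raises :class:`FormatError` naming the offending line for duplicate ids,
    ragged rows or non-numeric cells.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "probe_id":
            raise FormatError(f"{path}: first header column must be 'probe_id'")
        sample_ids = header[1:]
        n_cols = len(header)
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} fields, found {len(row)}"
                )
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            probe_ids.append(row[0])
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        for i, pid in enumerate(probe_ids):
            if pid in seen:
                raise FormatError(f"{path}:{i + 2}: duplicate probe id {pid!r}")
            seen.add(pid)
    data = pd.DataFrame(
        np.asarray(rows, dtype=float), index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_ids,
    )
    return ExpressionMatrix(data)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read probe annotation; unmapped probes (empty chrom) get chrom_class NA."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    df = df[list(ANNOTATION_COLUMNS)]
    df.loc[df["chrom"] == "", "chrom_class"] = "NA"
    df["chrom_class"] = df["chrom_class"].replace("", "NA")
    for col in ("start", "stop"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "", np.nan), errors="raise")
    df = df.set_index("probe_id")
    return AnnotationTable(df)


def write_annotation(ann: AnnotationTable, path: str | Path) -> None:
    df = ann.df.copy()
    for col in ("start", "stop"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_escapees(path: str | Path) -> EscapeeList:
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    return EscapeeList(frozenset(symbols))


def write_escapees(esc: EscapeeList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(esc.gene_symbols)) + "\n")


def read_branches(path: str | Path) -> BranchTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_key": str, "branch": int})
    missing = {"gene_key", "branch"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing branch-table columns {sorted(missing)}")
    series = df.set_index("gene_key")["branch"]
    return BranchTable(series)


def write_branches(branches: BranchTable, path: str | Path) -> None:
    df = branches.branches.rename("branch").rename_axis("gene_key").reset_index()
    df.to_csv(path, sep="\t", index=False)
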