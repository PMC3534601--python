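"""Shared data model: expression matrices, sample tables, probe annotation.

The in-memory containers are thin, validated wrappers around pandas objects.
All expression values are log2 intensities; genomic coordinates are 1-based
inclusive throughout the package (matching probe-alignment extents), and all
gap arithmetic uses that convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, MetadataError

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

CHROM_CLASSES = ("A", "X", "Y", "NA")

#: Annotation columns, in canonical file order.
ANNOTATION_COLUMNS = (
    "probe_id",
    "entry_id",
    "gene_symbol",
    "chrom_class",
    "chrom",
    "start",
    "stop",
    "feature_class",
    "ensembl_id",
)

FEATURE_CLASSES = ("gene", "intron", "intergenic")


@dataclass(frozen=True)
class SampleTable:
    """Sample metadata: one row per array (sample_id, sex, tissue)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "tissue"}
        missing = required - set(self.df.columns)
        if missing:
            raise MetadataError(f"sample table missing columns: {sorted(missing)}")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise MetadataError(f"duplicate sample ids: {sorted(set(dups))[:5]}")
        bad = set(self.df["sex"]) - set(SEXES)
        if bad:
            raise MetadataError(f"unknown sex labels: {sorted(bad)}")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.df["tissue"]))

    def for_tissue(self, tissue: str) -> "SampleTable":
        return SampleTable(self.df[self.df["tissue"] == tissue].reset_index(drop=True))

    def sex_of(self, sample_ids: Iterable[str]) -> pd.Series:
        """Sex label per sample id, raising if any id is unannotated."""
        lookup = self.df.set_index("sample_id")["sex"]
        ids = list(sample_ids)
        missing = [s for s in ids if s not in lookup.index]
        if missing:
            raise MetadataError(f"samples without sex annotation: {missing[:5]}")
        return lookup.loc[ids]

    def require_two_per_sex(self, tissue: str) -> None:
        sub = self.df[self.df["tissue"] == tissue]
        counts = sub["sex"].value_counts()
        for sex in SEXES:
            if counts.get(sex, 0) < 2:
                raise MetadataError(
                    f"tissue {tissue!r} has {counts.get(sex, 0)} {sex} samples; "
                    "need at least 2 of each sex"
                )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probes x samples log2 intensity matrix for one tissue.

    ``data`` is a float DataFrame indexed by probe_id with sample_id columns.
    Invariants: unique ids, finite values, no missing cells.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()]
            raise FormatError(f"duplicate probe ids: {sorted(set(dups))[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()]
            raise FormatError(f"duplicate sample ids: {sorted(set(dups))[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise FormatError(f"{n_bad} non-finite expression values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def standardize(
    m: ExpressionMatrix, target_mean: float = 8.0, target_sd: float = 2.0
) -> ExpressionMatrix:
    """Affinely rescale the pooled matrix to the target mean and SD.

    A single affine transform of all values (not per probe or per array):
    the whole dataset is shifted and scaled so the pooled mean equals
    ``target_mean`` (default 8) and the pooled SD equals ``target_sd``
    (default 2). The pooled SD uses ddof=0 over every cell.
    """
    values = m.values
    if values.size == 0:
        raise DegenerateInputError("cannot standardize an empty matrix")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        raise DegenerateInputError("pooled SD is zero; matrix is constant")
    scaled = (values - mean) * (target_sd / sd) + target_mean
    out = pd.DataFrame(scaled, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out)


@dataclass(frozen=True)
class AnnotationTable:
    """Probe annotation: genomic mapping and gene-level grouping per probe.

    Indexed by probe_id with columns entry_id, gene_symbol, chrom_class
    (A/X/Y/NA), chrom, start, stop (1-based inclusive, NaN when unmapped),
    feature_class (gene/intron/intergenic) and ensembl_id.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.name != "probe_id":
            raise FormatError("annotation must be indexed by probe_id")
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()]
            raise FormatError(f"duplicate probe ids in annotation: {sorted(set(dups))[:5]}")
        bad = set(self.df["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise FormatError(f"unknown chrom_class tokens: {sorted(bad)}")
        both = self.df[["start", "stop"]].notna().all(axis=1)
        inverted = both & (self.df["start"] > self.df["stop"])
        if inverted.any():
            raise FormatError(
                f"start > stop for probes: {list(self.df.index[inverted])[:5]}"
            )

    def classes_of(self, probe_ids: Iterable[str]) -> pd.Series:
        ids = list(probe_ids)
        missing = [p for p in ids if p not in self.df.index]
        if missing:
            raise MetadataError(f"probes missing from annotation: {missing[:5]}")
        return self.df.loc[ids, "chrom_class"]

    def subset(self, probe_ids: Iterable[str]) -> "AnnotationTable":
        return AnnotationTable(self.df.loc[list(probe_ids)])


@dataclass(frozen=True)
class EscapeeList:
    """Symbols of genes known to escape X-chromosome inactivation."""

    gene_symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise MetadataError("escapee list is empty")

    def matches(self, label: str) -> bool:
        """True if any whitespace/paren-delimited token of ``label`` is listed.

        Table-style gene labels may carry aliases in parentheses, e.g.
        ``2010000I03Rik (Jpx)``; either name matches.
        """
        tokens = label.replace("(", " ").replace(")", " ").split()
        return any(t in self.gene_symbols for t in tokens)


@dataclass(frozen=True)
class BranchTable:
    """Gene -> phylogenetic branch (0-11) assignment.

    Branches 0-5 predate the placental-mammal radiation (>100 myr);
    branches 6-11 are younger. Keys are Ensembl ids or gene symbols.
    """

    branches: pd.Series  # index gene_key, values int 0..11

    def __post_init__(self) -> None:
        if self.branches.index.duplicated().any():
            dups = self.branches.index[self.branches.index.duplicated()]
            raise FormatError(f"duplicate gene keys in branch table: {sorted(set(dups))[:5]}")
        vals = self.branches.to_numpy()
        if vals.size and ((vals < 0) | (vals > 11)).any():
            raise FormatError("branch labels must be integers in 0..11")

    def get(self, key: str) -> int | None:
        if key in self.branches.index:
            return int(self.branches.loc[key])
        return None
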