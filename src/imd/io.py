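"""Readers, writers and validated in-memory containers for the pipeline's formats.

All tabular formats are delimited text (TSV by default, comma accepted); gene
sets travel as GMT. Containers are thin wrappers over pandas with the
invariants the downstream stages rely on (unique ids, finite values, closed
vocabularies) enforced at construction time.

Mutation input is a flat MAF-like table, not VCF: the somatic filters operate
on fields (VAF, caller concordance, normal support, population frequency)
already joined across callers. Coordinates are 1-based fully closed; strand is
not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("imd")

TIMEPOINTS = ("pre", "on", "post")
SUBTYPES = ("luminal", "TNBC")
VARIANT_CLASSES = ("SNV", "indel")
CALLER_FLAGS = ("callerA", "callerB")


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


# ---------------------------------------------------------------------------
# ExpressionMatrix


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with an explicit intensity scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``scale`` is ``"log2"`` (default for microarray-style data) or
    ``"linear"``; mixing of tumor and adjacent compartments is convex only in
    linear abundance, so stages that mix or unmix convert explicitly.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.values), scale="linear")

    def to_log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + pseudocount), scale="log2")


def read_expression_matrix(
    path, scale: str = "log2", sep: str | None = None, strict: bool = True
) -> ExpressionMatrix:
    """Read a genes x samples matrix: first column gene ids, header sample ids.

    Duplicate gene rows are collapsed by per-sample maximum (logged).
    Non-numeric cells raise a :class:`FormatError` naming the offending
    row/column under ``strict=True``; otherwise the gene row is dropped with a
    warning.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    delim = sep if sep is not None else ("\t" if "\t" in header else ",")
    sample_ids = header.split(delim)[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"duplicate sample ids in {path}: {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        if strict:
            raise FormatError(
                f"non-numeric cell in {path} at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}: {df.iloc[r, c]!r}"
            )
        drop = bad.any(axis=1)
        logger.warning(
            "dropping %d gene rows with non-numeric cells from %s",
            int(drop.sum()), path,
        )
        numeric = numeric.loc[~drop]
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        if strict:
            raise FormatError(
                f"missing value in {path} at gene {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r}"
            )
        drop = numeric.isna().any(axis=1)
        logger.warning("dropping %d gene rows with missing values", int(drop.sum()))
        numeric = numeric.loc[~drop]
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning(
            "collapsing %d duplicated gene rows by max in %s", n_dup, path
        )
        order = numeric.index.unique()
        numeric = numeric.groupby(level=0, sort=False).max().loc[order]
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric, scale=scale)


def write_expression_matrix(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene_id")


# ---------------------------------------------------------------------------
# GeneSetCollection


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: d for n, d in self.descriptions.items() if n in names},
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within a set are de-duplicated (first occurrence kept)
    with a warning; a line with fewer than three fields is an error naming
    the line number. An empty file yields an empty collection with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning(
                    "set %r: %d duplicate genes removed", name, len(genes) - len(uniq)
                )
            sets[name] = uniq
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# SampleAnnotationTable


@dataclass
class SampleAnnotationTable:
    """Per-sample clinical annotation: patient, timepoint, subtype, cellularity.

    One row per sample; (patient_id, timepoint) must be unique and timepoints
    come from the closed vocabulary pre/on/post (biopsy before therapy, after
    two cycles, and at surgery).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "timepoint")
    OPTIONAL = ("subtype", "cellularity", "response")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in annotation table")
        if df.duplicated(subset=["patient_id", "timepoint"]).any():
            raise ValueError("duplicate (patient_id, timepoint) pairs")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}; allowed {TIMEPOINTS}")
        if "subtype" in df.columns:
            bad_st = set(df["subtype"].dropna()) - set(SUBTYPES)
            if bad_st:
                raise ValueError(f"unknown subtypes {sorted(bad_st)}")
        if "cellularity" in df.columns:
            cell = df["cellularity"].dropna()
            if ((cell < 0) | (cell > 1)).any():
                raise ValueError("cellularity outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def for_timepoint(self, timepoint: str) -> pd.DataFrame:
        return self.table[self.table["timepoint"] == timepoint]


def read_sample_annotations(path, sep: str | None = None) -> SampleAnnotationTable:
    df = pd.read_csv(path, sep=sep, engine="python", dtype={"sample_id": str, "patient_id": str})
    return SampleAnnotationTable(df)


# ---------------------------------------------------------------------------
# MutationTable

_MUT_REQUIRED = (
    "chrom", "pos", "ref", "alt", "variant_class", "alt_count", "depth",
    "sample_id", "patient_id", "timepoint",
)
_MUT_DEFAULTS = {
    "cn_n": 2.0,
    "normal_vaf": 0.0,
    "normal_alt_count": 0,
    "population_freq": 0.0,
    "caller_flags": "callerA,callerB",
}


@dataclass
class MutationTable:
    """MAF-like somatic mutation records with the fields the filters and the
    cancer-cell-fraction mapping (VAF, purity p, CN_t, CN_n) need.

    ``caller_flags`` is a comma-joined subset of {callerA, callerB} marking
    which variant callers reported the record. VAF is recomputed from
    alt_count/depth when absent.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in _MUT_REQUIRED:
            if col not in df.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        for col, default in _MUT_DEFAULTS.items():
            if col not in df.columns:
                df[col] = default
        if "vaf" not in df.columns:
            df["vaf"] = df["alt_count"] / df["depth"]
        if "purity" not in df.columns:
            raise ValueError("mutation table missing column 'purity'")
        if (df["alt_count"] > df["depth"]).any():
            bad = df.index[df["alt_count"] > df["depth"]][0]
            raise ValueError(f"alt_count > depth at row {bad}")
        if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
            raise ValueError("purity outside (0, 1]")
        if (df["pos"] <= 0).any():
            raise ValueError("coordinates must be positive (1-based)")
        bad_class = set(df["variant_class"]) - set(VARIANT_CLASSES)
        if bad_class:
            raise ValueError(f"unknown variant classes {sorted(bad_class)}")
        if (df["cn_t"] < 0).any() if "cn_t" in df.columns else False:
            raise ValueError("cn_t must be >= 0")
        if "cn_t" not in df.columns:
            df["cn_t"] = 2.0
        mismatch = (df["vaf"] - df["alt_count"] / df["depth"]).abs() > 0.01
        if mismatch.any():
            raise ValueError("vaf inconsistent with alt_count/depth beyond rounding")
        for flags in df["caller_flags"].fillna(""):
            parts = [p for p in str(flags).split(",") if p]
            if set(parts) - set(CALLER_FLAGS):
                raise ValueError(f"unknown caller flags {flags!r}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def keys(self) -> pd.Series:
        """Mutation identity keys: chrom:pos:ref:alt."""
        df = self.table
        return (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str)
        )


def read_mutation_table(path, sep: str | None = None) -> MutationTable:
    df = pd.read_csv(path, sep=sep, engine="python",
                     dtype={"chrom": str, "sample_id": str, "patient_id": str})
    return MutationTable(df)


def write_table(obj, path, sep: str = "\t") -> None:
    """Loss-free writer for annotation and mutation tables (and DataFrames)."""
    if isinstance(obj, (SampleAnnotationTable, MutationTable)):
        obj.table.to_csv(path, sep=sep, index=False)
    elif isinstance(obj, ExpressionMatrix):
        write_expression_matrix(obj, path, sep=sep)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
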