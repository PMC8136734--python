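"""Readers and writers for count matrices, metadata tables and GMT gene sets.

Matrices are represented as pandas DataFrames with gene identifiers in the
index and sample identifiers in the columns. Metadata travels with a small
schema declaring each column categorical or continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "na", "NULL", "."}


@dataclass
class MetadataTable:
    """Per-sample covariates with declared types.

    ``schema`` maps column name -> ``"categorical"`` or ``"continuous"``.
    Categorical columns are pandas ``category`` dtype; continuous columns
    are floats with NaN for missing.
    """

    data: pd.DataFrame
    schema: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def levels(self, column: str) -> list:
        if self.schema.get(column) != "categorical":
            raise ValueError(f"{column!r} is not categorical")
        return list(self.data[column].cat.categories)


def _validate_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {source}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {source}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entries in {source}: {exc}") from exc
    if not np.isfinite(values).all():
        raise ValueError(f"non-finite entries in {source}")
    if (values < 0).any():
        raise ValueError(f"negative counts in {source}")
    df = df.astype(float)
    logger.info("read counts from %s: %d genes x %d samples", source, *df.shape)
    return df


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a nonnegative gene x sample count matrix.

    TSV/CSV files carry gene identifiers in the first column and sample
    identifiers in the header. MTX files are MatrixMarket triplets with
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` sidecars listing row
    and column identifiers, one per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif format == "mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path))
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        df = pd.DataFrame(mat.toarray(), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return _validate_counts(df, str(path))


def write_counts(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        df.to_csv(path, sep="\t" if format == "tsv" else ",", index_label="gene")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(df.to_numpy()))
        stem = path.with_suffix("")
        Path(f"{stem}.genes.txt").write_text("\n".join(df.index) + "\n")
        Path(f"{stem}.samples.txt").write_text("\n".join(df.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a real-valued TSV matrix (first column = row ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path: str | Path, schema: dict[str, str]) -> MetadataTable:
    """Read a per-sample metadata TSV with a ``sample_id`` column.

    ``schema`` declares each used column ``"categorical"`` or
    ``"continuous"``. Unknown tokens in continuous columns raise unless
    they are in the missing-value list; missing values are kept as NaN,
    never dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValueError("metadata must have a sample_id column")
    if raw["sample_id"].duplicated().any():
        dups = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id: {dups[:5]}")
    raw = raw.set_index("sample_id")
    for col, kind in schema.items():
        if col not in raw.columns:
            raise ValueError(f"declared column {col!r} absent from {path}")
        ser = raw[col].where(~raw[col].isin(MISSING_TOKENS))
        if kind == "continuous":
            try:
                raw[col] = ser.astype(float)
            except ValueError as exc:
                raise ValueError(
                    f"continuous column {col!r} has non-numeric token: {exc}"
                ) from exc
        elif kind == "categorical":
            raw[col] = ser.astype("category")
        else:
            raise ValueError(f"unknown column type {kind!r} for {col!r}")
    logger.info("read metadata from %s: %d samples", path, len(raw))
    return MetadataTable(data=raw[list(schema)], schema=dict(schema))


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: per line, set name, description, then member genes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
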