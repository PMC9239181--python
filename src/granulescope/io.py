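"""Tabular I/O: TSV schemas, validation, deterministic writing.

All tables are tab-delimited UTF-8 text with a header row and '.' decimal.
Schemas declare required columns with types and row-level invariants;
validation failures name the file, row and column.  Unknown columns are
accepted with a warning.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd

__all__ = [
    "TableSchema",
    "SchemaError",
    "validate_table",
    "write_tsv",
    "file_digest",
    "PSM_SCHEMA",
    "ANNOTATION_SCHEMA",
    "FOCI_SCHEMA",
    "PROFILE_SCHEMA",
    "GRANULE_SCHEMA",
    "CELLS_SCHEMA",
]


class SchemaError(ValueError):
    """A table failed schema validation."""


@dataclass(frozen=True)
class TableSchema:
    """Required columns (name → pandas dtype) plus row-level checks.

    ``row_checks`` maps a description to a predicate over the DataFrame
    returning a boolean Series that is True for VALID rows.
    """

    name: str
    columns: dict[str, str]
    row_checks: dict[str, Callable[[pd.DataFrame], pd.Series]] = field(
        default_factory=dict
    )
    optional: tuple[str, ...] = ()


PSM_SCHEMA = TableSchema(
    name="psm",
    columns={"protein_id": "object", "replicate": "int64",
             "fraction": "object", "psm_count": "int64"},
    row_checks={
        "psm_count >= 0": lambda df: df["psm_count"] >= 0,
        "fraction in {pellet, lysate}":
            lambda df: df["fraction"].isin(["pellet", "lysate"]),
    },
)

ANNOTATION_SCHEMA = TableSchema(
    name="annotations",
    columns={"protein_id": "object", "is_ribosomal": "bool"},
    optional=("charge", "sequence"),
)

FOCI_SCHEMA = TableSchema(
    name="foci",
    columns={"cell_id": "object", "channel": "object",
             "length_um": "float64", "position_um": "float64",
             "intensity": "float64"},
    row_checks={
        "length_um > 0": lambda df: df["length_um"] > 0,
        # NaN position marks a zero-foci cell's sentinel row
        "0 <= position_um <= length_um":
            lambda df: df["position_um"].isna()
            | ((df["position_um"] >= 0)
               & (df["position_um"] <= df["length_um"])),
        "intensity > 0": lambda df: df["intensity"].isna()
            | (df["intensity"] > 0),
    },
)

PROFILE_SCHEMA = TableSchema(
    name="profiles",
    columns={"cell_id": "object", "channel": "object",
             "segment_index": "int64", "intensity": "float64"},
    row_checks={"intensity >= 0": lambda df: df["intensity"] >= 0},
)

GRANULE_SCHEMA = TableSchema(
    name="granules",
    columns={"cell_id": "object", "group": "object",
             "diameter_nm": "float64"},
    row_checks={"diameter_nm > 0": lambda df: df["diameter_nm"] > 0},
)

CELLS_SCHEMA = TableSchema(
    name="cells",
    columns={"cell_id": "object", "group": "object"},
    optional=("count", "pre_fusion_count"),
)


def validate_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a TSV against a schema.

    Missing required columns, uncoercible types, and row-check violations
    raise :class:`SchemaError` naming the file, row (1-based, excluding the
    header) and column; unknown columns only warn.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t")
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    extra = set(df.columns) - set(schema.columns) - set(schema.optional)
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {sorted(extra)}",
                      stacklevel=2)
    for column, dtype in schema.columns.items():
        try:
            df[column] = df[column].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column {column!r} not coercible to {dtype}: {exc}"
            ) from None
    for description, predicate in schema.row_checks.items():
        valid = predicate(df)
        if not valid.all():
            row = int(df.index[~valid][0]) + 1
            raise SchemaError(
                f"{path}: row {row} violates '{description}'"
            )
    return df


def write_tsv(df: pd.DataFrame, path: str | Path,
              float_format: str = "%.9g") -> Path:
    """Write a DataFrame as deterministic TSV (fixed float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format,
              lineterminator="\n")
    return path


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
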