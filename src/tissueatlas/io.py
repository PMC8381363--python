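"""Tabular input/output and replicate-to-tissue aggregation.

Expression tables are dense TSV files: first column header ``gene_id``,
remaining columns one per sample, '.' decimal separator, no missing
cells (undetected genes carry 0). Sample metadata is a TSV with columns
``sample_id``, ``tissue``, ``donor_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import FormatError, MappingError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "TissueProfile",
    "read_expression_table",
    "write_expression_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "aggregate_by_tissue",
    "read_table",
    "write_table",
]

Unit = Literal["FPKM", "TPM"]

METADATA_COLUMNS = ("sample_id", "tissue", "donor_id")


def _check_axis_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dupes}")


def _check_values(frame: pd.DataFrame, what: str) -> None:
    if frame.isna().to_numpy().any():
        bad = frame.columns[frame.isna().any(axis=0)].tolist()
        raise FormatError(f"{what} contains missing/non-numeric cells in columns {bad}")
    if (frame.to_numpy() < 0).any():
        raise ValidationError(f"{what} contains negative abundance values")


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance matrix with a declared unit.

    ``values`` is a pandas DataFrame indexed by gene id with one column
    per sample id.
    """

    values: pd.DataFrame
    unit: Unit = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ValidationError(f"unknown abundance unit {self.unit!r}")
        _check_axis_unique(self.values.index, "gene")
        _check_axis_unique(self.values.columns, "sample")
        _check_values(self.values, "expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TissueProfile:
    """Genes × tissues matrix of replicate-averaged FPKM."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axis_unique(self.values.index, "gene")
        _check_axis_unique(self.values.columns, "tissue")
        _check_values(self.values, "tissue profile")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def read_expression_table(path: str | Path, unit: Unit = "FPKM") -> ExpressionMatrix:
    """Read a genes × samples TSV into an :class:`ExpressionMatrix`.

    The first column must be headed ``gene_id``; every body cell must be
    a non-negative number.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id column plus >=1 sample column")
    if frame.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be headed 'gene_id', got {frame.columns[0]!r}")
    frame = frame.set_index("gene_id")
    body = frame.apply(pd.to_numeric, errors="coerce")
    return ExpressionMatrix(values=body, unit=unit)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, tissue, donor_id)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {sorted(missing)}")
    _check_axis_unique(pd.Index(meta["sample_id"]), "sample")
    return meta[list(METADATA_COLUMNS)]


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def aggregate_by_tissue(matrix: ExpressionMatrix, meta: pd.DataFrame) -> TissueProfile:
    """Average replicate samples into one FPKM column per tissue.

    Tissue-level expression is the arithmetic mean of that tissue's
    replicate samples; single-replicate tissues pass through unchanged.
    Tissue columns are emitted in sorted name order so the result is
    invariant to sample ordering.
    """
    if matrix.unit != "FPKM":
        raise ValidationError("tissue aggregation is defined on FPKM matrices")
    tissue_of = dict(zip(meta["sample_id"], meta["tissue"]))
    unmapped = [s for s in matrix.sample_ids if s not in tissue_of]
    if unmapped:
        raise MappingError(f"sample(s) without metadata: {unmapped}")
    groups = matrix.values.T.groupby([tissue_of[s] for s in matrix.sample_ids])
    profile = groups.mean().T
    profile = profile[sorted(profile.columns)]
    return TissueProfile(values=profile)


def read_table(path: str | Path, columns: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a generic TSV result table, optionally checking its columns."""
    frame = pd.read_csv(path, sep="\t")
    if columns is not None:
        missing = set(columns) - set(frame.columns)
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a deterministic column order."""
    frame.to_csv(path, sep="\t", index=False)
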