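"""In-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` is a genes x species table of expression values
for one tissue, either on the raw TPM-like scale or on log2(TPM+1).
A :class:`GeneAnnotation` maps gene ids to genomic intervals (0-based,
half-open, BED convention).  Longitudinal lipid panels and kinetics series
are plain :class:`pandas.DataFrame` objects validated by
:mod:`expevo.io_formats`; they carry no extra structure worth wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateLabelError, NonNumericValueError, ValidationError

GENOTYPES = ("WT", "ASGR1+/-", "ASGR1-/-")
DIETS = ("standard", "HFHC")

PANEL_COLUMNS = ("animal_id", "genotype", "diet", "age_months", "analyte", "value", "unit")
SERIES_COLUMNS = ("group", "time_h", "value", "unit")


@dataclass
class ExpressionMatrix:
    """Genes x species expression values for one tissue.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per species.
    scale
        ``"log2"`` for log2(TPM+1) values (may be negative after noise) or
        ``"tpm"`` for raw non-negative TPM-like values.
    tissue
        Optional tissue label carried through to reports.
    """

    values: pd.DataFrame
    scale: str = "log2"
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "tpm"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DuplicateLabelError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DuplicateLabelError(f"duplicate species ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise NonNumericValueError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise NonNumericValueError(
                f"missing value at gene {self.values.index[i]!r}, "
                f"species {self.values.columns[j]!r}"
            )
        if self.scale == "tpm" and (arr < 0).any():
            raise ValidationError("TPM-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on log2(TPM+1) scale (no-op if already there)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), scale="log2", tissue=self.tissue)


@dataclass
class GeneAnnotation:
    """Gene genomic coordinates, BED convention (0-based, half-open)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise DuplicateLabelError(f"duplicate gene ids in annotation: {dups}")
        if (self.table["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table.loc[self.table["start"] >= self.table["end"], "gene_id"].tolist()
            raise ValidationError(f"start >= end for genes {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def row(self, gene_id: str) -> pd.Series:
        hit = self.table[self.table["gene_id"] == gene_id]
        if hit.empty:
            raise ValidationError(f"gene {gene_id!r} not in annotation")
        return hit.iloc[0]
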