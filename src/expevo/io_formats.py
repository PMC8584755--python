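"""Readers and writers for every file format the pipeline touches.

Formats
-------
* expression matrix: TSV, header row of species labels, first column gene ids
* trees: Newick (dendropy-backed); round trips preserve topology and branch
  lengths to at least 10 significant digits
* gene annotation: BED (0-based, half-open), columns chrom/start/end/gene_id
* lipid panel CSV: ``animal_id,genotype,diet,age_months,analyte,value,unit``
* kinetics series CSV: ``group,time_h,value,unit``

All validation failures raise the typed errors in :mod:`expevo.errors`;
nothing is silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    DIETS,
    GENOTYPES,
    PANEL_COLUMNS,
    SERIES_COLUMNS,
    ExpressionMatrix,
    GeneAnnotation,
)
from .errors import (
    DuplicateLabelError,
    MonotonicityError,
    NewickError,
    NonNumericValueError,
    RaggedTableError,
    SchemaError,
)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(path: str | Path, scale: str = "log2",
                        tissue: str | None = None) -> ExpressionMatrix:
    """Read a genes x species TSV with strict validation.

    Raises :class:`RaggedTableError` for non-rectangular files,
    :class:`DuplicateLabelError` for repeated gene/species labels and
    :class:`NonNumericValueError` (naming the offending cell) for anything
    that does not parse as a number.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:
        raise RaggedTableError(f"{path}: {exc}") from exc

    # pandas pads short rows with NaN instead of erroring; detect that here.
    widths = {len(line.rstrip("\n").split("\t")) for line in path.open() if line.strip()}
    if len(widths) > 1:
        raise RaggedTableError(f"{path}: rows have differing column counts {sorted(widths)}")

    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise DuplicateLabelError(f"{path}: duplicated gene id(s) {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DuplicateLabelError(f"{path}: duplicated species label(s) {dups}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise NonNumericValueError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, species {raw.columns[j]!r}"
        )
    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric, scale=scale, tissue=tissue)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         as_tpm: bool = False) -> None:
    """Write a matrix as TSV; ``as_tpm`` exponentiates log2 values first."""
    values = matrix.values
    if as_tpm and matrix.scale == "log2":
        values = (2.0 ** values) - 1.0
    values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# trees

def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick file; malformed input raises :class:`NewickError`."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickError(f"{path}: {exc}") from exc
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        return dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise NewickError(str(exc)) from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with 12 significant digits on branch lengths."""
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        ).strip()
        + "\n"
    )


# ---------------------------------------------------------------------------
# BED annotation

def read_bed(path: str | Path) -> GeneAnnotation:
    """Read a 4-column BED (chrom, start, end, gene_id; 0-based half-open)."""
    try:
        table = pd.read_csv(path, sep="\t", header=None,
                            names=["chrom", "start", "end", "gene_id"],
                            dtype={"chrom": str, "gene_id": str})
    except pd.errors.ParserError as exc:
        raise RaggedTableError(f"{path}: {exc}") from exc
    for col in ("start", "end"):
        if not np.issubdtype(table[col].dtype, np.integer):
            raise NonNumericValueError(f"{path}: column {col!r} is not integer")
    return GeneAnnotation(table[["gene_id", "chrom", "start", "end"]])


def write_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.table[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# measurement CSVs

def _require_header(frame: pd.DataFrame, expected: tuple[str, ...], path: Path) -> None:
    if list(frame.columns) != list(expected):
        raise SchemaError(
            f"{path}: header {list(frame.columns)} does not match schema {list(expected)}"
        )


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a longitudinal lipid panel CSV.

    Checks: header matches the panel schema, genotype/diet labels are known,
    ages are positive integers, values numeric, units uniform per analyte,
    and (animal, analyte, age) rows unique.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    _require_header(frame, PANEL_COLUMNS, path)
    bad_geno = set(frame["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise SchemaError(f"{path}: unknown genotype label(s) {sorted(bad_geno)}")
    bad_diet = set(frame["diet"]) - set(DIETS)
    if bad_diet:
        raise SchemaError(f"{path}: unknown diet label(s) {sorted(bad_diet)}")
    ages = pd.to_numeric(frame["age_months"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any() or (ages != ages.astype(int)).any():
        raise SchemaError(f"{path}: age_months must be positive integers")
    values = pd.to_numeric(frame["value"], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise NonNumericValueError(f"{path}: non-numeric value in row {row}")
    frame["age_months"] = ages.astype(int)
    frame["value"] = values.astype(float)
    units = frame.groupby("analyte")["unit"].nunique()
    mixed = units[units > 1].index.tolist()
    if mixed:
        raise SchemaError(f"{path}: mixed units for analyte(s) {mixed}")
    dup = frame.duplicated(subset=["animal_id", "analyte", "age_months"])
    if dup.any():
        raise DuplicateLabelError(
            f"{path}: duplicate (animal, analyte, age) rows at index {dup[dup].index.tolist()}"
        )
    return frame


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a kinetics series CSV (clearance or secretion).

    Times must be strictly increasing within each group; values finite.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    _require_header(frame, SERIES_COLUMNS, path)
    for col in ("time_h", "value"):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        if parsed.isna().any() or not np.isfinite(parsed).all():
            raise NonNumericValueError(f"{path}: non-numeric or non-finite {col}")
        frame[col] = parsed.astype(float)
    if (frame["time_h"] < 0).any():
        raise SchemaError(f"{path}: negative time_h")
    for group, sub in frame.groupby("group"):
        if (np.diff(sub["time_h"].to_numpy()) <= 0).any():
            raise MonotonicityError(
                f"{path}: times not strictly increasing within group {group!r}"
            )
    return frame


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False)


def write_series_csv(series: pd.DataFrame, path: str | Path) -> None:
    series[list(SERIES_COLUMNS)].to_csv(path, index=False)
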