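"""Data preparation: zero-population exclusion, median imputation,
direction reversal, and the exploratory measure correlation matrix.

The fixed pipeline order is: drop zero-population tracts, then impute each
measure's missing cells with the column median (so medians reflect analyzed
tracts only), then negate reverse-coded measures so that higher always
means more deprivation. Every change is recorded in a :class:`PreprocessLog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import MeasureRegistry

__all__ = [
    "PreprocessLog",
    "measure_columns",
    "filter_zero_population",
    "impute_median",
    "reverse_code",
    "correlation_matrix",
    "preprocess",
]


@dataclass
class PreprocessLog:
    """Audit trail of the preprocessing stage."""

    excluded_fips: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, str, float]] = field(default_factory=list)
    reversed_measures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "PreprocessLog") -> "PreprocessLog":
        return PreprocessLog(
            excluded_fips=self.excluded_fips + other.excluded_fips,
            imputed_cells=self.imputed_cells + other.imputed_cells,
            reversed_measures=self.reversed_measures + other.reversed_measures,
            warnings=self.warnings + other.warnings,
        )


def measure_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a tract table that hold measure values (everything except
    the key and population columns)."""
    return [c for c in table.columns if c not in ("fips", "population")]


def filter_zero_population(table: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessLog]:
    """Drop tracts with zero population, preserving the order of the rest."""
    if "population" not in table.columns:
        raise ValueError("table has no 'population' column")
    log = PreprocessLog()
    zero = table["population"] == 0
    log.excluded_fips = [str(f) for f in table.loc[zero, "fips"]]
    kept = table.loc[~zero].reset_index(drop=True)
    if kept.empty:
        log.warnings.append("all tracts have zero population; result is empty")
    return kept, log


def impute_median(table: pd.DataFrame) -> tuple[pd.DataFrame, PreprocessLog]:
    """Replace each missing measure cell with the median of that measure's
    non-missing values; log every imputed cell as (fips, measure, value)."""
    log = PreprocessLog()
    out = table.copy()
    for col in measure_columns(table):
        vals = out[col]
        missing = vals.isna()
        if not missing.any():
            continue
        if missing.all():
            raise ValueError(f"measure {col!r} is entirely missing; cannot impute")
        med = float(vals.median(skipna=True))
        for f in out.loc[missing, "fips"]:
            log.imputed_cells.append((str(f), col, med))
        out[col] = vals.fillna(med)
    return out, log


def reverse_code(table: pd.DataFrame, registry: MeasureRegistry) -> pd.DataFrame:
    """Negate every reverse-coded measure present in the table.

    After this step higher values mean more deprivation for every measure.
    Applying the function twice restores the original table.
    """
    out = table.copy()
    for mid in registry.reversed_ids:
        if mid in out.columns:
            out[mid] = -out[mid].astype(float)
    return out


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the measure columns.

    Zero-variance columns yield NaN off-diagonal entries rather than an
    error; the diagonal is exactly 1.
    """
    cols = measure_columns(table)
    if len(table) < 3:
        raise ValueError("correlation matrix requires at least 3 tracts")
    corr = table[cols].corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def preprocess(
    table: pd.DataFrame, registry: MeasureRegistry
) -> tuple[pd.DataFrame, PreprocessLog]:
    """Apply the full preparation pipeline in its fixed order."""
    unknown = [c for c in measure_columns(table) if c not in registry.measure_ids]
    if unknown:
        raise ValueError(f"table columns not in registry: {unknown}")
    missing = [m for m in registry.measure_ids if m not in table.columns]
    if missing:
        raise ValueError(f"registry measures missing from table: {missing}")
    filtered, log1 = filter_zero_population(table)
    imputed, log2 = impute_median(filtered)
    coded = reverse_code(imputed, registry)
    log = log1.merge(log2)
    log.reversed_measures = [m for m in registry.reversed_ids if m in coded.columns]
    return coded, log
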