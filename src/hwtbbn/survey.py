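"""Reading, validating, writing and summarizing household survey tables.

A survey table is one row per household.  Cell validation is driven entirely
by the codebook: Likert answers outside 1–5, binary answers outside {0, 1},
and categorical tokens outside the declared state list are converted to
missing and counted in a validation report — never silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook import Codebook

logger = logging.getLogger(__name__)

#: extra tokens (besides the empty cell) treated as the missing marker
DEFAULT_MISSING_TOKENS = ("", "NA", "N/A", "nan", "NaN", ".")


class SurveySchemaError(ValueError):
    """Missing mandatory columns or duplicate household ids."""


@dataclass
class ValidationReport:
    """Per-variable counts of cells coerced to missing during reading."""

    invalid_cells: dict[str, int] = field(default_factory=dict)
    missing_cells: dict[str, int] = field(default_factory=dict)

    @property
    def n_invalid(self) -> int:
        return sum(self.invalid_cells.values())

    @property
    def n_missing(self) -> int:
        return sum(self.missing_cells.values())


@dataclass
class SurveyTable:
    """Validated per-household survey responses.

    ``data`` holds one column per codebook survey variable: numeric scales as
    floats with NaN for missing, categorical scales as strings with NaN for
    missing.  Household ids are unique and kept as a plain column.
    """

    data: pd.DataFrame
    codebook: Codebook
    report: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data[self.codebook.id_variable]


def _coerce_numeric(series: pd.Series, lo: float, hi: float,
                    integral: bool) -> tuple[pd.Series, int]:
    """Coerce to float in [lo, hi]; out-of-range/unparseable become NaN."""
    was_missing = series.isna()
    values = pd.to_numeric(series, errors="coerce")
    bad = (~was_missing) & (
        values.isna()
        | (values < lo)
        | (values > hi)
        | (integral & (values != np.round(values)))
    )
    values[bad] = np.nan
    return values.astype(float), int(bad.sum())


def _coerce_categorical(series: pd.Series, states: tuple[str, ...]) -> tuple[pd.Series, int]:
    was_missing = series.isna()
    tokens = series.astype("string").str.strip()
    bad = (~was_missing) & ~tokens.isin(states)
    out = tokens.astype(object)
    out[bad | was_missing] = np.nan
    return out, int(bad.sum())


def validate_frame(frame: pd.DataFrame, codebook: Codebook) -> SurveyTable:
    """Validate a raw DataFrame against the codebook.

    Returns a :class:`SurveyTable` whose row count equals the input's; every
    unparseable or out-of-range cell becomes missing and is tallied in the
    table's :class:`ValidationReport`.
    """
    expected = codebook.survey_columns()
    missing_cols = [c for c in expected if c not in frame.columns]
    if missing_cols:
        raise SurveySchemaError(f"missing mandatory columns: {missing_cols}")

    id_col = codebook.id_variable
    ids = frame[id_col]
    if ids.isna().any():
        raise SurveySchemaError("missing household ids")
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()].astype(str)))
        raise SurveySchemaError(f"duplicate household ids: {dupes}")

    report = ValidationReport()
    out = {id_col: ids.reset_index(drop=True)}
    for var in codebook.variables:
        if var.derived or var.role == "id":
            continue
        raw = frame[var.name].reset_index(drop=True)
        if var.scale == "likert_1_5":
            col, n_bad = _coerce_numeric(raw, 1, 5, integral=True)
        elif var.scale == "binary_0_1":
            col, n_bad = _coerce_numeric(raw, 0, 1, integral=True)
        elif var.scale == "count":
            col, n_bad = _coerce_numeric(raw, 0, np.inf, integral=True)
        else:
            col, n_bad = _coerce_categorical(raw, var.states)
        if n_bad:
            report.invalid_cells[var.name] = n_bad
            logger.warning("%d invalid cell(s) in %r set to missing", n_bad, var.name)
        n_miss = int(col.isna().sum())
        if n_miss:
            report.missing_cells[var.name] = n_miss
        out[var.name] = col
    return SurveyTable(data=pd.DataFrame(out), codebook=codebook, report=report)


def read_survey(path: str | Path, codebook: Codebook, *,
                sheet: int | str = 0,
                missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS) -> SurveyTable:
    """Read a CSV or XLSX survey file and validate it against the codebook."""
    path = Path(path)
    na_values = list(missing_tokens)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        frame = pd.read_excel(path, sheet_name=sheet, na_values=na_values,
                              keep_default_na=False)
    else:
        frame = pd.read_csv(path, na_values=na_values, keep_default_na=False,
                            skipinitialspace=True)
    return validate_frame(frame, codebook)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey table to CSV (empty cell = missing).

    Numeric columns are written as integers where possible so that the file
    round-trips bit-identically through :func:`read_survey`.
    """
    frame = table.data.copy()
    for var in table.codebook.variables:
        if var.name in frame.columns and var.scale in ("likert_1_5", "binary_0_1", "count"):
            frame[var.name] = frame[var.name].astype("Int64")
    frame.to_csv(path, index=False)


def summarize(table: SurveyTable) -> pd.DataFrame:
    """Descriptive statistics per variable, Table-1 style.

    Likert/binary/count items get mean and sample SD (n−1 denominator) over
    non-missing responses; categorical variables get state frequencies.
    Missing counts are reported separately, so frequencies sum to the row
    count per variable.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty survey table")
    rows = []
    n = len(table)
    for var in table.codebook.variables:
        if var.role == "id" or var.derived:
            continue
        col = table.data[var.name]
        n_missing = int(col.isna().sum())
        if var.scale in ("likert_1_5", "binary_0_1", "count"):
            vals = col.dropna().astype(float)
            rows.append({
                "variable": var.name, "role": var.role, "scale": var.scale,
                "n": n, "n_missing": n_missing,
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else
                      (0.0 if len(vals) == 1 else np.nan),
            })
        else:
            freqs = col.value_counts(dropna=True)
            for state in var.states:
                rows.append({
                    "variable": var.name, "role": var.role, "scale": var.scale,
                    "n": n, "n_missing": n_missing, "state": state,
                    "count": int(freqs.get(state, 0)),
                })
    return pd.DataFrame(rows)
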