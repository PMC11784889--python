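"""Cohort data cleaning: inspection, z-score / IQR outlier detection,
mean imputation of flagged values, and cohort CSV input/output.

The cohort schema is one row per patient with a binary ``sex``, serum ``ACE``
(U/mL, positive), serum ``sIL2R`` (pg/mL, positive) and a binary
``diagnosis``. Loading validates the schema and rejects missing cells —
missing-data imputation is deliberately out of scope; only values flagged as
outliers are ever replaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "OutlierReport",
    "zscore_flags",
    "iqr_flags",
    "impute_outliers",
    "clean_cohort",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

REQUIRED_COLUMNS = ("sex", "ACE", "sIL2R", "diagnosis")
NUMERIC_COLUMNS = ("ACE", "sIL2R")

# common spellings seen in exported tables, mapped onto the canonical schema
DEFAULT_ALIASES = {
    "sex": "sex",
    "gender": "sex",
    "ace": "ACE",
    "sil2r": "sIL2R",
    "sil_2r": "sIL2R",
    "sil-2r": "sIL2R",
    "diagnosis": "diagnosis",
    "sarcoidosis": "diagnosis",
}


def zscore_flags(values, threshold: float = 3.0, ddof: int = 0) -> np.ndarray:
    """Flag points with |x - mean| / sd beyond ``threshold``.

    The population standard deviation (``ddof=0``) is the default; a constant
    vector (sd = 0) flags nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-score screening needs at least 2 values")
    sigma = values.std(ddof=ddof)
    if sigma == 0.0:
        return np.zeros(values.size, dtype=bool)
    return np.abs(values - values.mean()) / sigma > threshold


def iqr_flags(values, k: float = 1.5) -> np.ndarray:
    """Flag points outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (numpy's default dialect).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("IQR screening needs at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def impute_outliers(values, flags, include_flagged: bool = False) -> np.ndarray:
    """Replace flagged entries by the mean of the unflagged ones.

    ``include_flagged=True`` averages over all points instead (the literal
    mean-imputation formula); the default excludes the flagged values so an
    outlier cannot contaminate its own replacement.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != values.shape:
        raise ValueError("flags must align with values")
    if flags.all():
        raise ValueError("cannot impute: every value is flagged")
    out = values.copy()
    replacement = values.mean() if include_flagged else values[~flags].mean()
    out[flags] = replacement
    return out


@dataclass
class OutlierReport:
    """What the cleaning pass found and changed, per numeric column."""

    method: str
    threshold: float
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    replacements: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return int(sum(f.sum() for f in self.flags.values()))

    def to_frame(self) -> pd.DataFrame:
        """Flat (column, row, old, new) table of every replacement made."""
        rows = [
            {"column": col, "row": idx, "old_value": old, "new_value": new}
            for col, repl in self.replacements.items()
            for idx, (old, new) in repl.items()
        ]
        return pd.DataFrame(rows, columns=["column", "row", "old_value", "new_value"])


def clean_cohort(
    table: pd.DataFrame,
    method: str = "zscore",
    threshold: float | None = None,
    columns=NUMERIC_COLUMNS,
    include_flagged: bool = False,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Detect and mean-impute outliers per numeric column, independently.

    ``threshold`` is the z cutoff for ``method='zscore'`` (default 3.0) or the
    fence multiplier k for ``method='iqr'`` (default 1.5). Row count and
    non-screened columns are never touched.
    """
    if method == "zscore":
        detector, default = zscore_flags, 3.0
    elif method == "iqr":
        detector, default = iqr_flags, 1.5
    else:
        raise ValueError("method must be 'zscore' or 'iqr'")
    threshold = default if threshold is None else threshold

    cleaned = table.copy()
    report = OutlierReport(method=method, threshold=threshold)
    for col in columns:
        values = cleaned[col].to_numpy(dtype=float)
        flags = detector(values, threshold)
        report.flags[col] = flags
        if flags.any():
            new_values = impute_outliers(values, flags, include_flagged=include_flagged)
            report.replacements[col] = {
                int(cleaned.index[i]): (float(values[i]), float(new_values[i]))
                for i in np.flatnonzero(flags)
            }
            cleaned[col] = new_values
    return cleaned, report


_SEX_CODES = {"m": 0, "male": 0, "f": 1, "female": 1, "0": 0, "1": 1}


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Type-check and validate a cohort table; returns the typed copy.

    Raises ValueError naming the offending column on: missing columns, missing
    cells, non-positive ACE/sIL-2R, non-binary sex or diagnosis.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {', '.join(missing)}")
    table = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing cells in column(s): {', '.join(bad)}")

    sex = table["sex"]
    if sex.dtype == object:
        sex = sex.astype(str).str.strip().str.lower().map(_SEX_CODES)
        if sex.isna().any():
            raise ValueError("column sex: values must be binary (M/F or 0/1)")
    table["sex"] = sex.astype(int)
    if not table["sex"].isin([0, 1]).all():
        raise ValueError("column sex: values must be binary (0/1)")

    for col in NUMERIC_COLUMNS:
        try:
            table[col] = table[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column {col}: non-numeric values") from exc
        if not (table[col] > 0).all():
            raise ValueError(f"column {col}: values must be positive")

    table["diagnosis"] = table["diagnosis"].astype(int)
    if not table["diagnosis"].isin([0, 1]).all():
        raise ValueError("column diagnosis: values must be 0 or 1")
    return table


def read_cohort_csv(
    path, column_map: dict[str, str] | None = None, delimiter: str = ","
) -> pd.DataFrame:
    """Load and validate a cohort CSV; header row required.

    ``column_map`` renames source headers onto the canonical schema and is
    merged over the built-in aliases (case-insensitive).
    """
    raw = pd.read_csv(path, sep=delimiter)
    aliases = dict(DEFAULT_ALIASES)
    if column_map:
        aliases.update({k.strip().lower(): v for k, v in column_map.items()})
    renames = {
        col: aliases[col.strip().lower()]
        for col in raw.columns
        if col.strip().lower() in aliases
    }
    return validate_cohort(raw.rename(columns=renames))


def write_cohort_csv(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a validated cohort table; read -> write -> read round-trips values."""
    validate_cohort(table).to_csv(Path(path), sep=delimiter, index=False)
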