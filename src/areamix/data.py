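"""County-table schema, validation, and the standardized feature container.

A "county table" is an ordinary :class:`pandas.DataFrame` with one row per
areal unit and the fixed column roster in :data:`COUNTY_COLUMNS`; helper
functions here validate and round-trip it as CSV. The clustering stages work
on a :class:`FeatureMatrix`, a thin N×D array wrapper that records variable
names and, once standardized, the means/SDs used so the transform is
auditable and reusable on new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """An invalid simulation or pipeline configuration."""


class SchemaError(ValueError):
    """A county table violating the schema; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DegenerateComponentError(RuntimeError):
    """A mixture component collapsed (vanishing responsibility mass)."""


class FitFailureError(RuntimeError):
    """Every attempted initialization or model cell failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


#: Fixed column order for county CSV files.
COUNTY_COLUMNS = [
    "county_id",
    "state",
    "nchs_class",
    "unemployment_pct",
    "pop_density",
    "median_income",
    "pct_less_hs",
    "pct_single_female_hh",
    "pct_nonwhite",
    "poverty_rate",
    "low_access_pct",
    "obesity_pct",
    "diabetes_pct",
]

#: Columns constrained to [0, 100].
PERCENT_COLUMNS = [
    "unemployment_pct",
    "pct_less_hs",
    "pct_single_female_hh",
    "pct_nonwhite",
    "poverty_rate",
    "low_access_pct",
    "obesity_pct",
    "diabetes_pct",
]

#: NCHS urban-rural classification, six levels from most to least urban.
NCHS_LABELS = {
    1: "Large central metro",
    2: "Large fringe metro",
    3: "Medium metro",
    4: "Small metro",
    5: "Micropolitan",
    6: "Noncore",
}


@dataclass
class FeatureMatrix:
    """N×D matrix of clustering variables with names and standardization audit.

    Parameters
    ----------
    values : ndarray, shape (N, D)
        Observations; no missing values allowed.
    variable_names : list of str
        One name per column.
    standardized : bool
        If True, every column must have mean 0 and sample SD 1 (N−1
        denominator) to within 1e-10.
    means, sds : ndarray, shape (D,), optional
        The location/scale removed during standardization, recorded so the
        transform can be exported and replayed.
    """

    values: np.ndarray
    variable_names: list[str]
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.variable_names = list(self.variable_names)
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.variable_names)} names for {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMatrix contains non-finite values")
        if self.standardized and self.values.shape[0] > 1:
            col_mean = self.values.mean(axis=0)
            col_sd = self.values.std(axis=0, ddof=1)
            if np.any(np.abs(col_mean) > 1e-10) or np.any(np.abs(col_sd - 1) > 1e-10):
                raise ValueError("standardized flag set but columns are not z-scores")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        """Column subset by name, preserving the standardization audit."""
        idx = [self.variable_names.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, idx],
            [self.variable_names[i] for i in idx],
            standardized=self.standardized,
            means=None if self.means is None else self.means[idx],
            sds=None if self.sds is None else self.sds[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)


def as_feature_matrix(data) -> FeatureMatrix:
    """Coerce an ndarray / DataFrame / FeatureMatrix to a FeatureMatrix."""
    if isinstance(data, FeatureMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return FeatureMatrix(data.to_numpy(dtype=float), list(data.columns))
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return FeatureMatrix(arr, [f"x{i}" for i in range(arr.shape[1])])


def validate_county_table(df: pd.DataFrame) -> list[str]:
    """Check a county table against the schema.

    Returns the exhaustive list of violations (empty when valid) rather than
    stopping at the first failure.
    """
    errors: list[str] = []
    for col in COUNTY_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing column: {col}")
    present = [c for c in COUNTY_COLUMNS if c in df.columns]
    numeric = [c for c in present if c not in ("county_id", "state")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        for i in bad:
            errors.append(f"non-numeric or missing value in row {i}, column {col}")
        ok = vals.dropna()
        if col in PERCENT_COLUMNS:
            for i in ok.index[(ok < 0) | (ok > 100)]:
                errors.append(
                    f"percent out of [0, 100] in row {i}, column {col}: {vals[i]}"
                )
        if col == "nchs_class":
            for i in ok.index[~ok.isin(list(NCHS_LABELS))]:
                errors.append(f"nchs_class not in 1..6 in row {i}: {vals[i]}")
        if col in ("pop_density", "median_income"):
            for i in ok.index[ok <= 0]:
                errors.append(f"non-positive value in row {i}, column {col}: {vals[i]}")
    if "county_id" in df.columns and df["county_id"].duplicated().any():
        dups = df["county_id"][df["county_id"].duplicated()].tolist()
        errors.append(f"duplicated county_id values: {dups}")
    return errors


def read_county_csv(path) -> pd.DataFrame:
    """Read and validate a county table CSV (raises SchemaError on violations)."""
    df = pd.read_csv(path, comment="#")
    errors = validate_county_table(df)
    if errors:
        raise SchemaError(errors)
    df["nchs_class"] = df["nchs_class"].astype(int)
    return df[COUNTY_COLUMNS].copy()


def write_county_csv(df: pd.DataFrame, path, header_comment: str | None = None):
    """Write a county table CSV in the fixed column order."""
    errors = validate_county_table(df)
    if errors:
        raise SchemaError(errors)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df[COUNTY_COLUMNS].to_csv(fh, index=False)
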