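"""Socioeconomic deprivation index and variable standardization.

The SES index is a county-level deprivation score in the tradition of the
Townsend and Carstairs indices, adapted to US data: the sum of z-scores of
four components — percent of adults (25+) with less than a high-school
degree, percent single-female-headed households, percent non-white residents,
and the poverty rate. Because each component is standardized over the study
units before summing, the index has mean exactly zero over those units by
construction; larger values indicate greater deprivation.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import FeatureMatrix

#: Component columns of the SES deprivation index, in fixed order.
SES_COMPONENTS = [
    "pct_less_hs",
    "pct_single_female_hh",
    "pct_nonwhite",
    "poverty_rate",
]


def pct_nonwhite_from_nhw(pct_non_hispanic_white):
    """Percent non-white residents from percent non-Hispanic White (100 − x).

    Accepts a scalar or array; values must lie in [0, 100].
    """
    x = np.asarray(pct_non_hispanic_white, dtype=float)
    if np.any(x < 0) or np.any(x > 100):
        raise ValueError("percent non-Hispanic White must be in [0, 100]")
    out = 100.0 - x
    return out.item() if np.isscalar(pct_non_hispanic_white) else out


def _zscore_columns(values: np.ndarray, names: list[str]):
    """Column z-scores with N−1 sample SD; errors name zero-variance columns."""
    if values.shape[0] < 2:
        raise ValueError("standardization requires at least 2 units")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing or non-finite values; imputation is not supported")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    dead = [names[j] for j in np.flatnonzero(sds == 0)]
    if dead:
        raise ValueError(f"zero-variance column(s): {', '.join(dead)}")
    return (values - means) / sds, means, sds


def ses_index(components) -> np.ndarray:
    """Sum of the standardized scores of the four SES components.

    Parameters
    ----------
    components : DataFrame with the :data:`SES_COMPONENTS` columns, or an
        (N, 4) array in that column order. All values must be percentages in
        [0, 100].

    Returns
    -------
    ndarray, shape (N,)
        The deprivation index; its mean over the input units is 0 up to
        floating error.
    """
    if isinstance(components, pd.DataFrame):
        missing = [c for c in SES_COMPONENTS if c not in components.columns]
        if missing:
            raise ValueError(f"missing SES component column(s): {', '.join(missing)}")
        values = components[SES_COMPONENTS].to_numpy(dtype=float)
    else:
        values = np.asarray(components, dtype=float)
    if values.ndim != 2 or values.shape[1] != 4:
        raise ValueError("expected an N×4 array of SES components")
    if np.any(values < 0) or np.any(values > 100):
        raise ValueError("SES components must be percentages in [0, 100]")
    z, _, _ = _zscore_columns(values, SES_COMPONENTS)
    return z.sum(axis=1)


def standardize(table, variables: list[str]) -> FeatureMatrix:
    """Z-score the named columns of a table into a FeatureMatrix.

    Uses the N−1 sample SD and records the removed means/SDs on the result
    for export. Missing columns, non-finite values and zero-variance columns
    are hard errors.
    """
    if isinstance(table, FeatureMatrix):
        table = table.to_dataframe()
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    values = table[list(variables)].to_numpy(dtype=float)
    z, means, sds = _zscore_columns(values, list(variables))
    return FeatureMatrix(z, list(variables), standardized=True, means=means, sds=sds)


def export_standardization(fm: FeatureMatrix, path):
    """Write the standardization parameters of a FeatureMatrix as JSON."""
    if fm.means is None or fm.sds is None:
        raise ValueError("FeatureMatrix carries no standardization parameters")
    payload = {
        "variables": fm.variable_names,
        "means": [float(m) for m in fm.means],
        "sds": [float(s) for s in fm.sds],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def apply_standardization(table: pd.DataFrame, path) -> FeatureMatrix:
    """Re-apply exported standardization parameters to new data."""
    with open(path) as fh:
        payload = json.load(fh)
    names = payload["variables"]
    means = np.asarray(payload["means"], dtype=float)
    sds = np.asarray(payload["sds"], dtype=float)
    values = table[names].to_numpy(dtype=float)
    return FeatureMatrix((values - means) / sds, names, standardized=False,
                         means=means, sds=sds)
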