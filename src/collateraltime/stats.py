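"""Cohort association statistics for the collateral-ratio variables.

Provides the Spearman correlation matrix across the ten CR variables,
standardized simple linear regressions of each CR against the clinical
covariates, and median/IQR summaries.

Conventions (stated because results depend on them):

* Regressions are *standardized*: both variables are z-scored before
  ordinary least squares, so the slope is the standardized coefficient
  (numerically equal to the Pearson correlation) and lies in (-1, 1);
  its 95% CI uses the t distribution with n - 2 df. Raw-scale slopes are
  available via ``standardize=False``.
* Quartiles use linear interpolation (numpy's default percentile method).
* Missing CRs are pairwise-deleted by default; listwise deletion by flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigurationError
from .timepoints import CR_VARIABLES

__all__ = ["spearman", "correlation_matrix", "standardized_regression",
            "median_iqr", "association_table", "CR_VARIABLES"]


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and p-value (t approximation, ties averaged).

    Returns ``(nan, nan)`` for a constant vector (undefined correlation).
    Requires at least 3 complete pairs.
    """
    x, y = _complete_pairs(x, y)
    if len(x) < 3:
        raise ConfigurationError("spearman needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def correlation_matrix(table: pd.DataFrame,
                       columns=None,
                       listwise: bool = False) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix over the CR variables.

    Symmetric with unit diagonal; missing values are pairwise-deleted unless
    ``listwise``. Use :func:`upper_triangle` for the reporting layout.
    """
    columns = list(columns) if columns is not None else [c for c in CR_VARIABLES
                                                         if c in table.columns]
    data = table[columns]
    if listwise:
        data = data.dropna()
    if len(data) < 3:
        raise ConfigurationError("correlation matrix needs at least 3 subjects")
    mat = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for a, b in combinations(columns, 2):
        try:
            r, _ = spearman(data[a], data[b])
        except ConfigurationError:
            r = float("nan")
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def upper_triangle(mat: pd.DataFrame) -> pd.DataFrame:
    """Reporting layout: rows drop the last variable, columns the first,
    lower triangle blanked."""
    out = mat.iloc[:-1, 1:].copy()
    cols = list(mat.columns)
    for i, row in enumerate(out.index):
        for j, col in enumerate(out.columns):
            if cols.index(col) <= cols.index(row):
                out.loc[row, col] = np.nan
    return out


def standardized_regression(x, y,
                            standardize: bool = True) -> tuple[float, float, float]:
    """Simple linear regression of ``y`` on ``x``: ``(beta, ci_low, ci_high)``.

    With ``standardize`` (default) both variables are z-scored first, making
    beta the standardized coefficient; the 95% CI comes from the t
    distribution with n - 2 degrees of freedom.
    """
    x, y = _complete_pairs(x, y)
    if len(x) < 4:
        raise ConfigurationError("regression needs at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("regression requires nonconstant x and y")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    beta = float(model.params[1])
    lo, hi = model.conf_int(alpha=0.05)[1]
    return beta, float(lo), float(hi)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles ``(median, q1, q3)`` by linear interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ConfigurationError("median_iqr needs at least one finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def association_table(table: pd.DataFrame,
                      covariate: str,
                      cr_columns=None) -> pd.DataFrame:
    """Per-CR association with one covariate: Spearman r/p and standardized
    beta with its 95% CI (one row per CR variable)."""
    cr_columns = list(cr_columns) if cr_columns is not None else [
        c for c in CR_VARIABLES if c in table.columns]
    rows = []
    for col in cr_columns:
        rec = {"cr_variable": col}
        try:
            rec["spearman_r"], rec["spearman_p"] = spearman(table[col], table[covariate])
        except ConfigurationError:
            rec["spearman_r"] = rec["spearman_p"] = float("nan")
        try:
            b, lo, hi = standardized_regression(table[col], table[covariate])
            rec["beta"], rec["ci_low"], rec["ci_high"] = b, lo, hi
        except ConfigurationError:
            rec["beta"] = rec["ci_low"] = rec["ci_high"] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cr_variable")


def summary_table(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Median [IQR] summary of the given columns (one row per column)."""
    rows = []
    for col in columns:
        med, q1, q3 = median_iqr(table[col])
        rows.append({"variable": col, "median": med, "q1": q1, "q3": q3,
                     "n": int(np.isfinite(pd.to_numeric(table[col], errors="coerce")).sum())})
    return pd.DataFrame(rows).set_index("variable")
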