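"""Validation battery for a built index.

Construct validity: OLS regressions of tract outcomes on septile indicator
variables (septile 1, the least advantaged group, as reference), the
model-implied septile contrasts, and a test of trend across the ordered
septiles (OLS on the septile coded 1-7). Criterion validity: squared
Pearson correlation between the built index and an external reference
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SeptileRegression",
    "ValidationReport",
    "fit_septile_regression",
    "trend_test",
    "septile_contrast",
    "criterion_r2",
    "validate_index",
]

_SEPTILES = tuple(range(1, 8))


@dataclass(frozen=True)
class SeptileRegression:
    """OLS fit of an outcome on septile indicators, reference septile 1.

    ``coef[k]`` for k in 2..7 is the model-implied mean difference between
    septile k and septile 1; the intercept is the septile-1 mean. Because
    the model is a saturated one-way layout, fitted values equal the
    within-septile sample means exactly.
    """

    outcome: str
    intercept: float
    coef: dict[int, float]
    se: dict[int, float]
    pvalues: dict[int, float]
    r_squared: float
    f_pvalue: float
    n: int


def _check_septiles(septiles: np.ndarray) -> np.ndarray:
    s = np.asarray(septiles, dtype=int)
    bad = set(np.unique(s)) - set(_SEPTILES)
    if bad:
        raise ValueError(f"septile labels outside 1..7: {sorted(bad)}")
    empty = [k for k in _SEPTILES if not (s == k).any()]
    if empty:
        raise ValueError(
            f"septile(s) {empty} contain no tracts; use more tracts so every "
            "septile is populated"
        )
    return s


def fit_septile_regression(outcome, septiles, name: str = "outcome") -> SeptileRegression:
    """OLS of an outcome on indicators for septiles 2-7 (septile 1 reference)."""
    y = np.asarray(outcome, dtype=float)
    s = _check_septiles(septiles)
    if len(y) != len(s):
        raise ValueError("outcome and septile vectors differ in length")
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    X = np.column_stack([(s == k).astype(float) for k in _SEPTILES[1:]])
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    coef = {k: float(fit.params[i + 1]) for i, k in enumerate(_SEPTILES[1:])}
    se = {k: float(fit.bse[i + 1]) for i, k in enumerate(_SEPTILES[1:])}
    pv = {k: float(fit.pvalues[i + 1]) for i, k in enumerate(_SEPTILES[1:])}
    return SeptileRegression(
        outcome=name,
        intercept=float(fit.params[0]),
        coef=coef,
        se=se,
        pvalues=pv,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=len(y),
    )


def trend_test(outcome, septiles) -> tuple[float, float]:
    """Test of trend: OLS of the outcome on the septile coded 1-7.

    Returns the slope's t-statistic and its two-sided p-value. A positive
    statistic indicates the outcome increases with advantage.
    """
    y = np.asarray(outcome, dtype=float)
    s = _check_septiles(septiles).astype(float)
    X = sm.add_constant(s)
    fit = sm.OLS(y, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def septile_contrast(report: SeptileRegression, a: int, b: int) -> float:
    """Model-implied mean outcome difference between septiles ``a`` and ``b``.

    With ``b`` equal to the reference septile 1 this is just the septile-``a``
    coefficient."""
    full = {1: 0.0, **report.coef}
    if a not in full or b not in full:
        raise ValueError(f"unknown septile label in contrast ({a}, {b})")
    return full[a] - full[b]


def criterion_r2(index_a, index_b) -> float:
    """Squared Pearson correlation between two per-tract indices."""
    x = np.asarray(index_a, dtype=float)
    y = np.asarray(index_b, dtype=float)
    if len(x) != len(y):
        raise ValueError("indices differ in length")
    if len(x) < 3:
        raise ValueError("criterion R^2 requires at least 3 joined tracts")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("criterion R^2 undefined for a constant index")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ValidationReport:
    """Full validation output: one septile regression, trend test, and
    7-vs-1 contrast per outcome, plus optional criterion R^2."""

    regressions: dict[str, SeptileRegression]
    trend: dict[str, tuple[float, float]]
    contrast_7_vs_1: dict[str, float]
    criterion_r_squared: float | None = None

    def to_dict(self) -> dict:
        out: dict = {"outcomes": {}}
        for name, reg in self.regressions.items():
            t_stat, t_p = self.trend[name]
            out["outcomes"][name] = {
                "n": reg.n,
                "intercept": reg.intercept,
                "coefficients": {str(k): reg.coef[k] for k in sorted(reg.coef)},
                "standard_errors": {str(k): reg.se[k] for k in sorted(reg.se)},
                "p_values": {str(k): reg.pvalues[k] for k in sorted(reg.pvalues)},
                "r_squared": reg.r_squared,
                "overall_p": reg.f_pvalue,
                "contrast_septile7_vs_1": self.contrast_7_vs_1[name],
                "trend_statistic": t_stat,
                "trend_p": t_p,
            }
        if self.criterion_r_squared is not None:
            out["criterion_r_squared"] = self.criterion_r_squared
        return out


def validate_index(
    index_frame: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_columns: tuple[str, ...] = ("life_expectancy", "pct_black", "pct_minority"),
    reference_column: str | None = None,
) -> ValidationReport:
    """Join a built index to an outcome table on ``fips`` and run the full
    battery for each available outcome column."""
    joined = index_frame.merge(outcomes, on="fips", how="inner", validate="one_to_one")
    if joined.empty:
        raise ValueError("index and outcome tables share no fips keys")
    regressions: dict[str, SeptileRegression] = {}
    trend: dict[str, tuple[float, float]] = {}
    contrast: dict[str, float] = {}
    for col in outcome_columns:
        if col not in joined.columns:
            continue
        reg = fit_septile_regression(joined[col], joined["septile"], name=col)
        regressions[col] = reg
        trend[col] = trend_test(joined[col], joined["septile"])
        contrast[col] = septile_contrast(reg, 7, 1)
    if not regressions:
        raise ValueError(f"none of the outcome columns {outcome_columns} are present")
    r2 = None
    if reference_column is not None:
        if reference_column not in joined.columns:
            raise ValueError(f"reference column {reference_column!r} not found")
        r2 = criterion_r2(joined["ocoi_score"], joined[reference_column])
    return ValidationReport(
        regressions=regressions,
        trend=trend,
        contrast_7_vs_1=contrast,
        criterion_r_squared=r2,
    )
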