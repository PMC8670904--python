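"""Baseline regressors, error metrics, and the clinical comparison statistics.

Per-beat blood-pressure predictors are compared on mean absolute error,
reported as ``MAE ± SD of the absolute errors`` (mmHg) together with the
fraction of beats within 5 mmHg.  Baselines are ordinary linear regression
and a random forest, each fed either the two transit-time features ("PTT")
or the fixed-length PPG waveform ("PPG").  The clinical group comparisons
use the uncorrected Pearson chi-square test on 2x2 tables and the
pooled-variance two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

__all__ = [
    "EvalReport",
    "fit_linear_regression",
    "fit_random_forest",
    "evaluate",
    "pearson_chi_square",
    "two_sample_t_test",
]


@dataclass(frozen=True)
class EvalReport:
    """Prediction-error summary for one method and one target."""

    mae: float            # mean absolute error, mmHg
    sd_abs_error: float   # SD of the absolute errors, mmHg
    within_5mmhg: float   # fraction of beats with |error| <= 5 mmHg
    n: int

    def __str__(self) -> str:
        return (
            f"{self.mae:.2f} ± {self.sd_abs_error:.2f} mmHg "
            f"({100 * self.within_5mmhg:.1f}% within 5 mmHg, n={self.n})"
        )


def fit_linear_regression(features, targets):
    """Ordinary least-squares regressor; rejects constant feature columns."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 examples")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("a feature column is constant; linear regression is degenerate")
    return LinearRegression().fit(x, y)


def fit_random_forest(features, targets, n_estimators: int = 100, seed: int = 0):
    """Random forest regressor (100 trees, unlimited depth, seeded)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 examples")
    return RandomForestRegressor(n_estimators=n_estimators, random_state=seed).fit(x, y)


def evaluate(predictions, truth, mode: str = "mae") -> EvalReport:
    """Summarize per-beat prediction errors.

    ``mode="mae"`` (default) reports mean ± SD of the *absolute* errors;
    ``mode="me"`` reports mean ± SD of the signed errors in the same fields.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError(f"length mismatch: {predictions.shape} vs {truth.shape}")
    err = predictions - truth
    abs_err = np.abs(err)
    if mode == "mae":
        center, spread = abs_err.mean(), abs_err.std()
    elif mode == "me":
        center, spread = err.mean(), err.std()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EvalReport(
        mae=float(center),
        sd_abs_error=float(spread),
        within_5mmhg=float(np.mean(abs_err <= 5.0)),
        n=int(err.size),
    )


def pearson_chi_square(table, correction: bool = False):
    """Pearson chi-square test for a 2x2 contingency table.

    Uses the uncorrected statistic ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``
    by default; ``correction=True`` applies the Yates continuity correction.
    Returns ``(statistic, df, p_value)`` with ``df = 1``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined: a table margin is zero")
    (a, b), (c, d) = t
    n = t.sum()
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    statistic = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), 1, p


def two_sample_t_test(a, b):
    """Two-sided pooled-variance t test; returns ``(t, df, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("t test undefined: pooled variance is zero")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), int(df), p
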