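"""Method-comparison statistics.

Compares algorithm-derived trait values ("observed") against a
reference method ("standard"): RMSE, MAE, residual standard error
(RSE), percent-normalized variants, and an ordinary-least-squares
linear fit with R², slope, and intercept.

Definitions
-----------
RMSE = sqrt( (1/n) Σ (o_i − s_i)² )
MAE  = (1/n) Σ |o_i − s_i|
RSE  = sqrt( Σ (o_i − s_i)² / df ),  df defaulting to n − 2

Percent metrics divide each absolute metric by mean(standard) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .errors import ContractViolationError, DegenerateFitError

__all__ = [
    "MethodComparison",
    "ComparisonReport",
    "rmse",
    "mae",
    "rse",
    "percent_metrics",
    "linear_fit",
    "compare",
    "prediction_band",
]


@dataclass(frozen=True)
class MethodComparison:
    """Paired observations from two measurement methods.

    ``observed`` holds the algorithm-derived values, ``standard`` the
    reference-method values.  ``df`` is the residual degrees of freedom
    used by RSE; it defaults to n − 2 (two-parameter linear fit).
    """

    observed: np.ndarray
    standard: np.ndarray
    df: int | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        std = np.asarray(self.standard, dtype=float)
        if obs.ndim != 1 or std.ndim != 1:
            raise ContractViolationError("observed and standard must be 1-D vectors")
        if obs.shape != std.shape:
            raise ContractViolationError(
                f"length mismatch: observed has {obs.size}, standard has {std.size}"
            )
        if obs.size < 2:
            raise ContractViolationError("need at least 2 paired observations")
        df = self.df if self.df is not None else max(obs.size - 2, 1)
        if df < 1:
            raise ContractViolationError(f"df must be >= 1; got {df}")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "standard", std)
        object.__setattr__(self, "df", int(df))

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.standard


@dataclass(frozen=True)
class ComparisonReport:
    """Full metric set for one trait comparison."""

    n: int
    rmse: float
    mae: float
    rse: float
    rmse_pct: float
    mae_pct: float
    rse_pct: float
    r2: float
    slope: float
    intercept: float


def rmse(cmp: MethodComparison) -> float:
    """Root mean square error of observed against standard."""
    return float(np.sqrt(np.mean(cmp.residuals**2)))


def mae(cmp: MethodComparison) -> float:
    """Mean absolute error of observed against standard."""
    return float(np.mean(np.abs(cmp.residuals)))


def rse(cmp: MethodComparison) -> float:
    """Residual standard error: sqrt(RSS / df)."""
    return float(np.sqrt(np.sum(cmp.residuals**2) / cmp.df))


def percent_metrics(cmp: MethodComparison) -> tuple[float, float, float]:
    """(rmse_pct, mae_pct, rse_pct): each metric / mean(standard) × 100."""
    mean_std = float(np.mean(cmp.standard))
    if mean_std == 0:
        raise ContractViolationError("percent normalization undefined: mean(standard) is 0")
    scale = 100.0 / mean_std
    return (rmse(cmp) * scale, mae(cmp) * scale, rse(cmp) * scale)


def linear_fit(cmp: MethodComparison) -> tuple[float, float, float]:
    """OLS fit of observed on standard: returns (r2, slope, intercept)."""
    if cmp.n < 3:
        raise ContractViolationError("linear fit needs at least 3 points")
    if np.ptp(cmp.standard) == 0:
        raise DegenerateFitError("standard vector is constant; fit is degenerate")
    res = _stats.linregress(cmp.standard, cmp.observed)
    return (float(res.rvalue**2), float(res.slope), float(res.intercept))


def compare(cmp: MethodComparison) -> ComparisonReport:
    """Compute every metric at once."""
    rmse_pct, mae_pct, rse_pct = percent_metrics(cmp)
    r2, slope, intercept = linear_fit(cmp)
    return ComparisonReport(
        n=cmp.n,
        rmse=rmse(cmp),
        mae=mae(cmp),
        rse=rse(cmp),
        rmse_pct=rmse_pct,
        mae_pct=mae_pct,
        rse_pct=rse_pct,
        r2=r2,
        slope=slope,
        intercept=intercept,
    )


def prediction_band(
    cmp: MethodComparison, x: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS fitted line with symmetric prediction bands at ``level``.

    Returns ``(fitted, lower, upper)`` evaluated at ``x``; used for the
    optional fit-of-plot output.
    """
    _, slope, intercept = linear_fit(cmp)
    x = np.asarray(x, dtype=float)
    s = cmp.standard
    fitted = intercept + slope * x
    resid = cmp.observed - (intercept + slope * s)
    n = cmp.n
    dof = n - 2
    sigma = np.sqrt(np.sum(resid**2) / dof)
    sxx = np.sum((s - s.mean()) ** 2)
    se = sigma * np.sqrt(1 + 1 / n + (x - s.mean()) ** 2 / sxx)
    t = _stats.t.ppf(0.5 + level / 2, dof)
    return fitted, fitted - t * se, fitted + t * se
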