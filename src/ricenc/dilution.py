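"""The power-law critical-N dilution curve, NNI, and shared statistics.

The critical nitrogen concentration N_C (% of dry weight) is the minimum
plant N concentration that still permits maximum growth at a given
aboveground biomass DW (t ha⁻¹).  It declines with biomass as structural
tissue accumulates and is modelled as

    N_C = a · DW^(−b)

where *a* is the plant N concentration at DW = 1 t ha⁻¹ and *b* the
dimensionless dilution exponent.  The nitrogen nutrition index
NNI = N_measured / N_C diagnoses N status (1 = optimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    DomainError,
    FitError,
    InsufficientDataError,
    UnderdeterminedFitError,
)

# Nonlinear least-squares settings for the power fit.
FIT_TOL = 1e-8
FIT_MAX_ITER = 500


@dataclass
class DilutionCurve:
    """A fitted (or assumed) critical-N dilution curve ``a · DW^(−b)``.

    ``provenance`` records which route produced the curve: SDM (simple
    data-mixing of critical points), Average (mean of measured specific
    parameters), RFA (mean of random-forest-estimated parameters),
    BHM-Mean / BHM-Median / BHM-MPN (posterior summaries), or
    ``specific`` for a single-group curve.
    """

    a: float
    b: float
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    provenance: str = "specific"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise DomainError(f"parameter a must be > 0, got {self.a}")
        if not (0 <= self.b < 1):
            raise DomainError(f"parameter b must be in [0, 1), got {self.b}")


@dataclass
class NCPoint:
    """One critical point (DW_c, N_c) determined at a sampling date."""

    dw_c: float
    nc: float
    stage: str | None = None
    experiment_id: str | None = None
    extrapolated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.dw_c > 0 or not self.nc > 0:
            raise DomainError("NCPoint requires dw_c > 0 and nc > 0")


def critical_n(curve: DilutionCurve, dw) -> float | np.ndarray:
    """Critical N concentration (%) at biomass ``dw`` (t ha⁻¹).

    At DW = 1 t ha⁻¹ this returns *a* by definition; for b > 0 the value
    strictly decreases with biomass.
    """
    dw = np.asarray(dw, dtype=float)
    if np.any(dw <= 0):
        raise DomainError("dw must be > 0")
    out = curve.a * dw ** (-curve.b)
    return float(out) if out.ndim == 0 else out


def nni(measured_n, critical) -> float | np.ndarray:
    """Nitrogen nutrition index: measured N% over critical N%.

    > 1 indicates N surplus, 1 suitability, < 1 deficiency.
    """
    critical = np.asarray(critical, dtype=float)
    if np.any(critical <= 0):
        raise DomainError("critical N must be > 0")
    out = np.asarray(measured_n, dtype=float) / critical
    return float(out) if out.ndim == 0 else out


def fit_power_curve(
    points: Sequence[NCPoint] | None = None,
    *,
    dw: np.ndarray | None = None,
    nc: np.ndarray | None = None,
    provenance: str = "specific",
) -> DilutionCurve:
    """Least-squares fit of ``nc = a · dw^(−b)`` on the original scale.

    Accepts either a sequence of :class:`NCPoint` or raw ``dw``/``nc``
    arrays.  The fit is initialized from ordinary least squares on
    ``log(nc) ~ log(dw)`` and refined by nonlinear least squares, so on
    noise-free power-law points it returns the generating parameters to
    numerical tolerance.
    """
    if points is not None:
        dw = np.array([p.dw_c for p in points], dtype=float)
        nc = np.array([p.nc for p in points], dtype=float)
    dw = np.asarray(dw, dtype=float)
    nc = np.asarray(nc, dtype=float)
    if dw.size < 2 or np.unique(dw).size < 2:
        raise UnderdeterminedFitError(
            "need >= 2 critical points with distinct dw"
        )
    if np.any(dw <= 0) or np.any(nc <= 0):
        raise DomainError("dw and nc must be > 0 for the power fit")

    # log-log OLS initialization: log nc = log a - b log dw
    slope, intercept = np.polyfit(np.log(dw), np.log(nc), 1)
    a0 = float(np.exp(intercept))
    b0 = float(np.clip(-slope, 0.0, 0.999))

    def residuals(theta):
        return theta[0] * dw ** (-theta[1]) - nc

    res = optimize.least_squares(
        residuals,
        x0=[a0, b0],
        bounds=([1e-12, -0.999], [np.inf, 0.999]),
        xtol=FIT_TOL,
        ftol=FIT_TOL,
        gtol=FIT_TOL,
        max_nfev=FIT_MAX_ITER,
    )
    if not res.success:
        raise FitError(f"power fit did not converge: {res.message}")
    a_hat, b_hat = float(res.x[0]), float(res.x[1])
    # flat data legitimately yields b == 0 (up to solver tolerance)
    b_hat = max(0.0, b_hat) if abs(b_hat) < 1e-10 else b_hat
    if b_hat < 0:
        b_hat = 0.0
        a_hat = float(np.mean(nc))
    return DilutionCurve(a=a_hat, b=b_hat, provenance=provenance)


def sd_cv(values: Sequence[float]) -> tuple[float, float]:
    """Sample standard deviation (n−1 denominator) and CV = SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("sd_cv needs n >= 2")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0.0:
        return 0.0, 0.0
    if mean == 0.0:
        raise DomainError("CV undefined for zero mean")
    return sd, sd / mean


def fluctuation_range(values: Sequence[float]) -> float:
    """Distribution range over the mean: ``(max − min) / mean``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("fluctuation_range needs n >= 2")
    mean = float(np.mean(x))
    if mean <= 0:
        raise DomainError("fluctuation_range requires mean > 0")
    return float((x.max() - x.min()) / mean)


def r2(estimated: Sequence[float], measured: Sequence[float]) -> float:
    """Coefficient of determination as the squared Pearson correlation."""
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.size != m.size or e.size < 2:
        raise InsufficientDataError("r2 needs equal lengths >= 2")
    if np.std(e) == 0 or np.std(m) == 0:
        raise DomainError("r2 undefined when either sequence is constant")
    return float(stats.pearsonr(e, m).statistic ** 2)


def rrmse(estimated: Sequence[float], measured: Sequence[float]) -> float:
    """Relative RMSE: root-mean-square error over the measured mean."""
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.size != m.size or e.size < 1:
        raise InsufficientDataError("rrmse needs equal lengths >= 1")
    mbar = float(np.mean(m))
    if mbar == 0:
        raise DomainError("rrmse undefined for zero measured mean")
    return float(np.sqrt(np.mean((e - m) ** 2)) / mbar)


def curves_to_frame(curves: Sequence[DilutionCurve]) -> pd.DataFrame:
    """Tabulate curves as one row each (the curves CSV schema)."""
    rows = []
    for c in curves:
        ci_a = c.ci_a or (np.nan, np.nan)
        ci_b = c.ci_b or (np.nan, np.nan)
        rows.append(
            {
                "provenance": c.provenance,
                "a": c.a,
                "b": c.b,
                "ci_a_low": ci_a[0],
                "ci_a_high": ci_a[1],
                "ci_b_low": ci_b[0],
                "ci_b_high": ci_b[1],
            }
        )
    return pd.DataFrame(rows)
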