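"""Simple data-mixing (SDM): the traditional critical-point route.

Per experiment and sampling date the N-rate treatments are split into
N-limiting and non-N-limiting sets by one-way ANOVA on plot biomass
followed by an LSD-style comparison against the highest-biomass
treatment (pooled error variance, default α = 0.05).  The critical
point of the date is the intersection of the linear biomass response
fitted over the limiting treatment means with the plateau (mean biomass
of non-limiting treatments).  All critical points are pooled and fitted
to one power curve; uncertainty comes from a case-resampling bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dilution import DilutionCurve, NCPoint, fit_power_curve
from .exceptions import (
    InsufficientReplicationError,
    NonResponsiveDateError,
    UnderdeterminedFitError,
)
from .indicators import add_derived_columns

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


@dataclass
class DateGroup:
    """Replicate biomass and N% observations of one experiment × date."""

    experiment_id: str
    stage: str
    # parallel per-treatment arrays; dw[i]/nconc[i] hold that treatment's reps
    n_rates: np.ndarray
    dw: list[np.ndarray]
    nconc: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.dw) < 3:
            raise InsufficientReplicationError(
                f"{self.experiment_id}/{self.stage}: need >= 3 treatments"
            )
        if any(len(x) < 2 for x in self.dw):
            raise InsufficientReplicationError(
                f"{self.experiment_id}/{self.stage}: every treatment needs "
                ">= 2 replicates"
            )

    @property
    def dw_means(self) -> np.ndarray:
        return np.array([np.mean(x) for x in self.dw])

    @property
    def n_means(self) -> np.ndarray:
        return np.array([np.mean(x) for x in self.nconc])


@dataclass
class LimitingLabels:
    """Per-treatment limiting / non-limiting labels for one date."""

    limiting: np.ndarray  # boolean, True = N-limiting
    usable: bool          # False when the date carries no information
    reason: str = ""

    @property
    def n_limiting(self) -> int:
        return int(self.limiting.sum())

    @property
    def n_non_limiting(self) -> int:
        return int((~self.limiting).sum())


def build_date_groups(
    samples: pd.DataFrame, group_col: str = "experiment_id"
) -> list[DateGroup]:
    """Assemble per-(experiment, date) replicate groups from raw samples."""
    df = add_derived_columns(samples)
    out = []
    for (gid, date), g in df.groupby([group_col, "date"], sort=True):
        rates = np.sort(g["n_rate"].unique())
        out.append(
            DateGroup(
                experiment_id=str(gid),
                stage=str(g["stage"].iloc[0]),
                n_rates=rates,
                dw=[g.loc[g["n_rate"] == r, "dw"].to_numpy(float)
                    for r in rates],
                nconc=[g.loc[g["n_rate"] == r, "plant_n_conc"].to_numpy(float)
                       for r in rates],
            )
        )
    return out


def classify_limiting(group: DateGroup, alpha: float = 0.05) -> LimitingLabels:
    """Label each treatment N-limiting or non-N-limiting.

    Overall one-way ANOVA across treatments first; if it is not
    significant at ``alpha`` the date is flagged unusable (all labels
    non-limiting).  Otherwise each treatment is compared against the
    highest-mean treatment with a one-sided LSD test using the pooled
    within-treatment error variance; significantly lower → limiting.
    Degenerate zero-variance data falls back to exact mean comparison.
    """
    means = group.dw_means
    n_per = np.array([len(x) for x in group.dw])
    n_total = int(n_per.sum())
    k = len(means)
    df_err = n_total - k
    sse = float(sum(np.sum((x - m) ** 2) for x, m in zip(group.dw, means)))
    mse = sse / df_err

    if np.ptp(means) < _ZERO_VAR_TOL and mse < _ZERO_VAR_TOL:
        return LimitingLabels(
            limiting=np.zeros(k, bool),
            usable=False,
            reason="all treatments identical",
        )

    if mse < _ZERO_VAR_TOL:
        # zero replicate noise: any strictly lower mean is limiting
        limiting = means < means.max() - _ZERO_VAR_TOL
    else:
        f_stat, p = stats.f_oneway(*group.dw)
        if not p < alpha:
            return LimitingLabels(
                limiting=np.zeros(k, bool),
                usable=False,
                reason=f"ANOVA not significant (p={p:.3g})",
            )
        top = int(np.argmax(means))
        t_crit = stats.t.ppf(1.0 - alpha, df_err)
        se = np.sqrt(mse * (1.0 / n_per[top] + 1.0 / n_per))
        t_vals = (means[top] - means) / se
        limiting = t_vals > t_crit
        limiting[top] = False

    if limiting.sum() == 0:
        return LimitingLabels(
            limiting=limiting, usable=False, reason="no limiting treatment"
        )
    if (~limiting).sum() == 0:  # pragma: no cover - top is never limiting
        return LimitingLabels(
            limiting=limiting, usable=False, reason="no non-limiting treatment"
        )
    return LimitingLabels(limiting=limiting, usable=True)


def determine_nc_point(group: DateGroup, labels: LimitingLabels) -> NCPoint:
    """Critical point of one date via the linear-plateau intersection.

    The oblique branch ``DW = α + β·N%`` is fitted over the limiting
    treatment means; the plateau is the mean biomass of non-limiting
    treatments; the critical N concentration is where the line reaches
    the plateau.
    """
    if labels.n_limiting < 2 or labels.n_non_limiting < 1:
        raise UnderdeterminedFitError(
            "need >= 2 limiting and >= 1 non-limiting treatments"
        )
    lim = labels.limiting
    x = group.n_means[lim]
    y = group.dw_means[lim]
    beta, alpha_int = np.polyfit(x, y, 1)
    if beta <= 0:
        raise NonResponsiveDateError(
            f"{group.experiment_id}/{group.stage}: fitted slope "
            f"{beta:.3g} <= 0"
        )
    dw_max = float(group.dw_means[~lim].mean())
    nc = (dw_max - alpha_int) / beta
    n_all = np.concatenate([np.asarray(v) for v in group.nconc])
    span = n_all.max() - n_all.min()
    extrapolated = not (
        n_all.min() - 0.5 * span <= nc <= n_all.max() + 0.5 * span
    )
    if extrapolated:
        logger.warning(
            "%s/%s: critical N %.3f outside observed N range ±50%%",
            group.experiment_id, group.stage, nc,
        )
    return NCPoint(
        dw_c=dw_max,
        nc=float(nc),
        stage=group.stage,
        experiment_id=group.experiment_id,
        extrapolated=extrapolated,
    )


def determine_all_nc_points(
    groups: Sequence[DateGroup], alpha: float = 0.05
) -> tuple[list[NCPoint], list[str]]:
    """Critical points for every usable date; skipped dates are logged."""
    points, skipped = [], []
    for g in groups:
        labels = classify_limiting(g, alpha=alpha)
        if not labels.usable or labels.n_limiting < 2:
            skipped.append(f"{g.experiment_id}/{g.stage}: {labels.reason or 'too few limiting treatments'}")
            continue
        try:
            points.append(determine_nc_point(g, labels))
        except NonResponsiveDateError as exc:
            skipped.append(str(exc))
    for msg in skipped:
        logger.info("skipped date: %s", msg)
    return points, skipped


def fit_sdm_curve(points: Sequence[NCPoint]) -> DilutionCurve:
    """Pool all critical points and fit the mixed power curve."""
    if len(points) < 3:
        raise UnderdeterminedFitError("SDM fit needs >= 3 critical points")
    dw = np.array([p.dw_c for p in points])
    if dw.max() - dw.min() < 1.0:
        raise UnderdeterminedFitError(
            "critical points must span >= 1 t/ha of biomass"
        )
    return fit_power_curve(points, provenance="SDM")


@dataclass
class BootstrapBand:
    """Percentile confidence band of the fitted curve over a biomass grid."""

    dw_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_degenerate: int = 0
    curves: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.upper - self.lower))


def bootstrap_band(
    curve: DilutionCurve,
    points: Sequence[NCPoint],
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    dw_grid: np.ndarray | None = None,
) -> BootstrapBand:
    """Case-resampling bootstrap band around the fitted power curve."""
    if len(points) < 3:
        raise UnderdeterminedFitError("bootstrap needs >= 3 points")
    dw = np.array([p.dw_c for p in points])
    nc = np.array([p.nc for p in points])
    if dw_grid is None:
        dw_grid = np.linspace(dw.min(), dw.max(), 50)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, dw_grid.size), np.nan)
    n_degenerate = 0
    params = []
    for i in range(n_boot):
        idx = rng.integers(0, dw.size, size=dw.size)
        if np.unique(dw[idx]).size < 2:
            n_degenerate += 1
            continue
        try:
            c = fit_power_curve(dw=dw[idx], nc=nc[idx])
        except Exception:  # non-convergent resample: skip, like degenerate
            n_degenerate += 1
            continue
        params.append((c.a, c.b))
        boots[i] = c.a * dw_grid ** (-c.b)
    q = (1.0 - level) / 2.0
    lower = np.nanpercentile(boots, 100 * q, axis=0)
    upper = np.nanpercentile(boots, 100 * (1 - q), axis=0)
    return BootstrapBand(
        dw_grid=dw_grid,
        lower=lower,
        upper=upper,
        level=level,
        n_degenerate=n_degenerate,
        curves=pd.DataFrame(params, columns=["a", "b"]),
    )


def run_sdm(
    samples: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "experiment_id",
    with_band: bool = False,
    seed: int = 0,
    exclude_extrapolated: bool = True,
) -> tuple[DilutionCurve, list[NCPoint], list[str]]:
    """Full SDM route: classify → critical points → mixed power curve.

    Critical points whose N concentration falls far outside the observed
    N range of their date (extrapolation-flagged) are kept in the point
    list but excluded from the pooled fit by default — a plot-level
    quality control against unstable early-season intersections.
    """
    groups = build_date_groups(samples, group_col=group_col)
    points, skipped = determine_all_nc_points(groups, alpha=alpha)
    fit_points = (
        [p for p in points if not p.extrapolated]
        if exclude_extrapolated
        else points
    )
    if len(fit_points) < 3:
        fit_points = points
    curve = fit_sdm_curve(fit_points)
    if with_band:
        band = bootstrap_band(curve, fit_points, seed=seed)
        curve.ci_a = (
            float(np.percentile(band.curves["a"], 2.5)),
            float(np.percentile(band.curves["a"], 97.5)),
        )
        curve.ci_b = (
            float(np.percentile(band.curves["b"], 2.5)),
            float(np.percentile(band.curves["b"], 97.5)),
        )
    return curve, points, skipped


def nc_points_to_frame(points: Sequence[NCPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "experiment_id": p.experiment_id,
                "stage": p.stage,
                "dw_c": p.dw_c,
                "nc": p.nc,
                "extrapolated": p.extrapolated,
            }
            for p in points
        ]
    )
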