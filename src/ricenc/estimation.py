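"""Estimating curve parameters from growth indicators.

Per-indicator screening ranks the 14 candidate indicators by their
univariate R² with the target parameter; the top three feed either a
multiple linear regression or a random-forest regression (500 trees,
per-split feature subset size ``mtry`` tuned to minimise the
leave-one-out cross-validated relative RMSE).  Averaging per-group
estimates yields the universal curve parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .dilution import DilutionCurve, r2 as _r2, rrmse as _rrmse
from .exceptions import InsufficientDataError
from .synthetic import FEATURE_COLUMNS

RF_NTREE = 500


@dataclass
class EstimatorReport:
    """One row of the method-comparison table."""

    method: str              # "MLR" | "RF"
    target: str              # "a" | "b"
    predictors: list[str]
    modeling_r2: float
    loocv_r2: float
    loocv_rrmse: float
    mtry: int | None = None
    loocv_predictions: np.ndarray | None = None


def indicator_r2(
    features: pd.DataFrame,
    targets: Sequence[float],
    columns: Sequence[str] = tuple(FEATURE_COLUMNS),
) -> pd.DataFrame:
    """Univariate R² of each indicator with the target parameter.

    Constant (degenerate) indicators are reported with R² = 0 and
    flagged rather than erroring, so screening stays total.
    """
    y = np.asarray(targets, float)
    if y.size < 5:
        raise InsufficientDataError("indicator screening needs >= 5 groups")
    rows = []
    for c in columns:
        x = features[c].to_numpy(float)
        degenerate = np.std(x) == 0 or np.std(y) == 0
        rows.append(
            {
                "indicator": c,
                "r2": 0.0 if degenerate else _r2(x, y),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def select_predictors(r2_table: pd.DataFrame, k: int = 3) -> list[str]:
    """Top-k indicators by R²; ties break by fixed column order."""
    if len(r2_table) < k:
        raise InsufficientDataError(f"need >= {k} indicators")
    order = np.argsort(-r2_table["r2"].to_numpy(), kind="stable")
    return r2_table["indicator"].to_numpy()[order][:k].tolist()


def _loocv_predict(make_model, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One held-out prediction per record, each trained without it."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = make_model()
        model.fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def fit_and_validate(
    method: str,
    X: pd.DataFrame,
    y: Sequence[float],
    target: str = "a",
    rf_ntree: int = RF_NTREE,
    rf_mtry: int | str = "auto",
    seed: int = 0,
) -> EstimatorReport:
    """Fit MLR or RF on the selected predictors and LOOCV-validate it.

    ``rf_mtry="auto"`` scans every feasible per-split feature count and
    keeps the one with the smallest LOOCV RRMSE (smaller mtry wins ties).
    Constant targets short-circuit: both methods predict the constant
    with RRMSE 0 (modeling/validation R² are undefined and reported 0).
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float)
    predictors = list(X.columns)
    if method == "MLR" and len(ya) < len(predictors) + 2:
        raise InsufficientDataError("MLR needs >= predictors + 2 records")
    if len(ya) < 6:
        raise InsufficientDataError("fit_and_validate needs >= 6 records")

    if np.std(ya) == 0:
        const = float(ya[0])
        return EstimatorReport(
            method=method, target=target, predictors=predictors,
            modeling_r2=0.0, loocv_r2=0.0, loocv_rrmse=0.0,
            mtry=None if method == "MLR" else 1,
            loocv_predictions=np.full(len(ya), const),
        )

    if method == "MLR":
        make = LinearRegression
        mtry_used = None
    elif method == "RF":
        if rf_mtry == "auto":
            best = None
            for m in range(1, len(predictors) + 1):
                def make_m(m=m):
                    return RandomForestRegressor(
                        n_estimators=rf_ntree, max_features=m,
                        random_state=seed, n_jobs=1,
                    )
                preds = _loocv_predict(make_m, Xa, ya)
                score = _rrmse(preds, ya)
                if best is None or score < best[0]:
                    best = (score, m, preds)
            mtry_used = best[1]
        else:
            mtry_used = int(rf_mtry)

        def make(m=mtry_used):
            return RandomForestRegressor(
                n_estimators=rf_ntree, max_features=m,
                random_state=seed, n_jobs=1,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    model = make()
    model.fit(Xa, ya)
    fitted = model.predict(Xa)
    if method == "RF" and rf_mtry == "auto":
        loocv = best[2]
    else:
        loocv = _loocv_predict(make, Xa, ya)
    return EstimatorReport(
        method=method,
        target=target,
        predictors=predictors,
        modeling_r2=_r2(fitted, ya) if np.std(fitted) > 0 else 0.0,
        loocv_r2=_r2(loocv, ya) if np.std(loocv) > 0 else 0.0,
        loocv_rrmse=_rrmse(loocv, ya),
        mtry=mtry_used,
        loocv_predictions=loocv,
    )


def universal_from_estimates(
    a_hats: Sequence[float],
    b_hats: Sequence[float],
    provenance: str = "RFA",
) -> DilutionCurve:
    """Universal parameters as the arithmetic means of per-group values."""
    a_hats = np.asarray(a_hats, float)
    b_hats = np.asarray(b_hats, float)
    if a_hats.size < 2 or b_hats.size != a_hats.size:
        raise InsufficientDataError("averaging needs >= 2 groups")
    return DilutionCurve(
        a=float(a_hats.mean()), b=float(b_hats.mean()), provenance=provenance
    )


def compare_groups(
    level_draws: Mapping[str, np.ndarray],
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, str]:
    """Compact letter display for per-level parameter distributions.

    Two levels differ when the central ``level`` interval of the
    difference of their draws excludes zero (draws paired by a seeded
    random permutation when lengths allow; repeated to equal length
    otherwise).  Letters come from the standard insert-and-absorb
    construction: levels sharing no letter differ significantly.
    """
    names = list(level_draws.keys())
    if len(names) < 2:
        raise InsufficientDataError("need >= 2 levels to compare")
    rng = np.random.default_rng(seed)
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    def differs(x, y) -> bool:
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        m = max(x.size, y.size)
        xs = rng.choice(x, size=m, replace=True)
        ys = rng.choice(y, size=m, replace=True)
        diff = xs - ys
        lo, hi = np.percentile(diff, [q_lo, q_hi])
        return lo > 0 or hi < 0

    distinct = {
        frozenset((a, b))
        for a, b in combinations(names, 2)
        if differs(level_draws[a], level_draws[b])
    }
    # insert-and-absorb: start from one letter covering everything, split
    # on each significant pair, drop redundant (absorbed) letters
    letters: list[set[str]] = [set(names)]
    for a, b in (tuple(sorted(p)) for p in sorted(distinct, key=sorted)):
        for grp in [g for g in letters if a in g and b in g]:
            letters.remove(grp)
            ga, gb = grp - {b}, grp - {a}
            for g in (ga, gb):
                if not any(g <= other for other in letters):
                    letters.append(g)
            letters = [
                g for g in letters
                if not any(g < other for other in letters)
            ]
    letters.sort(key=lambda g: sorted(names.index(x) for x in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for i, grp in enumerate(letters):
        for n in names:
            if n in grp:
                out[n] += alphabet[i]
    return out


def reports_to_frame(reports: Sequence[EstimatorReport]) -> pd.DataFrame:
    """Method-comparison CSV schema (mirrors the published layout)."""
    return pd.DataFrame(
        [
            {
                "target": r.target,
                "method": r.method,
                "modeling_r2": r.modeling_r2,
                "validation_r2": r.loocv_r2,
                "validation_rrmse": r.loocv_rrmse,
                "mtry": r.mtry,
                "predictors": "+".join(r.predictors),
            }
            for r in reports
        ]
    )
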