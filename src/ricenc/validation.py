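"""Validating universal curves through the N nutrition index.

A universal curve is useful if the NNI it assigns to each sample agrees
with the NNI from that sample's own group-specific curve (the reference
standard).  Agreement is scored by R² (squared Pearson correlation) and
relative RMSE over all samples; the per-sample diagnosis maps NNI to
deficient / suitable / surplus around 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dilution import DilutionCurve, critical_n, nni, r2, rrmse
from .exceptions import DomainError, MappingError
from .indicators import add_derived_columns


@dataclass
class ValidationResult:
    provenance: str
    n_samples: int
    r2: float
    rrmse: float
    pairs: pd.DataFrame = field(repr=False)  # nni_reference, nni_universal


def validate_universal(
    universal: DilutionCurve,
    specific: Mapping[str, DilutionCurve],
    samples: pd.DataFrame,
    group_col: str = "experiment_id",
) -> ValidationResult:
    """Score a universal curve's NNI against group-specific reference NNI.

    Each sample's NNI is computed twice — with the universal curve and
    with its group's specific curve — and the two vectors are compared.
    ``specific`` may hold the generator's true curves when validating on
    synthetic data.
    """
    df = add_derived_columns(samples)
    missing = sorted(set(df[group_col].astype(str)) - set(specific))
    if missing:
        raise MappingError(f"groups without a specific curve: {missing}")
    if (df["dw"] <= 0).any():
        raise DomainError("all samples need dw > 0")
    dw = df["dw"].to_numpy(float)
    n_meas = df["plant_n_conc"].to_numpy(float)
    nni_uni = nni(n_meas, critical_n(universal, dw))
    a_g = df[group_col].astype(str).map(lambda g: specific[g].a).to_numpy(float)
    b_g = df[group_col].astype(str).map(lambda g: specific[g].b).to_numpy(float)
    nni_ref = n_meas / (a_g * dw ** (-b_g))
    pairs = pd.DataFrame(
        {
            "sample": df.index,
            group_col: df[group_col],
            "dw": dw,
            "measured_n": n_meas,
            "nni_reference": nni_ref,
            "nni_universal": nni_uni,
        }
    )
    return ValidationResult(
        provenance=universal.provenance,
        n_samples=len(pairs),
        r2=r2(nni_uni, nni_ref),
        rrmse=rrmse(nni_uni, nni_ref),
        pairs=pairs,
    )


def diagnose(
    curve: DilutionCurve,
    dw: float,
    measured_n: float,
    band: float = 0.05,
) -> tuple[str, float]:
    """Three-way N status from the NNI with a neutrality band around 1.

    Returns ``(status, nni_value)`` with status in
    {"deficient", "suitable", "surplus"}.  The band is a practical
    convenience; ``band=0`` recovers the strict trichotomy at 1.
    """
    value = nni(measured_n, critical_n(curve, dw))
    if value > 1.0 + band:
        return "surplus", value
    if value < 1.0 - band:
        return "deficient", value
    return "suitable", value
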