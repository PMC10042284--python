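"""Synthetic multi-rate N trials with known true dilution parameters.

Real critical-N studies pool plot-level samples from many experiments;
here each synthetic *group* (a cultivar × region × year × management
combination) carries its own true curve (a, b) drawn from the observed
japonica-rice population (a ~ N(3.56, 0.21), b ~ N(0.34, 0.08),
truncated to the prior supports a ∈ (0, 6), b ∈ (0, 1)).  Biomass at
each sampling date follows a logistic trajectory between 0.5 and
12 t ha⁻¹, and the plot-level biomass response to plant N concentration
is linear-plus-plateau: below the critical concentration
N_c = a · B^(−b) biomass drops linearly with the N deficit; at or above
it the plateau B is reached.  Measurement noise is additive Gaussian.

The generator also emits a 14-indicator feature table whose designated
columns are statistically linked to the true parameters (PH, SLA-T,
DW-V → a; AGDD-T, SLR-T, LAI-V → b through convex-exponential, hence
nonlinear and mutually correlated, links), plus independent negative
controls (TGW, AC) and weakly informative fillers — mirroring the
indicator screening a real trial series would support.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .indicators import SAMPLE_COLUMNS, STAGE_ORDER, WeatherDay

#: The 14 indicator columns, in fixed order (ties in screening break here).
FEATURE_COLUMNS = [
    "TGW", "AC", "PH", "SLA-T", "SLA-V",
    "AGDD", "AGDD-T", "AGDD-V",
    "DW-T", "LAI-T", "SLR-T", "DW-V", "LAI-V", "SLR-V",
]

_CULTIVARS = ["WXJ14", "LXY18", "WYJ19", "YY8", "NJ4", "LJ7", "WYJ24", "NJ9108"]
_REGIONS = ["YZ", "WJ", "RG", "SH", "HA", "XH"]


@dataclass
class SyntheticConfig:
    """Conditions of a simulated trial series.

    Defaults follow the source trial design: 29 groups (one per specific
    curve), N rates 0/135/270/405 kg N ha⁻¹, five sampling dates
    (tillering → heading) and the observed (a, b) population moments.
    """

    n_groups: int = 29
    n_rates: tuple[float, ...] = (0.0, 135.0, 270.0, 405.0)
    n_replicates: int = 3
    n_dates: int = 5
    pop_mean_a: float = 3.56
    pop_sd_a: float = 0.21
    pop_mean_b: float = 0.34
    pop_sd_b: float = 0.08
    dw_noise_sd: float = 0.1
    n_noise_sd: float = 0.08
    feature_noise_sd: float = 0.25
    seed: int = 0
    # N% targets span deficiency to surplus around the critical value
    nmult_lo: float = 0.6
    nmult_hi: float = 1.3
    # plateau biomass trajectory span (t/ha)
    dw_min: float = 0.5
    dw_max: float = 12.0
    # fraction of plateau biomass lost when N% = 0 (sets the slope S_j)
    deficit_slope_frac: float = 0.9

    def __post_init__(self) -> None:
        if min(self.dw_noise_sd, self.n_noise_sd, self.feature_noise_sd) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 (ANOVA replication)")
        if self.n_groups < 1 or self.n_dates < 1 or len(self.n_rates) < 3:
            raise ConfigError("need >= 1 group, >= 1 date, >= 3 N rates")
        if not (0 < self.pop_mean_a < 6 and 0 < self.pop_mean_b < 1):
            raise ConfigError("population means outside prior support")


@dataclass
class TruthRecord:
    """Ground truth for one group: curve parameters and per-date response."""

    group_id: str
    true_a: float
    true_b: float
    plateau_dw: np.ndarray = field(repr=False)   # B_j, strictly increasing
    slope: np.ndarray = field(repr=False)        # S_j > 0, t/ha per %N
    cultivar: str = ""
    region: str = ""
    year: int = 0
    management: str = ""


def _draw_truncated(rng, mean, sd, lo, hi, size):
    """Rejection-sample Normal(mean, sd) truncated to (lo, hi)."""
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw > lo) & (draw < hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate_trial(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Simulate plot-level samples for every group, date, N rate, replicate.

    Returns the samples table (raw-measurement schema consumed by the
    indicators module) and the per-group ground truth.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    a_true = _draw_truncated(
        rng, config.pop_mean_a, config.pop_sd_a, 0.0, 6.0, config.n_groups
    )
    b_true = _draw_truncated(
        rng, config.pop_mean_b, config.pop_sd_b, 0.0, 1.0, config.n_groups
    )

    # logistic biomass trajectory shared in shape, jittered per group
    j = np.arange(config.n_dates, dtype=float)
    center = (config.n_dates - 1) / 2.0
    base_traj = config.dw_min + (config.dw_max - config.dw_min) / (
        1.0 + np.exp(-1.5 * (j - center))
    )
    stages = (STAGE_ORDER * ((config.n_dates // 5) + 1))[: config.n_dates]
    dates = [dt.date(2020, 7, 10) + dt.timedelta(days=12 * int(d)) for d in j]

    # target N% multipliers: evenly spaced from deficiency to surplus
    mults = np.linspace(config.nmult_lo, config.nmult_hi, len(config.n_rates))

    truth: list[TruthRecord] = []
    rows: list[dict] = []
    tiller_density, sampled_tillers = 300.0, 15
    for g in range(config.n_groups):
        gid = f"G{g:02d}"
        scale = float(np.exp(rng.normal(0.0, 0.08)))
        plateau = base_traj * scale
        nc_dates = a_true[g] * plateau ** (-b_true[g])
        slope = config.deficit_slope_frac * plateau / nc_dates
        truth.append(
            TruthRecord(
                group_id=gid,
                true_a=float(a_true[g]),
                true_b=float(b_true[g]),
                plateau_dw=plateau,
                slope=slope,
                cultivar=_CULTIVARS[g % len(_CULTIVARS)],
                region=_REGIONS[g % len(_REGIONS)],
                year=2015 + g % 6,
                management="ABCDE"[g % 5],
            )
        )
        for d in range(config.n_dates):
            # late-season partitioning: leaves shrink, spikes appear
            frac_leaf = 0.55 - 0.30 * d / max(1, config.n_dates - 1)
            frac_spike = max(0.0, 0.30 * (d / max(1, config.n_dates - 1) - 0.5))
            frac_stem = 1.0 - frac_leaf - frac_spike
            for rate, mult in zip(config.n_rates, mults):
                target_n = mult * nc_dates[d]
                for rep in range(1, config.n_replicates + 1):
                    n_obs = target_n + rng.normal(0.0, config.n_noise_sd)
                    n_obs = float(np.clip(n_obs, 0.05, 6.95))
                    deficit = max(0.0, nc_dates[d] - n_obs)
                    dw = plateau[d] - slope[d] * deficit
                    dw += rng.normal(0.0, config.dw_noise_sd)
                    dw = float(max(dw, 0.05))
                    # back out per-tiller raw measurements
                    w_total = dw * sampled_tillers * 1e2 / tiller_density
                    lai = 0.9 * dw
                    rows.append(
                        {
                            "experiment_id": gid,
                            "cultivar": truth[-1].cultivar,
                            "region": truth[-1].region,
                            "year": truth[-1].year,
                            "management": truth[-1].management,
                            "n_rate": rate,
                            "stage": stages[d],
                            "date": dates[d].isoformat(),
                            "replicate": rep,
                            "leaf_area_reading": lai
                            * sampled_tillers
                            * 1e4
                            / tiller_density,
                            "tiller_density": tiller_density,
                            "sampled_tillers": sampled_tillers,
                            "leaf_dw": w_total * frac_leaf,
                            "stem_dw": w_total * frac_stem,
                            "spike_dw": w_total * frac_spike,
                            "plant_n_conc": n_obs,
                        }
                    )
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    return samples, truth


def generate_features(
    truth: list[TruthRecord], config: SyntheticConfig
) -> pd.DataFrame:
    """Per-group 14-indicator table linked to the true (a, b).

    Noise terms scale with ``config.feature_noise_sd`` (0 gives exact
    links); the stream is seeded independently of the trial stream so
    the table only depends on the truth and the seed.
    """
    if not truth:
        raise ConfigError("truth must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    a = np.array([t.true_a for t in truth])
    b = np.array([t.true_b for t in truth])
    # degenerate (zero-SD) populations standardize to zero
    za = (a - config.pop_mean_a) / (config.pop_sd_a or 1.0)
    zb = (b - config.pop_mean_b) / (config.pop_sd_b or 1.0)
    n = len(truth)
    k = config.feature_noise_sd / 0.25  # noise relative to the default

    def eps(scale):
        return scale * k * rng.normal(size=n)

    feats = {
        # negative controls: independent of both parameters
        "TGW": 26.0 + 1.5 * rng.normal(size=n),
        "AC": 15.0 + 2.0 * rng.normal(size=n),
        # strong links to a (PH linear; SLA-T/DW-V monotone)
        "PH": 100.0 + 12.0 * za + eps(6.0),
        "SLA-T": 200.0 + 30.0 * np.tanh(za) + eps(8.0),
        "DW-V": 11.0 + 1.2 * za + eps(0.5),
        # strong links to b: all three convex-exponential (nonlinear) and
        # mutually correlated, as real thermal/partitioning indicators are
        "AGDD-T": 420.0 + 35.0 * np.exp(0.9 * zb) + eps(10.0),
        "SLR-T": 1.6 + 0.25 * np.exp(0.8 * zb) + eps(0.07),
        "LAI-V": 5.5 + 0.8 * np.exp(0.7 * zb) + eps(0.22),
        # weakly informative fillers
        "SLA-V": 180.0 + 5.0 * za + eps(20.0),
        "AGDD": 1600.0 + 30.0 * zb + eps(100.0),
        "AGDD-V": 1100.0 + 25.0 * zb + eps(80.0),
        "DW-T": 1.0 + 0.1 * za + eps(0.3),
        "LAI-T": 1.2 + 0.1 * za + eps(0.35),
        "SLR-V": 3.5 + 0.08 * zb + eps(0.4),
    }
    out = pd.DataFrame({"group_id": [t.group_id for t in truth]})
    for c in FEATURE_COLUMNS:
        out[c] = feats[c]
    return out


def generate_weather(
    n_days: int,
    seed: int = 0,
    start: dt.date = dt.date(2020, 6, 15),
    constant: tuple[float, float] | None = None,
) -> list[WeatherDay]:
    """Daily Tmax/Tmin series: seasonal sinusoid plus noise, tmax >= tmin.

    ``constant=(tmax, tmin)`` switches to a fixed-temperature series
    (handy for closed-form thermal-time checks).
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    days = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    for i in range(n_days):
        date = start + dt.timedelta(days=i)
        if constant is not None:
            tmax, tmin = constant
        else:
            doy = date.timetuple().tm_yday
            tmean = 22.0 + 8.0 * np.sin(2 * np.pi * (doy - 110) / 365.0)
            tmean += rng.normal(0.0, 1.5)
            half_range = max(0.5, 4.0 + rng.normal(0.0, 1.0))
            tmax, tmin = tmean + half_range, tmean - half_range
        days.append(WeatherDay(date, float(tmax), float(tmin)))
    return days


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    """Tabulate truth records (one row per group; trajectories as JSON-ish)."""
    return pd.DataFrame(
        [
            {
                "group_id": t.group_id,
                "true_a": t.true_a,
                "true_b": t.true_b,
                "cultivar": t.cultivar,
                "region": t.region,
                "year": t.year,
                "management": t.management,
                "plateau_dw": ";".join(f"{v:.6f}" for v in t.plateau_dw),
                "slope": ";".join(f"{v:.6f}" for v in t.slope),
            }
            for t in truth
        ]
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_rates"] = list(d["n_rates"])
    return d
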