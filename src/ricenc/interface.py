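"""Command-line entry points and the file contracts tying stages together.

Every stage reads/writes plain CSV (plus JSON summaries).  Output files
open with a ``#`` metadata block recording the package version, the
seed and a digest of the effective configuration, and are written
atomically (temp file + rename) so a crashed stage never leaves a
half-written table behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bhm import (
    BHMConfig,
    draws_to_frame,
    fit_specific_curves,
    pool_posteriors,
    posterior_summary,
    summary_to_dict,
)
from .dilution import DilutionCurve, curves_to_frame
from .estimation import (
    fit_and_validate,
    indicator_r2,
    reports_to_frame,
    select_predictors,
    universal_from_estimates,
)
from .indicators import (
    compute_indicator_table,
    read_samples_csv,
    read_weather_csv,
)
from .validation import validate_universal
from .sdm import nc_points_to_frame, run_sdm
from .synthetic import (
    SyntheticConfig,
    config_to_dict,
    generate_features,
    generate_trial,
    generate_weather,
    truth_to_frame,
)

logger = logging.getLogger(__name__)


def config_digest(config: dict) -> str:
    """Stable short digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: Path, seed: int, config: dict | None = None
) -> None:
    """Atomically write a CSV with a metadata comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# ricenc v{__version__}\n"
        f"# seed={seed}\n"
        f"# config_digest={config_digest(config or {})}\n"
    )
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(obj: dict, path: Path, seed: int, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "meta": {
            "version": __version__,
            "seed": seed,
            "config_digest": config_digest(config or {}),
        },
        **obj,
    }
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_config(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def main(log_level: str) -> None:
    """Critical-N dilution curves and N nutrition diagnostics for rice."""
    logging.basicConfig(
        level=getattr(logging, log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML file with SyntheticConfig fields.")
@click.option("--n-groups", type=int, default=None)
@click.option("--n-replicates", type=int, default=None)
def simulate(seed, out_dir, config_path, n_groups, n_replicates) -> None:
    """Generate a synthetic trial: samples, weather, features, truth CSVs."""
    overrides = load_config(config_path)
    if n_groups is not None:
        overrides["n_groups"] = n_groups
    if n_replicates is not None:
        overrides["n_replicates"] = n_replicates
    overrides["seed"] = seed
    if "n_rates" in overrides:
        overrides["n_rates"] = tuple(overrides["n_rates"])
    cfg = SyntheticConfig(**overrides)
    samples, truth = generate_trial(cfg)
    features = generate_features(truth, cfg)
    weather = generate_weather(120, seed=seed)
    out = Path(out_dir)
    meta = config_to_dict(cfg)
    write_table(samples, out / "samples.csv", seed, meta)
    write_table(features, out / "features.csv", seed, meta)
    write_table(truth_to_frame(truth), out / "truth.csv", seed, meta)
    write_table(
        pd.DataFrame(
            {
                "date": [d.date.isoformat() for d in weather],
                "tmax": [d.tmax for d in weather],
                "tmin": [d.tmin for d in weather],
            }
        ),
        out / "weather.csv",
        seed,
        meta,
    )
    click.echo(f"wrote samples/features/truth/weather to {out}")


@main.command("indicators")
@click.option("--samples", "samples_path", type=click.Path(exists=True),
              required=True)
@click.option("--weather", "weather_path", type=click.Path(exists=True),
              default=None)
@click.option("--out", "out_path", type=click.Path(), default="out/indicators.csv",
              show_default=True)
@click.option("--seed", type=int, default=0)
def indicators_cmd(samples_path, weather_path, out_path, seed) -> None:
    """Compute per-group growth/thermal indicators from raw records."""
    samples = read_samples_csv(samples_path)
    weather = read_weather_csv(weather_path) if weather_path else None
    table = compute_indicator_table(samples, weather)
    write_table(table, Path(out_path), seed, {"samples": str(samples_path)})
    click.echo(f"wrote {out_path}")


@main.command()
@click.option("--samples", "samples_path", type=click.Path(exists=True),
              required=True)
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--seed", type=int, default=0)
def sdm(samples_path, out_dir, alpha, seed) -> None:
    """SDM route: critical points and the mixed power curve."""
    samples = read_samples_csv(samples_path)
    curve, points, skipped = run_sdm(
        samples, alpha=alpha, with_band=True, seed=seed
    )
    out = Path(out_dir)
    cfg = {"alpha": alpha}
    write_table(nc_points_to_frame(points), out / "nc_points.csv", seed, cfg)
    write_table(curves_to_frame([curve]), out / "curve_sdm.csv", seed, cfg)
    click.echo(
        f"SDM curve: a={curve.a:.4f} b={curve.b:.4f} "
        f"({len(points)} points, {len(skipped)} dates skipped)"
    )


@main.command()
@click.option("--samples", "samples_path", type=click.Path(exists=True),
              required=True)
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--n-adapt", type=int, default=50_000, show_default=True)
@click.option("--n-sample", type=int, default=50_000, show_default=True)
@click.option("--n-chains", type=int, default=3, show_default=True)
@click.option("--thin", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0)
def bhm(samples_path, out_dir, n_adapt, n_sample, n_chains, thin, seed) -> None:
    """BHM route: per-group posteriors, pooled universal posterior."""
    samples = read_samples_csv(samples_path)
    cfg = BHMConfig(
        n_adapt=n_adapt, n_sample=n_sample, n_chains=n_chains,
        thin=thin, seed=seed,
    )
    fits = fit_specific_curves(samples, cfg)
    out = Path(out_dir)
    meta = dataclasses.asdict(cfg)
    specific_rows = []
    for gid, (draws, summary) in fits.items():
        specific_rows.append(
            {
                "group_id": gid,
                "a_median": summary.a.median,
                "b_median": summary.b.median,
                "a_ci_low": summary.a.ci95[0],
                "a_ci_high": summary.a.ci95[1],
                "b_ci_low": summary.b.ci95[0],
                "b_ci_high": summary.b.ci95[1],
                "rhat_a": draws.rhat["a"],
                "rhat_b": draws.rhat["b"],
            }
        )
    write_table(pd.DataFrame(specific_rows), out / "bhm_specific.csv", seed, meta)
    pooled = pool_posteriors({g: d for g, (d, _) in fits.items()})
    pooled_summary = posterior_summary(pooled)
    write_json(
        {"pooled": summary_to_dict(pooled_summary)},
        out / "bhm_summary.json", seed, meta,
    )
    write_table(
        pd.DataFrame(pooled), out / "bhm_pooled_draws.csv", seed, meta
    )
    curves = [
        DilutionCurve(a=pooled_summary.a.mean, b=pooled_summary.b.mean,
                      provenance="BHM-Mean"),
        DilutionCurve(a=pooled_summary.a.median, b=pooled_summary.b.median,
                      provenance="BHM-Median"),
        DilutionCurve(a=pooled_summary.a.mpn, b=pooled_summary.b.mpn,
                      provenance="BHM-MPN"),
    ]
    write_table(curves_to_frame(curves), out / "curve_bhm.csv", seed, meta)
    last = fits[list(fits)[-1]][0]
    write_table(draws_to_frame(last), out / "bhm_draws_last_group.csv", seed, meta)
    click.echo(
        "BHM pooled MPN: a=%.4f b=%.4f (%d groups)"
        % (pooled_summary.a.mpn, pooled_summary.b.mpn, len(fits))
    )


@main.command()
@click.option("--features", "features_path", type=click.Path(exists=True),
              required=True)
@click.option("--params", "params_path", type=click.Path(exists=True),
              required=True,
              help="CSV with group_id and per-group a/b values "
                   "(e.g. bhm_specific.csv medians or truth.csv).")
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--rf-ntree", type=int, default=500, show_default=True)
@click.option("--rf-mtry", default="auto", show_default=True,
              help="per-split feature count, or 'auto' to scan.")
@click.option("--seed", type=int, default=0)
def estimate(features_path, params_path, out_dir, rf_ntree, rf_mtry, seed) -> None:
    """RFA route: screen indicators, fit MLR/RF, average the estimates."""
    features = pd.read_csv(features_path, comment="#")
    params = pd.read_csv(params_path, comment="#")
    a_col = "a_median" if "a_median" in params else "true_a"
    b_col = "b_median" if "b_median" in params else "true_b"
    merged = features.merge(params, on="group_id")
    out = Path(out_dir)
    reports, curves = [], []
    for target, col in (("a", a_col), ("b", b_col)):
        y = merged[col].to_numpy(float)
        table = indicator_r2(merged, y)
        write_table(table, out / f"indicator_r2_{target}.csv", seed, {})
        preds = select_predictors(table, k=3)
        mtry = rf_mtry if rf_mtry == "auto" else int(rf_mtry)
        for method in ("MLR", "RF"):
            reports.append(
                fit_and_validate(method, merged[preds], y, target=target,
                                 rf_ntree=rf_ntree, rf_mtry=mtry, seed=seed)
            )
    write_table(reports_to_frame(reports), out / "estimation_reports.csv",
                seed, {})
    rf_a = [r for r in reports if r.method == "RF" and r.target == "a"][0]
    rf_b = [r for r in reports if r.method == "RF" and r.target == "b"][0]
    curves.append(
        universal_from_estimates(
            rf_a.loocv_predictions, rf_b.loocv_predictions, provenance="RFA"
        )
    )
    curves.append(
        universal_from_estimates(
            merged[a_col], merged[b_col], provenance="Average"
        )
    )
    write_table(curves_to_frame(curves), out / "curve_estimate.csv", seed, {})
    click.echo(
        "RFA universal: a=%.4f b=%.4f | Average: a=%.4f b=%.4f"
        % (curves[0].a, curves[0].b, curves[1].a, curves[1].b)
    )


@main.command()
@click.option("--samples", "samples_path", type=click.Path(exists=True),
              required=True)
@click.option("--curves", "curves_path", type=click.Path(exists=True),
              required=True, help="curves CSV with provenance, a, b rows.")
@click.option("--specific", "specific_path", type=click.Path(exists=True),
              required=True,
              help="CSV with group_id and per-group a/b (reference curves).")
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--seed", type=int, default=0)
def validate(samples_path, curves_path, specific_path, out_dir, seed) -> None:
    """NNI validation of universal curves against group-specific curves."""
    samples = read_samples_csv(samples_path)
    curves = pd.read_csv(curves_path, comment="#")
    params = pd.read_csv(specific_path, comment="#")
    a_col = "a_median" if "a_median" in params else "true_a"
    b_col = "b_median" if "b_median" in params else "true_b"
    specific = {
        str(r["group_id"]): DilutionCurve(a=r[a_col], b=r[b_col])
        for _, r in params.iterrows()
    }
    out = Path(out_dir)
    summary = {}
    for _, row in curves.iterrows():
        uni = DilutionCurve(a=row["a"], b=row["b"],
                            provenance=str(row["provenance"]))
        result = validate_universal(uni, specific, samples)
        write_table(result.pairs, out / f"nni_{uni.provenance}.csv", seed, {})
        summary[uni.provenance] = {
            "n": result.n_samples, "r2": result.r2, "rrmse": result.rrmse
        }
        click.echo(
            f"{uni.provenance}: R2={result.r2:.3f} RRMSE={result.rrmse:.3f}"
        )
    write_json({"validation": summary}, out / "nni_summary.json", seed, {})


@main.command()
@click.option("--out-dir", type=click.Path(exists=True), default="out",
              show_default=True)
@click.option("--seed", type=int, default=0)
def report(out_dir, seed) -> None:
    """Collate every curve CSV in the output directory into one table."""
    out = Path(out_dir)
    frames = [
        pd.read_csv(p, comment="#") for p in sorted(out.glob("curve_*.csv"))
    ]
    if not frames:
        raise click.ClickException(f"no curve_*.csv files in {out}")
    table = pd.concat(frames, ignore_index=True)
    write_table(table, out / "curves.csv", seed, {})
    click.echo(table.to_string(index=False))


if __name__ == "__main__":  # pragma: no cover
    main()
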