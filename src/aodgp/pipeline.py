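"""End-to-end orchestration: simulate, gap-fill, fit, cross-validate, map.

A run is driven by a :class:`RunConfig` (loadable from TOML/YAML).  Every
daily model is independent; per-day failures are recorded in the manifest
and the run continues, failing only if no day succeeds.  The manifest
(config hash, seeds, per-day statuses) fully determines a rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gp as gpmod
from .evaluation import (
    GPAdapter,
    GWRAdapter,
    LMEAdapter,
    aggregate_fields,
    in_sample_metrics,
    kfold_cv,
)
from .grids import GridSpec
from .interpolate import PROV_INTERPOLATED, buffer_gapfill
from .io import write_field, write_json, write_matchups
from .synth import AOD_FLOOR, TruthParams, generate_days
from .variogram import empirical_variogram, fit_variogram

logger = logging.getLogger("aodgp")

__all__ = ["RunConfig", "run_experiment", "validate_inputs", "gapfill_day"]


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    Defaults follow the daily-model schedule: 5,000 sampler iterations with
    a 3,000-iteration burn-in and 10-fold CV.  ``n_days = 0`` is allowed
    and produces an empty manifest.
    """

    grid: GridSpec = dc_field(default_factory=lambda: GridSpec(105.0, 115.0, 25.0, 35.0, 0.1))
    n_days: int = 5
    n_sites: int = 100
    start_date: str = "2013-01-01"
    truth: TruthParams = dc_field(default_factory=TruthParams)
    aod_mean: float = 0.77
    aod_sigma2: float = 0.16
    aod_phi: float = 1.0
    cloud_coverage: float = 0.3
    cloud_clump_scale: float = 0.5
    n_iter: int = 5000
    burn_in: int = 3000
    cv_k: int = 10
    seed: int = 0
    models: tuple[str, ...] = ("gp", "gwr", "lme")
    gapfill: bool = True
    predict_maps: bool = True
    predict_thin: int = 10
    outdir: str = "aodgp_run"

    def __post_init__(self) -> None:
        if not 1 <= self.burn_in <= self.n_iter:
            raise ValueError(f"burn_in must lie in [1, n_iter], got {self.burn_in}")
        if self.cv_k < 2:
            raise ValueError(f"cv_k must be >= 2, got {self.cv_k}")
        unknown = set(self.models) - {"gp", "gwr", "lme"}
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = TruthParams(**d["truth"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            import tomllib

            d = tomllib.loads(text)
        else:
            import yaml

            d = yaml.safe_load(text)
        return cls.from_dict(d or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.to_dict()
        d["models"] = list(self.models)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def gapfill_day(masked_aod: np.ndarray, grid: GridSpec, min_donors: int = 5):
    """Fit the day's AOD variogram and run the buffer-constrained fill.

    Fits a spherical variogram to the observed cells (subsampled for cost
    when dense) and uses its effective range as the buffer radius.  If the
    variogram fit fails, no filling is done that day (returns the input and
    ``None`` for the report).
    """
    obs = np.isfinite(masked_aod)
    obs_ids = np.flatnonzero(obs.ravel())
    if len(obs_ids) < 10:
        return masked_aod, None, None
    centers = grid.cell_centers()
    if len(obs_ids) > 1500:
        step = len(obs_ids) // 1500 + 1
        sub = obs_ids[::step]
    else:
        sub = obs_ids
    try:
        emp = empirical_variogram(centers[sub], masked_aod.ravel()[sub])
        vg = fit_variogram(emp, "spherical")
    except (ValueError, RuntimeError) as exc:
        logger.warning("AOD variogram fit failed, day left unfilled: %s", exc)
        return masked_aod, None, None
    filled, prov, report = buffer_gapfill(masked_aod, grid, vg, min_donors=min_donors)
    return filled, prov, report


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "days": {},
        "outputs": [],
    }
    if config.n_days == 0:
        logger.warning("config has zero days; writing empty manifest")
        write_json(manifest, outdir / "run_manifest.json")
        return manifest

    t0 = time.time()
    days = generate_days(
        config.grid, config.n_days, config.n_sites, config.truth,
        start_date=config.start_date, seed=config.seed,
        aod_mean=config.aod_mean, aod_sigma2=config.aod_sigma2,
        aod_phi=config.aod_phi, cloud_coverage=config.cloud_coverage,
        cloud_clump_scale=config.cloud_clump_scale,
    )
    data = pd.concat([d.matchups for d in days], ignore_index=True)
    write_matchups(data, outdir / "matchups.csv")
    manifest["outputs"].append("matchups.csv")
    logger.info("simulate: %d days, %d matchups (%.1fs)", len(days), len(data), time.time() - t0)

    daily_pred_fields: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(config.seed)
    day_fit_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(days))]

    for idx, day in enumerate(days):
        date = day.date
        status: dict = {}
        masked = day.masked_aod()
        if config.gapfill:
            t = time.time()
            filled, prov, report = gapfill_day(masked, config.grid)
            if report is not None:
                status["gapfill"] = {
                    "filled": report.n_filled, "left_missing": report.n_missing,
                    "observed": report.n_observed, "secs": round(time.time() - t, 2),
                }
                write_field(filled, config.grid, outdir / f"aod_filled_{date}.csv", provenance=prov)
                manifest["outputs"].append(f"aod_filled_{date}.csv")
            else:
                status["gapfill"] = "skipped (variogram fit failed or too few cells)"

        if "gp" in config.models:
            t = time.time()
            try:
                fit = gpmod.fit_day(
                    day.matchups, n_iter=config.n_iter, burn_in=config.burn_in,
                    seed=day_fit_seeds[idx],
                )
                fit.chains.to_frame().to_csv(outdir / f"chains_{date}.csv", index=False)
                manifest["outputs"].append(f"chains_{date}.csv")
                status["gp"] = {
                    "status": "fitted", "n": len(day.matchups),
                    "acceptance": {k: round(v["rate"], 3) for k, v in fit.chains.acceptance.items()},
                    "secs": round(time.time() - t, 2),
                }
                if config.predict_maps:
                    # predict only where AOD is genuinely observed (never interpolated)
                    obs_cells = np.flatnonzero(np.isfinite(masked).ravel())
                    centers = config.grid.cell_centers()[obs_cells]
                    pf = fit.predict(
                        centers, masked.ravel()[obs_cells], thin=config.predict_thin
                    )
                    fld = np.full(config.grid.n_cells, np.nan)
                    fld[obs_cells] = pf.mean
                    daily_pred_fields[date] = fld.reshape(config.grid.shape)
                    pf.cell_id = obs_cells
                    pf.to_frame().to_csv(outdir / f"pm25_pred_{date}.csv", index=False)
                    manifest["outputs"].append(f"pm25_pred_{date}.csv")
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                status["gp"] = {"status": "failed", "error": str(exc)}
                logger.warning("day %s: GP stage failed: %s", date, exc)
        manifest["days"][date] = status
        logger.info("day %s done: %s", date, json.dumps(status, default=str))

    # --- pooled CV comparison with shared folds ---
    metrics = {}
    adapters = {
        "gp": GPAdapter(n_iter=config.n_iter, burn_in=config.burn_in, seed=config.seed,
                        thin=config.predict_thin),
        "gwr": GWRAdapter(),
        "lme": LMEAdapter(),
    }
    for name in config.models:
        ad = adapters[name]
        try:
            cv = kfold_cv(ad, data, k=config.cv_k, seed=config.seed)
            fitm = in_sample_metrics(ad, data)
            metrics[name] = {**cv.to_dict(), **fitm}
            scatter = pd.DataFrame(
                {
                    "observed": data["pm25"].to_numpy(),
                    "predicted": cv.predictions,
                    "fold": cv.fold_labels,
                }
            )
            scatter.to_csv(outdir / f"cv_scatter_{name}.csv", index=False)
            manifest["outputs"].append(f"cv_scatter_{name}.csv")
        except (RuntimeError, ValueError) as exc:
            metrics[name] = {"error": str(exc)}
            logger.warning("CV failed for %s: %s", name, exc)
    write_json(metrics, outdir / "metrics.json")
    manifest["outputs"].append("metrics.json")

    if daily_pred_fields:
        seas = aggregate_fields(daily_pred_fields)
        write_field(seas.annual, config.grid, outdir / "pm25_annual_mean.csv")
        manifest["outputs"].append("pm25_annual_mean.csv")
        for s, fld in seas.seasonal.items():
            if np.any(seas.counts[s] > 0):
                write_field(fld, config.grid, outdir / f"pm25_{s}_mean.csv")
                manifest["outputs"].append(f"pm25_{s}_mean.csv")

    n_failed = sum(
        1 for st in manifest["days"].values()
        if isinstance(st.get("gp"), dict) and st["gp"].get("status") == "failed"
    )
    if "gp" in config.models and n_failed == len(days) and len(days) > 0:
        raise RuntimeError("all daily GP fits failed")
    write_json(manifest, outdir / "run_manifest.json")
    return manifest


def validate_inputs(paths: list) -> dict:
    """Schema/sanity report for monitor and AOD input files.

    Recognizes monitor tables by a ``pm25`` column and AOD field tables by
    a ``value`` column.  Reports record counts, date coverage, coordinate
    range violations and AOD values below the -0.05 retrieval floor.
    Unreadable files get a per-file error entry rather than a crash.
    """
    report: dict = {"files": {}, "n_violations": 0}
    for p in paths:
        entry: dict = {}
        try:
            df = pd.read_csv(p)
        except Exception as exc:
            report["files"][str(p)] = {"error": str(exc)}
            report["n_violations"] += 1
            continue
        entry["n_records"] = len(df)
        violations = []
        if "pm25" in df.columns:
            kind = "monitors"
            required = ["site_id", "lon", "lat", "date", "pm25"]
        else:
            kind = "aod_field"
            required = ["cell_id", "lon", "lat", "value"]
        entry["kind"] = kind
        missing = [c for c in required if c not in df.columns]
        if missing:
            violations.append(f"missing columns: {missing}")
        if not missing:
            if "date" in required:
                dates = pd.to_datetime(df["date"], errors="coerce")
                entry["date_range"] = [str(dates.min().date()), str(dates.max().date())]
                n_bad = int(dates.isna().sum())
                if n_bad:
                    violations.append(f"{n_bad} unparseable dates")
            bad_lon = int(((df["lon"] < -180) | (df["lon"] > 180)).sum())
            bad_lat = int(((df["lat"] < -90) | (df["lat"] > 90)).sum())
            if bad_lon or bad_lat:
                violations.append(f"coordinates out of range: {bad_lon} lon, {bad_lat} lat")
            aod_col = "aod" if "aod" in df.columns else ("value" if kind == "aod_field" else None)
            if aod_col is not None:
                n_floor = int((df[aod_col] < AOD_FLOOR).sum())
                if n_floor:
                    violations.append(f"{n_floor} AOD values below the {AOD_FLOOR} floor")
        entry["violations"] = violations
        report["n_violations"] += len(violations)
        report["files"][str(p)] = entry
    return report
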