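"""End-to-end desk-scale experiment: simulate, fit, evaluate, stress.

The experiment mirrors a two-season field design: a training cohort
("year 1") and a held-out test cohort ("year 2") are simulated with
different seeds and drying-rate draws, size models are fitted on year 1
only, scored on year 2, and the year-2 growth/stress analysis is run with
the best model's image-based diameters alongside the caliper record.

Every stage reads and writes plain CSV, so stages are individually
resumable, and a JSON manifest records the config snapshot, seed, package
versions and output digests for reproducibility.  Fitted sklearn
estimators are not serialized; the evaluate stage refits them
deterministically from the year-1 CSVs (same seed) before scoring.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig, rng_for
from .scene_sim import simulate_cohort
from .size_models import (
    evaluate,
    feature_subset_sweep,
    fit_ratio_curve,
    fit_regressor,
    predict,
)
from .stress_pipeline import (
    build_stress_growth_records,
    default_periods,
    growth_stress_correlation,
)

logger = logging.getLogger(__name__)

YEARS = ("year1", "year2")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _shift_year(d: dt.date, delta: int) -> dt.date:
    return d.replace(year=d.year + delta)


def cohort_config(config: SimConfig, year: str) -> SimConfig:
    """Config for one synthetic season.

    ``year2`` keeps the configured season and seed; ``year1`` shifts the
    season back one calendar year and derives an independent sub-seed, so
    the two cohorts differ in drying rates, growth and poses, emulating a
    train/test split across seasons.
    """
    if year == "year2":
        return config
    if year != "year1":
        raise ValueError(f"unknown cohort year {year!r}")
    sub_seed = int(
        np.random.SeedSequence(config.seed, spawn_key=(101,)).generate_state(1)[0]
        % (2 ** 31)
    )
    start, end = config.season
    return config.replace(
        seed=sub_seed,
        season=(_shift_year(start, -1), _shift_year(end, -1)),
        rain_events=tuple(_shift_year(d, -1) for d in config.rain_events),
    )


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_csv_dated(path: Path, date_cols: tuple[str, ...] = ("date",)) -> pd.DataFrame:
    """Read a stage CSV, restoring date columns to ``datetime.date``."""
    if not path.exists():
        raise FileNotFoundError(f"expected upstream file {path}; run the prior stage")
    frame = pd.read_csv(path)
    for col in date_cols:
        if col in frame.columns:
            frame[col] = frame[col].map(dt.date.fromisoformat)
    return frame


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: SimConfig, outdir: Path) -> dict[str, Path]:
    """Simulate both cohorts and write their CSVs under ``simulated/``."""
    outputs: dict[str, Path] = {}
    for year in YEARS:
        cohort = simulate_cohort(cohort_config(config, year))
        base = outdir / "simulated" / year
        for name, frame in cohort.items():
            path = base / f"{name}.csv"
            _write_csv(frame, path)
            outputs[f"{year}/{name}"] = path
    return outputs


def modelling_frame(observations: pd.DataFrame, caliper: pd.DataFrame,
                    tier: str) -> pd.DataFrame:
    """Join one tier's photographs to their caliper target diameters.

    The regression target is the caliper diameter of the same fruit and
    day (mean of the two replicate readings), exposed under the
    ``truth_diameter_mm`` column the fitting functions expect; the true
    geometric diameter is kept as ``geometric_diameter_mm`` for residual
    diagnostics.
    """
    obs = observations[observations["resolution_tier"] == tier].copy()
    target = (caliper.groupby(["fruit_id", "date"], sort=True)["value_mm"]
              .mean().rename("caliper_mm").reset_index())
    merged = obs.rename(columns={"truth_diameter_mm": "geometric_diameter_mm"}).merge(
        target, on=["fruit_id", "date"], how="left", validate="many_to_one"
    )
    if merged["caliper_mm"].isna().any():
        missing = merged[merged["caliper_mm"].isna()]["fruit_id"].unique()
        raise ValueError(f"no caliper target for fruits {missing[:5]}")
    return merged.rename(columns={"caliper_mm": "truth_diameter_mm"})


def _load_modelling_frames(config: SimConfig, outdir: Path):
    frames: dict[str, dict[str, pd.DataFrame]] = {}
    for year in YEARS:
        base = outdir / "simulated" / year
        obs = read_csv_dated(base / "observations.csv")
        cal = read_csv_dated(base / "caliper.csv")
        frames[year] = {tier: modelling_frame(obs, cal, tier)
                        for tier in config.resolution}
    return frames


def stage_fit(config: SimConfig, outdir: Path) -> dict[str, Path]:
    """Fit the ratio curve per tier on year 1; persist coefficients."""
    frames = _load_modelling_frames(config, outdir)
    coeffs = {}
    for tier, train in frames["year1"].items():
        model = fit_ratio_curve(train)
        a, b = model.params
        coeffs[tier] = {"a": a, "b": b, "n_train": int(len(train))}
    path = outdir / "models" / "ratio_curve.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"ratio_curve": coeffs, "seed": config.seed}, indent=2))
    return {"ratio_curve": path}


def stage_evaluate(config: SimConfig, outdir: Path) -> dict[str, Path]:
    """Score every model on the held-out year-2 cohort.

    Writes the family x subset x tier metrics table, the ratio-curve
    metrics, and per-image predictions of the configured best model (used
    downstream as the image-based diameter record).
    """
    frames = _load_modelling_frames(config, outdir)
    train_by_tier, test_by_tier = frames["year1"], frames["year2"]

    coeff_path = outdir / "models" / "ratio_curve.json"
    if not coeff_path.exists():
        raise FileNotFoundError(f"expected upstream file {coeff_path}; run fit first")

    outputs: dict[str, Path] = {}
    ratio_rows = []
    for tier, train in train_by_tier.items():
        model = fit_ratio_curve(train)
        test = test_by_tier[tier]
        rep = evaluate(predict(model, test), test["truth_diameter_mm"].to_numpy(float))
        a, b = model.params
        ratio_rows.append((tier, a, b, rep.r2, rep.mae_mm, rep.rmse_mm, rep.n,
                           rep.n_outliers))
    ratio_metrics = pd.DataFrame(
        ratio_rows, columns=["tier", "a", "b", "r2", "mae_mm", "rmse_mm", "n",
                             "n_outliers"])
    outputs["metrics_ratio_curve"] = outdir / "models" / "metrics_ratio_curve.csv"
    _write_csv(ratio_metrics, outputs["metrics_ratio_curve"])

    sweep = feature_subset_sweep(train_by_tier, test_by_tier,
                                 families=config.families, seed=config.seed)
    outputs["metrics_models"] = outdir / "models" / "metrics_models.csv"
    _write_csv(sweep, outputs["metrics_models"])

    for tier, train in train_by_tier.items():
        best = fit_regressor(config.best_family, config.best_subset, train,
                             seed=config.seed)
        test = test_by_tier[tier]
        preds = test[["image_id", "fruit_id", "tree_id", "date",
                      "geometric_diameter_mm", "truth_diameter_mm"]].copy()
        preds["predicted_mm"] = predict(best, test)
        path = outdir / "models" / f"predictions_{tier}.csv"
        _write_csv(preds, path)
        outputs[f"predictions_{tier}"] = path
    return outputs


def stage_stress(config: SimConfig, outdir: Path) -> dict[str, Path]:
    """Year-2 growth/stress analysis: records plus per-period correlations."""
    base = outdir / "simulated" / "year2"
    psi = read_csv_dated(base / "psi.csv")
    caliper = read_csv_dated(base / "caliper.csv")

    parts = [caliper.assign(method="caliper")[
        ["fruit_id", "tree_id", "date", "method", "value_mm", "replicate_index"]]]
    for tier in config.resolution:
        preds = read_csv_dated(outdir / "models" / f"predictions_{tier}.csv")
        parts.append(pd.DataFrame({
            "fruit_id": preds["fruit_id"],
            "tree_id": preds["tree_id"],
            "date": preds["date"],
            "method": f"image_{tier}",
            "value_mm": preds["predicted_mm"],
            "replicate_index": np.arange(len(preds)),
        }))
    measurements = pd.concat(parts, ignore_index=True)

    periods = default_periods(config)
    methods = ["caliper"] + [f"image_{tier}" for tier in config.resolution]
    records = build_stress_growth_records(
        psi, measurements, periods, methods=methods,
        c=config.psi_baseline_c, seed=config.seed)
    correlations = pd.concat(
        [growth_stress_correlation(records, m) for m in methods], ignore_index=True)

    outputs = {
        "stress_growth": outdir / "stress" / "stress_growth.csv",
        "stress_correlations": outdir / "stress" / "stress_correlations.csv",
    }
    _write_csv(records, outputs["stress_growth"])
    _write_csv(correlations, outputs["stress_correlations"])
    return outputs


# ---------------------------------------------------------------------------
# manifest & run_all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(config: SimConfig, outdir: Path,
                   outputs: dict[str, Path]) -> Path:
    import sklearn

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "fruitgauge": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": {name: {"path": str(path.relative_to(outdir)),
                           "sha256": _sha256(path)}
                    for name, path in sorted(outputs.items())},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_all(config: SimConfig, outdir: str | Path) -> Path:
    """Execute simulate -> fit -> evaluate -> stress and write the manifest.

    Any stage failure aborts with the stage name attached.  Reruns with
    the same config and seed produce byte-identical CSV outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    for name, stage in (("simulate", stage_simulate), ("fit", stage_fit),
                        ("evaluate", stage_evaluate), ("stress", stage_stress)):
        logger.info("running stage %s", name)
        try:
            outputs.update(stage(config, outdir))
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(name, str(exc)) from exc
    return write_manifest(config, outdir, outputs)
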