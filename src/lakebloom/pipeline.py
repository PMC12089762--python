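"""End-to-end orchestration: simulate -> detect -> metrics -> trends ->
drivers -> report.

The pipeline streams one lake at a time (scenes are never all in memory),
writes every tabular intermediate as CSV with ISO-8601 dates, and emits a
machine-readable JSON report.  Identical config + seed produces a
byte-identical report; floats are serialized at 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import detection, drivers, metrics, synthetic, trends
from .detection import DetectionParams
from .synthetic import BloomModel, SimulationConfig

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unreadable pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and offending lake."""

    def __init__(self, stage: str, lake_id: Optional[str], cause: Exception):
        self.stage = stage
        self.lake_id = lake_id
        super().__init__(
            f"stage '{stage}' failed"
            + (f" on lake {lake_id}" if lake_id else "")
            + f": {cause}"
        )


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    period_a: tuple[int, int] = trends.DEFAULT_PERIOD_A
    period_b: tuple[int, int] = trends.DEFAULT_PERIOD_B
    alpha: float = 0.05
    write_scenes: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("significance level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            sim_kwargs = dict(raw.get("simulation", {}))
            if "bloom_model" in sim_kwargs:
                bm = sim_kwargs.pop("bloom_model")
                if isinstance(bm.get("season"), list):
                    bm["season"] = tuple(bm["season"])
                sim_kwargs["bloom_model"] = BloomModel(**bm)
            det_kwargs = dict(raw.get("detection", {}))
            if "green_region" in det_kwargs:
                det_kwargs["green_region"] = tuple(
                    tuple(v) for v in det_kwargs["green_region"]
                )
            return cls(
                simulation=SimulationConfig(**sim_kwargs),
                detection=DetectionParams(**det_kwargs),
                period_a=tuple(raw.get("period_a", trends.DEFAULT_PERIOD_A)),
                period_b=tuple(raw.get("period_b", trends.DEFAULT_PERIOD_B)),
                alpha=float(raw.get("alpha", 0.05)),
                write_scenes=bool(raw.get("write_scenes", False)),
                log_level=str(raw.get("log_level", "INFO")),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def _round_sig(value, digits: int = 6):
    """Recursively round floats to 6 significant digits for stable JSON."""
    if isinstance(value, dict):
        return {k: _round_sig(v, digits) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round_sig(v, digits) for v in value]
    if isinstance(value, (np.floating, float)):
        v = float(value)
        if not math.isfinite(v):
            return None
        return float(f"{v:.{digits}g}")
    if isinstance(value, (np.integer,)):
        return int(value)
    return value


def _detect_lake(stack, truth, geometry, params):
    det = detection.detect_stack(stack.reflectance, stack.valid, geometry, params)
    a_lake = geometry.area_km2
    freq = det["bloom_area_km2"] * det["valid_area_km2"] / a_lake**2
    return pd.DataFrame(
        {
            "date": stack.dates,
            "A_Bloom": det["bloom_area_km2"],
            "A_valid": det["valid_area_km2"],
            "A_Lake": a_lake,
            "frequency": freq,
        }
    )


def _annual_metrics_for_lake(daily: pd.DataFrame, geometry, cfg: SimulationConfig):
    rows = []
    for year in range(cfg.year_start, cfg.year_end + 1):
        window = metrics.bloom_year_window(geometry, year)
        if window.end > pd.Timestamp(cfg.year_end, 12, 31).date():
            continue  # trailing shifted window extends past simulated data
        am = metrics.phenology(daily, window, lake_id=geometry.lake_id)
        rows.append(
            {
                "lake": am.lake_id,
                "bloom_year": am.bloom_year,
                "onset": am.onset,
                "persistence": am.persistence,
                "annual_frequency": am.annual_frequency,
                "n_observations": am.n_observations,
            }
        )
    return rows


def _lake_attribution(lake_id, daily, met, nutrients, annual_rows, alpha):
    """Assemble the five-factor correlation table for one lake."""
    factors: dict = {k: None for k in drivers.FACTOR_ORDER}
    try:
        factors.update(daily_met := drivers.daily_driver_correlation(daily, met))
    except ValueError:
        pass
    annual = pd.DataFrame(annual_rows)
    observed = annual[annual["n_observations"] > 0]
    # bloom-free observed years count as zero annual frequency for the
    # nutrient correlation, else sparse bloomers never reach 5 overlap years
    freq = pd.Series(
        observed["annual_frequency"].fillna(0.0).values,
        index=observed["bloom_year"].values,
    )
    nut = drivers.annual_nutrient_correlation(freq, nutrients)
    extra = {}
    if nut is not None:
        factors["fertilizer_N"] = nut["fertilizer_N"]
        factors["fertilizer_P"] = nut["fertilizer_P"]
        extra = {k: v for k, v in nut.items()
                 if k not in ("fertilizer_N", "fertilizer_P")}
    att = drivers.assign_best_factor(lake_id, factors, alpha=alpha)
    return att, extra


def run_pipeline(config: PipelineConfig, out_dir: Union[str, Path]) -> dict:
    """Run every stage on the synthetic archive and write all artifacts.

    Returns the report dict (also written to ``report.json``).  Any stage
    failure is re-raised as :class:`StageError` naming the stage and lake.
    """
    out = Path(out_dir)
    for sub in ("detections", "met", "nutrients"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    params = config.detection

    daily_by_lake: dict[str, pd.DataFrame] = {}
    met_by_lake: dict[str, pd.DataFrame] = {}
    nutrients_by_lake: dict[str, pd.DataFrame] = {}
    annual_rows: list[dict] = []
    lake_ids: list[str] = []

    for i in range(cfg.n_lakes):
        lake_id = f"lake{i:04d}"
        try:
            geometry = synthetic.generate_lake_geometry(cfg, i)
            met = synthetic.generate_met_series(cfg, i)
            nutrients = synthetic.generate_nutrient_series(cfg, i)
            stack, truth = synthetic.generate_scene_series(geometry, met, cfg, i)
        except Exception as exc:
            raise StageError("simulate", lake_id, exc) from exc
        if config.write_scenes:
            from . import scene_io

            scenes_dir = out / "scenes"
            scenes_dir.mkdir(exist_ok=True)
            scene_io.write_scene_stack(scenes_dir / f"{lake_id}.nc", stack)
        try:
            daily = _detect_lake(stack, truth, geometry, params)
        except Exception as exc:
            raise StageError("detect", lake_id, exc) from exc
        del stack, truth
        try:
            annual_rows.extend(_annual_metrics_for_lake(daily, geometry, cfg))
        except Exception as exc:
            raise StageError("metrics", lake_id, exc) from exc

        _write_daily_csv(out / "detections" / f"{lake_id}.csv", daily)
        _write_met_csv(out / "met" / f"{lake_id}.csv", met)
        nutrients.to_csv(out / "nutrients" / f"{lake_id}.csv", index=False)
        daily_by_lake[lake_id] = daily
        met_by_lake[lake_id] = met
        nutrients_by_lake[lake_id] = nutrients
        lake_ids.append(lake_id)
        logger.info("lake %s: %d bloom days", lake_id,
                    int((daily["A_Bloom"] > 0).sum()))

    annual = pd.DataFrame(
        annual_rows,
        columns=["lake", "bloom_year", "onset", "persistence",
                 "annual_frequency", "n_observations"],
    )
    annual.to_csv(out / "annual_metrics.csv", index=False)

    bloom_affected = sorted(
        lake
        for lake, df in daily_by_lake.items()
        if (df["A_Bloom"] > 0).any()
    )

    # ---- trends -----------------------------------------------------------
    try:
        eligible = trends.eligible_lakes(annual)
        trend_rows = []
        for lake in sorted(eligible):
            grp = annual[annual["lake"] == lake].dropna(
                subset=["annual_frequency"]
            )
            for metric_name in ("annual_frequency", "onset", "persistence"):
                res = trends.lake_trend(
                    grp["bloom_year"], grp[metric_name],
                    lake_id=lake,
                    metric=metric_name,
                    alpha=config.alpha,
                )
                if res is not None:
                    trend_rows.append(res.__dict__)
        trends_df = pd.DataFrame(
            trend_rows,
            columns=["lake_id", "metric", "slope", "p_value", "n_years",
                     "trend_class"],
        )
        trends_df.to_csv(out / "trends.csv", index=False)

        aff = annual[annual["lake"].isin(bloom_affected)]
        medians = trends.global_median_series(aff)
        rel_rate = None
        if len(medians.dropna()) >= 3 and medians.mean() != 0:
            rel_rate = trends.global_relative_rate(medians)
        comparison = trends.period_comparison(
            aff, config.period_a, config.period_b
        )
    except Exception as exc:
        raise StageError("trends", None, exc) from exc

    # ---- drivers ----------------------------------------------------------
    try:
        attributions = []
        extras = []
        bloom_temps: list[np.ndarray] = []
        for lake in bloom_affected:
            daily = daily_by_lake[lake]
            rows = [r for r in annual_rows if r["lake"] == lake]
            att, extra = _lake_attribution(
                lake, daily, met_by_lake[lake], nutrients_by_lake[lake],
                rows, config.alpha,
            )
            attributions.append(att)
            extras.append(extra)
            met = met_by_lake[lake]
            ev = daily[daily["A_Bloom"] > 0].merge(
                met, on="date", how="left"
            )
            bloom_temps.append(ev["air_temperature"].to_numpy())
        threshold = drivers.temperature_threshold_stats(
            np.concatenate(bloom_temps) if bloom_temps else []
        )
        _write_drivers_csv(out / "drivers.csv", attributions, extras)
    except Exception as exc:
        raise StageError("drivers", None, exc) from exc

    # ---- report -----------------------------------------------------------
    class_counts = {c: 0 for c in trends.TREND_CLASSES}
    freq_trends = trends_df[trends_df["metric"] == "annual_frequency"]
    for c, n in freq_trends["trend_class"].value_counts().items():
        class_counts[c] = int(n)
    factor_counts: dict[str, int] = {}
    for att in attributions:
        factor_counts[att.best_factor] = factor_counts.get(att.best_factor, 0) + 1

    report = {
        "config": {
            "seed": cfg.seed,
            "n_lakes": cfg.n_lakes,
            "years": [cfg.year_start, cfg.year_end],
            "grid_size": cfg.grid_size,
            "cloud_prob": cfg.cloud_prob,
            "nfai_threshold": params.nfai_threshold,
            "water_presence_min": params.water_presence_min,
            "alpha": config.alpha,
        },
        "lakes": {
            "total": cfg.n_lakes,
            "bloom_affected": len(bloom_affected),
            "eligible_for_trends": len(eligible),
        },
        "trend_classes": class_counts,
        "global": {
            "yearly_medians": {
                str(y): (None if pd.isna(v) else float(v))
                for y, v in medians.items()
            },
            "relative_rate_pct_per_yr": (
                None if rel_rate is None else rel_rate.rate_pct_per_yr
            ),
            "relative_rate_p_value": (
                None if rel_rate is None else rel_rate.p_value
            ),
            "rate_convention": "ols_slope_over_longterm_mean_x100",
        },
        "period_comparison": (
            None
            if comparison is None
            else {
                "period_a": list(config.period_a),
                "period_b": list(config.period_b),
                "median_rate_a_pct_per_yr": comparison.median_rate_a,
                "median_rate_b_pct_per_yr": comparison.median_rate_b,
                "t_statistic": comparison.t_statistic,
                "p_value": comparison.p_value,
                "n_lakes": comparison.n_lakes,
                "split_by_early_frequency": comparison.split,
            }
        ),
        "drivers": {
            "best_factor_counts": dict(sorted(factor_counts.items())),
            "best_factor_selection": "max_abs_r_with_p_lt_alpha",
            "correlation": "pearson",
            "temperature_gt_20c_fraction": (
                None if threshold is None else threshold.frac_above_upper
            ),
            "temperature_le_16c_fraction": (
                None if threshold is None else threshold.frac_at_or_below_lower
            ),
            "n_bloom_events": 0 if threshold is None else threshold.n_events,
        },
    }
    report = _round_sig(report)
    (out / "report.json").write_bytes(
        json.dumps(report, indent=2, sort_keys=True).encode() + b"\n"
    )
    return report


def _write_daily_csv(path: Path, daily: pd.DataFrame) -> None:
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6g")


def _write_met_csv(path: Path, met: pd.DataFrame) -> None:
    df = met.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.6g")


def _write_drivers_csv(path: Path, attributions, extras) -> None:
    rows = []
    for att, extra in zip(attributions, extras):
        row: dict = {"lake": att.lake_id, "best_factor": att.best_factor}
        for name in drivers.FACTOR_ORDER:
            rp = att.factors.get(name)
            row[f"{name}_r"] = None if rp is None else rp[0]
            row[f"{name}_p"] = None if rp is None else rp[1]
        for name, rp in extra.items():
            row[f"{name}_r"] = None if rp is None else rp[0]
            row[f"{name}_p"] = None if rp is None else rp[1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
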