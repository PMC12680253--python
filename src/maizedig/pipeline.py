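"""End-to-end pipeline: weather → SID + category, trial → derived traits,
condition-mean tables with Tukey letters, and per-environment stepwise
decompositions with biochemistry/histology shares.

All interchange is CSV; a run is fully determined by its config and
inputs, and every model decision (interaction kept or dropped,
variables entered) is logged at info level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io, stats, traits, weather

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "table1_report"]

log = logging.getLogger("maizedig.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    weather_files: dict[str, str] = field(default_factory=dict)  # env -> csv path
    eawr: dict[str, float] = field(default_factory=dict)  # env -> mm
    init_deficit: float = 0.0
    trial_file: str | None = None
    segmentation_file: str | None = None
    report_traits: list[str] = field(default_factory=list)  # empty = all numeric traits
    response: str = "cw_digestibility"
    candidates: list[str] = field(default_factory=list)
    category_map: dict[str, str] = field(default_factory=dict)
    sid_params: weather.SIDParams = field(default_factory=weather.SIDParams)
    thresholds: weather.ClassificationThresholds = field(
        default_factory=weather.ClassificationThresholds
    )
    delta_r2: float = 4.0
    rmse_eps: float = 0.01
    alpha: float = 0.05
    out_dir: str = "reports"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in (
            "weather_files", "eawr", "init_deficit", "trial_file",
            "segmentation_file", "report_traits", "response", "candidates",
            "category_map", "delta_r2", "rmse_eps", "alpha", "out_dir",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "sid_params" in raw:
            cfg.sid_params = weather.SIDParams(**raw["sid_params"])
        if "thresholds" in raw:
            cfg.thresholds = weather.ClassificationThresholds(**raw["thresholds"])
        return cfg

    def validate(self) -> None:
        for env, p in self.weather_files.items():
            if not Path(p).exists():
                raise StageError("config", f"weather file for {env!r} not found: {p}")
            if env not in self.eawr:
                raise StageError("config", f"no eawr configured for environment {env!r}")
        for name in ("trial_file", "segmentation_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise StageError("config", f"{name} not found: {p}")


def table1_report(
    wide: pd.DataFrame, traits_list: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Condition-mean table with compact Tukey letters, one row per
    trait × condition.  With a single condition only means are reported."""
    rows = []
    n_cond = wide["condition"].nunique()
    for trait in traits_list:
        if trait not in wide.columns:
            raise StageError("table1", f"trait {trait!r} absent from trial table")
        means = wide.groupby("condition")[trait].mean()
        letters = {}
        if n_cond >= 2:
            cld = stats.tukey_cld(wide, trait, by="condition", alpha=alpha)
            letters = cld.letters
        for cond, mean in means.items():
            rows.append(
                {
                    "trait": trait,
                    "condition": cond,
                    "mean": float(mean),
                    "letters": letters.get(str(cond), ""),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage; returns and writes the report tables.

    Outputs (written under ``config.out_dir``): ``sid_environments.csv``,
    ``halfmonth_means.csv``, ``table1.csv``, ``decomposition.csv`` and
    ``shares.csv``.  Identical config + inputs give identical bytes.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, pd.DataFrame] = {}

    if config.weather_files:
        rows, hm_rows = [], []
        for env in sorted(config.weather_files):
            try:
                wdf = io.read_weather_csv(config.weather_files[env])
                series = weather.sid_series(
                    wdf,
                    eawr=config.eawr[env],
                    init_deficit=config.init_deficit,
                    params=config.sid_params,
                    env=env,
                )
                hm = weather.halfmonth_means(series)
                cat = weather.classify_environment(hm, config.thresholds)
                summ = weather.env_summary(wdf, config.sid_params.ptot, config.sid_params)
                rows.append(
                    {
                        "environment": env,
                        "pflo_sum": weather.period_sum(series, config.sid_params.pflo),
                        "ptot_sum": weather.period_sum(series, config.sid_params.ptot),
                        "pflo_mean": cat.pflo_mean,
                        "category": cat.label,
                        "twi_mm": summ.twi,
                        "twi_minus_etpp_mm": summ.twi_minus_etpp,
                        "mean_temp_c": summ.mean_temp,
                        "hsd_hours": summ.hsd,
                    }
                )
                hm = hm.assign(environment=env)
                hm_rows.append(hm)
                log.info("sid: %s classified %s (Pflo mean %.1f)", env, cat.label, cat.pflo_mean)
            except StageError:
                raise
            except Exception as exc:
                raise StageError("sid", f"environment {env!r}: {exc}") from exc
        reports["sid_environments"] = pd.DataFrame(rows)
        reports["halfmonth_means"] = pd.concat(hm_rows, ignore_index=True)

    wide = None
    if config.trial_file:
        try:
            long = io.read_trial_csv(config.trial_file)
            wide = traits.long_to_wide(long)
            wide = traits.derive_trial_traits(wide)
        except Exception as exc:
            raise StageError("trial", str(exc)) from exc

    if config.segmentation_file:
        try:
            seg = io.read_segmentation_csv(config.segmentation_file)
            reports["segmentation_traits"] = traits.segmentation_traits(seg)
        except Exception as exc:
            raise StageError("segmentation", str(exc)) from exc

    if wide is not None:
        try:
            tlist = config.report_traits or [
                c
                for c in wide.columns
                if c not in traits.DESIGN_COLS and pd.api.types.is_numeric_dtype(wide[c])
            ]
            reports["table1"] = table1_report(wide, tlist, alpha=config.alpha)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("table1", str(exc)) from exc

        if config.candidates:
            try:
                dec_rows, share_rows = [], []
                for env, sub in wide.groupby("condition"):
                    model = stats.stepwise_decompose(
                        sub,
                        response=config.response,
                        candidates=config.candidates,
                        category_map=config.category_map or None,
                        delta_r2=config.delta_r2,
                        rmse_eps=config.rmse_eps,
                    )
                    log.info(
                        "decompose: %s entered %s (R²=%.1f)",
                        env,
                        model.variables,
                        model.r_squared,
                    )
                    frame = model.summary_frame(config.category_map)
                    frame.insert(0, "environment", env)
                    dec_rows.append(frame)
                    for cat_name, share in sorted(model.category_shares.items()):
                        share_rows.append(
                            {
                                "environment": env,
                                "category": cat_name,
                                "share_r2": share,
                                "model_r2": model.r_squared,
                            }
                        )
                reports["decomposition"] = (
                    pd.concat(dec_rows, ignore_index=True) if dec_rows else pd.DataFrame()
                )
                reports["shares"] = pd.DataFrame(share_rows)
            except Exception as exc:
                raise StageError("decompose", str(exc)) from exc

    for name, frame in reports.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    return reports
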