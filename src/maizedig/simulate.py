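"""Synthetic weather, trial-trait and segmentation data.

Every stage of the analysis is exercisable without field data:

* ``gen_weather`` — one growing season of daily weather with a
  scenario-specific irrigation rule.  Rain is a marked Poisson process,
  temperature a sinusoidal seasonal mean with AR(1) noise plus
  scenario heatwaves, reference evapotranspiration a seasonal curve.
  Deficit-triggered scenarios emulate tensiometer-scheduled irrigation
  by firing a fixed dose when the simulated bucket deficit crosses a
  fraction of the reserve; triggered doses keep a 3-day minimum
  spacing, matching the calendar cadence of the well-watered regime —
  under a severe scenario the 13 mm dose then cannot keep up with
  Mediterranean summer evapotranspiration, so the deficit outruns the
  reserve exactly as a severe field season does.
* ``gen_trial`` — block-level trial tables with planted hybrid,
  condition, interaction and row/column gradient effects, where
  cell-wall digestibility is a planted linear combination of
  biochemical and histological predictors with condition-specific
  weights (so the moderate-stress "histology peaks" pattern can be
  planted and recovered).
* ``gen_segmentation`` — Dirichlet-multinomial zone pixel counts that
  partition a cross-section.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .traits import ZONES

__all__ = [
    "WeatherScenario",
    "SCENARIOS",
    "TrialDesign",
    "DEFAULT_CW_WEIGHTS",
    "DEFAULT_CATEGORY_MAP",
    "DEFAULT_ZONE_PROFILE",
    "gen_weather",
    "gen_trial",
    "gen_segmentation",
]


@dataclass(frozen=True)
class WeatherScenario:
    """One growing-season climate + irrigation regime."""

    name: str
    rain_rate: float  # rain events per day
    rain_mean_mm: float  # mean event depth (exponential marks)
    tmean_peak: float  # seasonal mean temperature at the mid-July peak, °C
    tmean_spring: float  # seasonal mean temperature at sowing, °C
    diurnal_range: float = 12.0  # tmax - tmin, °C
    temp_ar_sigma: float = 1.6  # AR(1) innovation SD, °C
    temp_ar_rho: float = 0.6
    heatwaves: int = 0  # number of July/August heatwave episodes
    heatwave_days: int = 5
    heatwave_boost: float = 5.0  # added to the seasonal mean during a wave, °C
    etp_peak: float = 6.0  # mm/day at the seasonal peak
    etp_base: float = 2.0  # mm/day shoulder value
    irrigation: tuple | None = None  # ("calendar", interval_days, dose_mm)
    #                               or ("deficit", fraction_of_eawr, dose_mm)
    eawr: float = 100.0  # easily accessible water reserve, mm
    stress_onset_days: int = 25  # days post-sowing before the deficit rule applies
    min_irrigation_spacing: int = 3  # days between triggered doses


# Scenario defaults: an oceanic rainfed site (wet, mild) and a
# Mediterranean site (sparse summer rain, ETP 6.5-8 mm/day at peak)
# under three irrigation regimes — 20 mm every 3 days (well-watered),
# 15 mm on 60 % reserve depletion (moderate deficit, the -125 kPa
# stand-in) and 13 mm on 85 % depletion (severe deficit, -300 kPa).
SCENARIOS: dict[str, WeatherScenario] = {
    "rainfed_humid": WeatherScenario(
        name="rainfed_humid",
        rain_rate=0.50,
        rain_mean_mm=10.0,
        tmean_peak=20.0,
        tmean_spring=11.0,
        etp_peak=3.8,
        etp_base=1.5,
        irrigation=None,
    ),
    "well_watered": WeatherScenario(
        name="well_watered",
        rain_rate=0.12,
        rain_mean_mm=5.0,
        tmean_peak=25.0,
        tmean_spring=14.0,
        etp_peak=6.5,
        etp_base=2.5,
        irrigation=("calendar", 3, 20.0),
    ),
    "moderate_deficit": WeatherScenario(
        name="moderate_deficit",
        rain_rate=0.05,
        rain_mean_mm=4.0,
        tmean_peak=26.0,
        tmean_spring=14.0,
        heatwaves=1,
        etp_peak=7.8,
        etp_base=2.5,
        irrigation=("deficit", 0.6, 15.0),
    ),
    "severe_deficit": WeatherScenario(
        name="severe_deficit",
        rain_rate=0.03,
        rain_mean_mm=4.0,
        tmean_peak=28.0,
        tmean_spring=15.0,
        heatwaves=2,
        heatwave_boost=6.0,
        etp_peak=8.2,
        etp_base=2.5,
        irrigation=("deficit", 0.85, 13.0),
    ),
}


def _season_curve(doy: np.ndarray, low: float, high: float) -> np.ndarray:
    # sinusoid peaking on July 15 (doy 196), trough six months away
    return (high + low) / 2.0 - (high - low) / 2.0 * np.cos(
        2.0 * np.pi * (doy - 15.0) / 365.0
    )


def gen_weather(
    scenario: WeatherScenario | str,
    year: int = 2022,
    seed: int = 0,
    sowing: tuple[int, int] = (4, 25),
    end: tuple[int, int] = (8, 31),
) -> pd.DataFrame:
    """One season of daily weather for *scenario* (sowing → end of August).

    Deterministic given *seed*.  Columns match the weather CSV schema:
    date, tmin, tmax, rainfall, irrigation, etp, humidity, par.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    start = date(year, *sowing)
    stop = date(year, *end)
    n = (stop - start).days + 1
    dates = [start + timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    tmean_seasonal = _season_curve(doy, scenario.tmean_spring, scenario.tmean_peak)
    ar = np.zeros(n)
    for i in range(1, n):
        ar[i] = scenario.temp_ar_rho * ar[i - 1] + rng.normal(0.0, scenario.temp_ar_sigma)
    boost = np.zeros(n)
    july1 = (date(year, 7, 1) - start).days
    for _ in range(scenario.heatwaves):
        w0 = int(rng.integers(july1 - 10, min(n - scenario.heatwave_days, july1 + 40)))
        boost[w0 : w0 + scenario.heatwave_days] += scenario.heatwave_boost
    tmean = tmean_seasonal + ar + boost
    tmax = tmean + scenario.diurnal_range / 2.0
    tmin = tmean - scenario.diurnal_range / 2.0

    events = rng.random(n) < scenario.rain_rate
    rain = np.where(events, rng.exponential(scenario.rain_mean_mm, n), 0.0)

    etp = _season_curve(doy, scenario.etp_base, scenario.etp_peak)
    etp = np.clip(etp + rng.normal(0.0, 0.3, n) - 0.04 * rain, 0.05, None)

    humidity = np.clip(85.0 - 1.8 * (tmean - 12.0) + rng.normal(0.0, 4.0, n), 20, 100)
    par = np.clip(80.0 + 6.0 * (tmean - 10.0) + rng.normal(0.0, 15.0, n), 10, None)

    irrigation = np.zeros(n)
    rule = scenario.irrigation
    deficit = 0.0
    last_dose = -scenario.min_irrigation_spacing
    onset = scenario.stress_onset_days
    for i in range(n):
        dose = 0.0
        if rule is not None:
            kind = rule[0]
            if kind == "calendar":
                # calendar watering runs all season; the 25-day onset
                # delay applies only to the deficit (stress) modalities
                _, interval, amount = rule
                if i % interval == 0:
                    dose = amount
            elif kind == "deficit":
                _, frac, amount = rule
                if i < onset:
                    # pre-stress establishment watering, well-watered cadence
                    if i % 3 == 0:
                        dose = 20.0
                elif (
                    deficit >= frac * scenario.eawr
                    and i - last_dose >= scenario.min_irrigation_spacing
                ):
                    dose = amount
                    last_dose = i
            else:
                raise ValueError(f"unknown irrigation rule {kind!r}")
        irrigation[i] = dose
        deficit = max(0.0, deficit + etp[i] - rain[i] - dose)

    return pd.DataFrame(
        {
            "date": dates,
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
            "rainfall": np.round(rain, 2),
            "irrigation": irrigation,
            "etp": np.round(etp, 2),
            "humidity": np.round(humidity, 1),
            "par": np.round(par, 1),
        }
    )


# ------------------------------------------------------------------ trial


#: Planted per-condition weights (R² points) linking cell-wall
#: digestibility to its predictors: biochemistry dominates in humid and
#: severe conditions, histology peaks under moderate stress.
DEFAULT_CW_WEIGHTS: dict[str, dict[str, float]] = {
    "humid": {"pcest": 67.0, "bo4_yield": 22.0, "highly_digestible": 5.0},
    "well_watered": {"pcest": 58.0, "bo4_yield": 31.0, "highly_digestible": 7.0},
    "moderate": {"highly_digestible": 50.0, "pcest": 20.0, "feest": 12.0},
    "severe": {"bo4_yield": 59.0, "pcest": 23.0, "feest": 8.0, "highly_digestible": 5.0},
}

DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "pcest": "biochemistry",
    "feest": "biochemistry",
    "feeth": "biochemistry",
    "lignin": "biochemistry",
    "bo4_yield": "biochemistry",
    "highly_digestible": "histology",
    "digestible": "histology",
    "blue_pith": "histology",
    "rind_total": "histology",
    "drt_total": "histology",
    "lrt_total": "histology",
}

#: Condition means for the auxiliary traits (loose field magnitudes).
_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "yield": {"humid": 17.0, "well_watered": 17.5, "moderate": 12.5, "severe": 6.5},
    "dm_digestibility": {"humid": 68.0, "well_watered": 69.5, "moderate": 73.0, "severe": 67.5},
    "lignin": {"humid": 15.7, "well_watered": 15.9, "moderate": 14.9, "severe": 14.2},
    "pcest": {"humid": 15.0, "well_watered": 15.5, "moderate": 12.5, "severe": 9.7},
    "feest": {"humid": 8.0, "well_watered": 7.3, "moderate": 7.8, "severe": 5.8},
    "bo4_yield": {"humid": 1050.0, "well_watered": 1080.0, "moderate": 1010.0, "severe": 1000.0},
    "highly_digestible": {"humid": 18.0, "well_watered": 17.0, "moderate": 24.0, "severe": 28.0},
    "rind_total": {"humid": 22.0, "well_watered": 22.5, "moderate": 24.0, "severe": 26.0},
    "cw_digestibility": {"humid": 33.8, "well_watered": 32.6, "moderate": 36.5, "severe": 36.0},
}

_TRAIT_SCALE: dict[str, float] = {
    "yield": 1.6,
    "dm_digestibility": 1.8,
    "lignin": 0.5,
    "pcest": 1.3,
    "feest": 0.8,
    "bo4_yield": 60.0,
    "highly_digestible": 3.0,
    "rind_total": 2.0,
    "cw_digestibility": 2.0,
}


@dataclass(frozen=True)
class TrialDesign:
    """Effect structure of a generated multi-environment trial."""

    hybrids: int = 11
    conditions: tuple[str, ...] = ("humid", "well_watered", "moderate", "severe")
    blocks: int = 3
    hybrid_sd: float = 0.6  # hybrid main effect, units of trait scale
    interaction_sd: float = 0.25
    col_slope: float = 0.1  # linear field gradients, trait-scale units per index
    row_slope: float = 0.05
    residual_sd: float = 0.55
    cw_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CW_WEIGHTS.items()}
    )
    year: int = 2022
    site: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hybrid_sd", "interaction_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cond, weights in self.cw_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative weight in condition {cond!r}")
            if sum(weights.values()) > 100.0 + 1e-9:
                raise ValueError(f"weights for {cond!r} exceed 100 R² points")


def gen_trial(design: TrialDesign = TrialDesign()) -> pd.DataFrame:
    """Generate a tidy (long) block-level trial table.

    Every trait follows Y = µ + hybrid + condition + interaction +
    column gradient + row gradient + noise on its own scale.  Cell-wall
    digestibility is instead built as the planted linear combination of
    the standardized predictor deviations with the condition-specific
    weights in ``design.cw_weights`` (weights are R² points: a weight w
    contributes sqrt(w/100) of the response scale), plus matching
    residual noise — so stepwise decomposition should recover each
    condition's planted category shares.
    """
    rng = np.random.default_rng(design.seed)
    hybrids = [chr(ord("A") + i) if i < 26 else f"H{i}" for i in range(design.hybrids)]
    conditions = list(design.conditions)
    predictor_traits = [t for t in _TRAIT_MEANS if t != "cw_digestibility"]

    # latent standardized deviations per trait: hybrid + interaction + residual
    h_eff = {
        t: rng.normal(0.0, design.hybrid_sd, design.hybrids) for t in predictor_traits
    }
    hc_eff = {
        t: rng.normal(0.0, design.interaction_sd, (design.hybrids, len(conditions)))
        for t in predictor_traits
    }
    lat_sd = np.sqrt(
        design.hybrid_sd**2 + design.interaction_sd**2 + design.residual_sd**2
    )
    if lat_sd == 0:
        lat_sd = 1.0  # all-zero effects: z stays 0, traits sit at their means

    records = []
    for ci, cond in enumerate(conditions):
        weights = design.cw_weights.get(cond, {})
        cw_mu = _TRAIT_MEANS["cw_digestibility"].get(cond, 35.0)
        cw_scale = _TRAIT_SCALE["cw_digestibility"]
        resid_share = max(0.0, 1.0 - sum(weights.values()) / 100.0)
        for b in range(1, design.blocks + 1):
            for hi, hyb in enumerate(hybrids):
                row_i, col_i = hi + 1, (ci * design.blocks) + b
                z = {}
                for t in predictor_traits:
                    z[t] = (
                        h_eff[t][hi]
                        + hc_eff[t][hi][ci]
                        + rng.normal(0.0, design.residual_sd)
                    ) / lat_sd
                gradient = design.col_slope * col_i + design.row_slope * row_i
                rec = {
                    "year": design.year,
                    "site": design.site,
                    "condition": cond,
                    "hybrid": hyb,
                    "block": b,
                    "row": row_i,
                    "col": col_i,
                }
                for t in predictor_traits:
                    mu = _TRAIT_MEANS[t].get(cond, np.mean(list(_TRAIT_MEANS[t].values())))
                    rec[t] = mu + _TRAIT_SCALE[t] * (z[t] + gradient)
                cw = cw_mu + cw_scale * gradient
                for t, w in weights.items():
                    cw += np.sqrt(w / 100.0) * cw_scale * z[t]
                if design.residual_sd > 0:
                    cw += rng.normal(0.0, np.sqrt(resid_share) * cw_scale)
                rec["cw_digestibility"] = cw
                # keep percentages physical
                for t in ("dm_digestibility", "cw_digestibility", "highly_digestible", "rind_total"):
                    rec[t] = float(np.clip(rec[t], 0.0, 100.0))
                rec["yield"] = float(max(rec["yield"], 0.0))
                records.append(rec)
    wide = pd.DataFrame(records)
    id_cols = ["year", "site", "condition", "hybrid", "block", "row", "col"]
    long = wide.melt(id_vars=id_cols, var_name="trait", value_name="value")
    return long.sort_values(id_cols + ["trait"]).reset_index(drop=True)


# ------------------------------------------------------------ segmentation

#: Expected %ICS per zone, summing to 100: a large low-lignified pith,
#: a rind split between dark and light tissues, small bundle and
#: epidermis fractions.
DEFAULT_ZONE_PROFILE: dict[str, float] = {
    # medullary / pith (58 %)
    "MT1a": 4.0, "MT1b": 3.0, "MT2": 9.0, "MT2a": 8.0, "MT2b": 10.0,
    "MT4a": 3.5, "MT4b": 2.5, "MT5": 6.0, "MT5a": 5.0, "MT5b": 7.0,
    # dark rind (12 %)
    "DRT1": 1.5, "DRT2": 2.5, "DRT3": 1.0, "DRT4": 2.0, "DRT5": 1.5,
    "DRT6": 0.8, "DRT7": 1.2, "DRT8": 0.8, "DRT9": 0.7,
    # light rind (12 %)
    "LRT1": 1.8, "LRT2": 2.2, "LRT3": 1.2, "LRT4": 1.8, "LRT5": 1.4,
    "LRT6": 1.0, "LRT7": 1.1, "LRT8": 0.8, "LRT9": 0.7,
    # bundles (10 %)
    "BT1": 2.5, "BT2": 2.0, "BT3": 2.0, "BT4": 1.8, "BT5": 1.7,
    # epidermis (8 %)
    "ET1": 1.2, "ET2": 1.0, "ET3": 0.9, "ET4": 0.8, "ET5": 0.8,
    "ET6": 0.7, "ET7": 0.7, "ET8": 0.6, "ET9": 0.5, "ET10": 0.4, "ET11": 0.4,
}


def gen_segmentation(
    n_samples: int,
    profile: dict[str, float] | None = None,
    seed: int = 0,
    total_px: int = 1_000_000,
    concentration: float = 400.0,
) -> pd.DataFrame:
    """Dirichlet-multinomial zone pixel counts for *n_samples* sections.

    *profile* gives the expected %ICS per zone and must sum to 100;
    *concentration* controls between-sample variability (→ ∞ gives the
    profile exactly).  Counts in each row sum to *total_px*.
    """
    profile = dict(DEFAULT_ZONE_PROFILE if profile is None else profile)
    if abs(sum(profile.values()) - 100.0) > 1e-6:
        raise ValueError("zone profile must sum to 100 %ICS")
    zones = [z for z in ZONES if z in profile] + [z for z in profile if z not in ZONES]
    p = np.array([profile[z] for z in zones]) / 100.0
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_samples):
        probs = rng.dirichlet(np.maximum(concentration * p, 1e-9))
        counts = rng.multinomial(total_px, probs)
        rec = {"sample": f"S{s + 1:03d}"}
        rec.update({z: int(c) for z, c in zip(zones, counts)})
        rec["total_px"] = int(counts.sum())
        rows.append(rec)
    return pd.DataFrame(rows)
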