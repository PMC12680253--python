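"""Daily water/heat stress index (SID) from weather series and a soil water balance.

The index scores each day of a maize growing season by adding

* a water term — the percentage of the soil's easily accessible water
  reserve (EAWR) currently depleted, ``deficit / eawr * 100``.  Values
  above 100 % mean the easily accessible reserve is exhausted and the
  crop is in the water-stress regime; the term is deliberately uncapped.
* a heat term — a small bonus driven by the number of hours spent above
  a heat-stress threshold (30 °C for maize) and by how far the daily
  maximum temperature exceeds that threshold:
  ``((h + 1) * (tmax / threshold)) / 2400 + 1``.

Daily values are summed over two agronomic windows (Pflo, the flowering
fortnight Jul 1–15, and Ptot, the May 16–Aug 15 culture window) and
averaged per half-month to rank and classify environments as humid,
moderate-to-severe or severe.

The soil water deficit is either advanced by a transparent bucket model
(``update_water_balance``) or supplied externally as a ``deficit``
column — the index is agnostic to the deficit's source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "SoilWaterState",
    "SIDParams",
    "ClassificationThresholds",
    "SIDSeries",
    "EnvSummary",
    "StressCategory",
    "PFLO",
    "PTOT",
    "resolve_window",
    "update_water_balance",
    "water_balance_series",
    "heat_hours",
    "heat_term",
    "daily_sid",
    "sid_series",
    "period_sum",
    "halfmonth_means",
    "env_summary",
    "classify_environment",
]

#: Aggregation windows as ((start month, start day), (end month, end day)),
#: closed on both ends.
PFLO = ((7, 1), (7, 15))
PTOT = ((5, 16), (8, 15))

WEATHER_COLUMNS = ("date", "rainfall", "irrigation", "etp")


def resolve_window(window, year: int) -> tuple[date, date]:
    """Turn a ((m, d), (m, d)) window into concrete dates for *year*."""
    (m0, d0), (m1, d1) = window
    start, end = date(year, m0, d0), date(year, m1, d1)
    if end < start:
        raise ValueError(f"window end {end} before start {start}")
    return start, end


@dataclass(frozen=True)
class SoilWaterState:
    """Bucket-model state: fixed reserve size and current depletion."""

    eawr: float  # easily accessible water reserve, mm (> 0)
    deficit: float = 0.0  # current soil water deficit, mm (>= 0)

    def __post_init__(self) -> None:
        if self.eawr <= 0:
            raise ValueError("eawr must be > 0")
        if self.deficit < 0:
            raise ValueError("deficit must be >= 0")


@dataclass(frozen=True)
class SIDParams:
    """Constants of the daily index and its aggregation windows."""

    heat_threshold: float = 30.0  # °C
    heat_scale: float = 2400.0  # unitless divisor of the heat term
    pflo: tuple = PFLO
    ptot: tuple = PTOT

    def __post_init__(self) -> None:
        if self.heat_threshold <= 0:
            raise ValueError("heat_threshold must be > 0")
        if self.heat_scale <= 0:
            raise ValueError("heat_scale must be > 0")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Configurable cutoffs of the stress-category rule.

    humid_ceiling: an environment is humid if no semi-monthly mean SID
        exceeds this (default 100, the full-reserve-utilisation mark).
    severe_pflo_mean: mean SID over the flowering fortnight above which
        the environment is severe (default 180).
    """

    humid_ceiling: float = 100.0
    severe_pflo_mean: float = 180.0


@dataclass
class SIDSeries:
    """Per-day index values for one environment."""

    env: str
    frame: pd.DataFrame  # columns: date, deficit, water_term, heat_term, sid

    def __post_init__(self) -> None:
        missing = {"date", "water_term", "heat_term", "sid"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"SIDSeries frame missing columns {sorted(missing)}")


@dataclass(frozen=True)
class EnvSummary:
    """Auxiliary environmental traits over one window (None when inputs absent)."""

    twi: float  # total water input = rain + irrigation, mm
    twi_minus_etpp: float  # signed; callers invert when needed
    mean_temp: float  # °C
    mean_humidity: float | None
    par_sum: float | None  # J/cm²
    hsd: float  # heat stress duration, hours above threshold


@dataclass(frozen=True)
class StressCategory:
    label: str  # humid | moderate_to_severe | severe
    pflo_mean: float
    max_halfmonth_mean: float


def _validate_day(rainfall: float, irrigation: float, etp: float) -> None:
    for name, v in (("rainfall", rainfall), ("irrigation", irrigation), ("etp", etp)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be finite and >= 0, got {v}")


def update_water_balance(state: SoilWaterState, day) -> SoilWaterState:
    """Advance the bucket model one day.

    ``deficit' = max(0, deficit + etp − rainfall − irrigation)``; the
    reserve size is a site constant.  *day* is any mapping (or pandas
    row) with ``rainfall``, ``irrigation`` and ``etp`` in mm.
    """
    rain, irr, etp = day["rainfall"], day["irrigation"], day["etp"]
    _validate_day(rain, irr, etp)
    new_deficit = max(0.0, state.deficit + etp - rain - irr)
    return replace(state, deficit=new_deficit)


def water_balance_series(
    weather: pd.DataFrame, eawr: float, init_deficit: float = 0.0
) -> np.ndarray:
    """Deficit after each day of *weather*, vectorised bucket model.

    Equivalent to folding :func:`update_water_balance` over the rows;
    the max-clamp at zero makes this a clipped running sum.
    """
    state = SoilWaterState(eawr=eawr, deficit=init_deficit)
    out = np.empty(len(weather), dtype=float)
    for i, (_, row) in enumerate(weather.iterrows()):
        state = update_water_balance(state, row)
        out[i] = state.deficit
    return out


def _diurnal_curve(tmin: float, tmax: float, hours: np.ndarray) -> np.ndarray:
    # cosine between the daily extremes: minimum at midnight, maximum at noon
    mid = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    return mid - amp * np.cos(2.0 * np.pi * hours / 24.0)


def heat_hours(day, threshold: float = 30.0) -> float:
    """Hours of the day spent above *threshold* °C.

    Counts hourly observations when ``hourly_temp`` (24 values) is
    available; otherwise estimates from a cosine diurnal interpolation
    between ``tmin`` and ``tmax`` sampled at each hour — a standard
    agro-meteorological stand-in when only daily extremes are recorded.
    """
    hourly = day.get("hourly_temp") if hasattr(day, "get") else getattr(day, "hourly_temp", None)
    if hourly is not None and not (np.isscalar(hourly) and pd.isna(hourly)):
        hourly = np.asarray(hourly, dtype=float)
        if hourly.shape != (24,):
            raise ValueError("hourly_temp must hold 24 values")
        return float(np.sum(hourly > threshold))
    tmin, tmax = day.get("tmin"), day.get("tmax")
    if tmin is None or tmax is None or pd.isna(tmin) or pd.isna(tmax):
        raise ValueError("heat_hours needs hourly_temp or both tmin and tmax")
    if tmax < tmin:
        raise ValueError("tmax below tmin")
    temps = _diurnal_curve(float(tmin), float(tmax), np.arange(24) + 0.5)
    return float(np.sum(temps > threshold))


def heat_term(
    hours_above: float, tmax: float, threshold: float = 30.0, scale: float = 2400.0
) -> float:
    """Heat component of the daily index.

    ``((h + 1) * (tmax / threshold)) / scale + 1`` — the most literal
    reading of the published grouping, isolated here so an alternative
    reading is a one-line change.  A sub-threshold tmax still
    contributes ``tmax/threshold < 1``; negative tmax is floored at 0
    so the term never drops below 1.
    """
    if not 0 <= hours_above <= 24:
        raise ValueError("hours_above must be in [0, 24]")
    tmax_eff = max(float(tmax), 0.0)
    return ((hours_above + 1.0) * (tmax_eff / threshold)) / scale + 1.0


def daily_sid(state: SoilWaterState, day, params: SIDParams = SIDParams()) -> float:
    """One day's index: water term plus heat term."""
    water = state.deficit / state.eawr * 100.0
    h = day.get("hours_above_30") if hasattr(day, "get") else None
    if h is None or pd.isna(h):
        h = heat_hours(day, params.heat_threshold)
    return water + heat_term(h, day["tmax"], params.heat_threshold, params.heat_scale)


def sid_series(
    weather: pd.DataFrame,
    eawr: float | None = None,
    init_deficit: float = 0.0,
    params: SIDParams = SIDParams(),
    env: str = "env",
) -> SIDSeries:
    """Per-day SID over a contiguous weather series.

    The balance is advanced first, then the day scored, so a day's own
    water inputs count against its deficit.  If *weather* carries a
    ``deficit`` column (e.g. from an external irrigation tool) it is
    used verbatim and *eawr* only sets the denominator.
    """
    weather = weather.reset_index(drop=True)
    missing = set(WEATHER_COLUMNS) - set(weather.columns)
    if missing:
        raise ValueError(f"weather missing columns {sorted(missing)}")
    dates = pd.to_datetime(weather["date"])
    gaps = dates.diff().dropna()
    if len(weather) == 0:
        raise ValueError("empty weather series")
    if (gaps != pd.Timedelta(days=1)).any():
        raise ValueError("weather dates must be contiguous daily and increasing")
    if eawr is None:
        raise ValueError("eawr is required")

    if "deficit" in weather.columns and weather["deficit"].notna().all():
        deficits = weather["deficit"].to_numpy(dtype=float)
        if (deficits < 0).any():
            raise ValueError("externally supplied deficit must be >= 0")
    else:
        deficits = water_balance_series(weather, eawr, init_deficit)

    water_terms = deficits / eawr * 100.0
    heat_terms = np.empty(len(weather))
    for i, (_, row) in enumerate(weather.iterrows()):
        h = row.get("hours_above_30")
        if h is None or pd.isna(h):
            h = heat_hours(row, params.heat_threshold)
        heat_terms[i] = heat_term(h, row["tmax"], params.heat_threshold, params.heat_scale)

    frame = pd.DataFrame(
        {
            "date": dates.dt.date,
            "deficit": deficits,
            "water_term": water_terms,
            "heat_term": heat_terms,
            "sid": water_terms + heat_terms,
        }
    )
    return SIDSeries(env=env, frame=frame)


def _window_mask(dates: pd.Series, start: date, end: date) -> pd.Series:
    return (dates >= start) & (dates <= end)


def period_sum(series: SIDSeries, window, year: int | None = None) -> float:
    """Sum of daily SID over a closed date window.

    *window* is either a ((m, d), (m, d)) template (resolved against
    *year*, defaulting to the series' first year) or a (date, date) pair.
    """
    dates = pd.Series(series.frame["date"])
    if isinstance(window[0], tuple):
        year = year if year is not None else dates.iloc[0].year
        start, end = resolve_window(window, year)
    else:
        start, end = window
    mask = _window_mask(dates, start, end)
    if not mask.any():
        raise ValueError(f"window {start}..{end} not covered by series")
    n_expected = (end - start).days + 1
    if mask.sum() < n_expected:
        raise ValueError(f"window {start}..{end} only partially covered")
    return float(series.frame.loc[mask.to_numpy(), "sid"].sum())


def _halfmonth_windows(start: date, end: date):
    """Yield (window_start, window_end) half-month windows touching [start, end]."""
    d = date(start.year, start.month, 1 if start.day <= 15 else 16)
    while d <= end:
        if d.day == 1:
            w_end = date(d.year, d.month, 15)
        else:
            nxt = (d.replace(day=28) + timedelta(days=4)).replace(day=1)
            w_end = nxt - timedelta(days=1)
        yield d, w_end
        w = w_end + timedelta(days=1)
        d = w
    return


def halfmonth_means(series: SIDSeries) -> pd.DataFrame:
    """Mean daily SID per half-month window (day 1–15 and 16–end).

    Returns one row per window touched by the series with columns
    ``start``, ``end``, ``mean_sid``, ``n_days`` and ``complete`` —
    partially covered windows are flagged, not dropped.
    """
    dates = pd.Series(series.frame["date"])
    if dates.empty:
        raise ValueError("empty series")
    rows = []
    for w_start, w_end in _halfmonth_windows(dates.iloc[0], dates.iloc[-1]):
        mask = _window_mask(dates, w_start, w_end)
        n = int(mask.sum())
        if n == 0:
            continue
        rows.append(
            {
                "start": w_start,
                "end": w_end,
                "mean_sid": float(series.frame.loc[mask.to_numpy(), "sid"].mean()),
                "n_days": n,
                "complete": n == (w_end - w_start).days + 1,
            }
        )
    return pd.DataFrame(rows)


def env_summary(
    weather: pd.DataFrame, window, params: SIDParams = SIDParams()
) -> EnvSummary:
    """Auxiliary environmental traits over one window.

    TWI (rain + irrigation), signed TWI − ETPP, mean temperature, mean
    humidity, PAR sum and heat-stress duration.  Humidity and PAR are
    optional inputs; their summaries are None when absent.
    """
    dates = pd.to_datetime(weather["date"]).dt.date
    if isinstance(window[0], tuple):
        start, end = resolve_window(window, dates.iloc[0].year)
    else:
        start, end = window
    sub = weather.loc[_window_mask(pd.Series(dates), start, end).to_numpy()]
    if sub.empty:
        raise ValueError(f"window {start}..{end} not covered")
    twi = float(sub["rainfall"].sum() + sub["irrigation"].sum())
    etpp = float(sub["etp"].sum())
    if "tmin" in sub.columns and sub["tmin"].notna().all():
        mean_temp = float(((sub["tmax"] + sub["tmin"]) / 2.0).mean())
    else:
        mean_temp = float(sub["tmax"].mean())
    humidity = (
        float(sub["humidity"].mean())
        if "humidity" in sub.columns and sub["humidity"].notna().any()
        else None
    )
    par = (
        float(sub["par"].sum())
        if "par" in sub.columns and sub["par"].notna().any()
        else None
    )
    hsd = 0.0
    for _, row in sub.iterrows():
        h = row.get("hours_above_30")
        if h is None or pd.isna(h):
            h = heat_hours(row, params.heat_threshold)
        hsd += float(h)
    return EnvSummary(
        twi=twi,
        twi_minus_etpp=twi - etpp,
        mean_temp=mean_temp,
        mean_humidity=humidity,
        par_sum=par,
        hsd=hsd,
    )


def classify_environment(
    halfmonth: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> StressCategory:
    """Label an environment from its semi-monthly SID profile.

    humid when no complete semi-monthly mean exceeds the humid ceiling;
    severe when the flowering-fortnight (Jul 1–15) mean exceeds the
    severe cutoff; moderate_to_severe otherwise.  Deterministic in the
    profile and the configured thresholds.
    """
    complete = halfmonth.loc[halfmonth["complete"]]
    if complete.empty:
        raise ValueError("no complete half-month windows in profile")
    pflo_rows = complete.loc[
        [s.month == 7 and s.day == 1 for s in complete["start"]]
    ]
    if pflo_rows.empty:
        raise ValueError("profile does not cover the Jul 1-15 flowering window")
    pflo_mean = float(pflo_rows["mean_sid"].iloc[0])
    max_mean = float(complete["mean_sid"].max())
    if max_mean <= thresholds.humid_ceiling:
        label = "humid"
    elif pflo_mean > thresholds.severe_pflo_mean:
        label = "severe"
    else:
        label = "moderate_to_severe"
    return StressCategory(label=label, pflo_mean=pflo_mean, max_halfmonth_mean=max_mean)
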