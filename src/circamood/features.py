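"""Per-day circadian feature engineering.

Thirteen basic features are computed for each patient-day from four sensor
categories (steps, light, sleep, heart rate), then each basic feature is
expanded with mean / sample-SD / linear-regression-gradient statistics over
the trailing 3-, 6- and 12-day windows, yielding
``13 + 13*3*3 = 130`` predictor columns per day.

Feature-day alignment (anti-leakage): every feature attributed to day ``d``
uses only data up to the end of day ``d``.  Concretely,

* ``*_during_bedtime`` for day ``d`` aggregates the 8-h night *ending at
  sunrise of day d* (the night the subject woke up from on day ``d``),
* ``*_during_daytime`` uses ``[sunrise(d), sunset(d))``,
* the cosinor window covers days ``d-1`` and ``d``,
* sleep records are attributed to the wake-up date,
* trailing windows of size ``w`` cover days ``d-w+1 .. d`` inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cosinor import CosinorFit, fit_cosinor
from .solar import SolarCalendar

__all__ = [
    "BASIC_FEATURES",
    "FEATURE_COLUMNS",
    "FAMILIES",
    "WINDOWS",
    "STATS",
    "family_columns",
    "basic_features",
    "daily_basic_frame",
    "sleep_timing_dev",
    "circular_mean_hours",
    "extend_features",
    "extract_features",
    "feature_dictionary",
]

WINDOWS = (3, 6, 12)
STATS = ("mean", "stdev", "gradient")

BASIC_FEATURES = (
    "steps_during_bedtime",
    "steps_during_daytime",
    "light_exposure_during_bedtime",
    "light_exposure_during_daytime",
    "sleep_length",
    "sleep_efficiency",
    "sleep_onset_dev",
    "sleep_offset_dev",
    "HR_CR_amplitude",
    "HR_CR_acrophase",
    "HR_CR_mesor",
    "HR_CR_rsquared",
    "resting_heart_rate",
)

#: the full, ordered 130-column predictor registry
FEATURE_COLUMNS = tuple(BASIC_FEATURES) + tuple(
    f"{b}_{w}d_{s}" for b in BASIC_FEATURES for w in WINDOWS for s in STATS
)

#: sensor family -> its basic features (each family also owns the
#: corresponding extended columns)
FAMILIES = {
    "steps": ("steps_during_bedtime", "steps_during_daytime"),
    "light": ("light_exposure_during_bedtime", "light_exposure_during_daytime"),
    "sleep": ("sleep_length", "sleep_efficiency", "sleep_onset_dev", "sleep_offset_dev"),
    "heart_rate": ("HR_CR_amplitude", "HR_CR_acrophase", "HR_CR_mesor", "HR_CR_rsquared", "resting_heart_rate"),
}

#: columns that wrap on the 24-h clock and need unwrapping before window stats
_CIRCULAR_BASICS = ("HR_CR_acrophase",)


def family_columns(family: str) -> list[str]:
    """All feature columns (basic + extended) belonging to a sensor family."""
    if family not in FAMILIES:
        raise KeyError(f"unknown feature family {family!r}; expected one of {sorted(FAMILIES)}")
    cols = []
    for b in FAMILIES[family]:
        cols.append(b)
        cols.extend(f"{b}_{w}d_{s}" for w in WINDOWS for s in STATS)
    return cols


# ---------------------------------------------------------------------------
# circular statistics for clock times

def circular_mean_hours(hours: Iterable[float]) -> float:
    """Circular mean of clock times on the 24-h dial, in ``[0, 24)``."""
    h = np.asarray(list(hours), dtype=float)
    ang = h * (2.0 * math.pi / 24.0)
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if s == 0.0 and c == 0.0:
        return float("nan")
    out = (math.atan2(s, c) * 24.0 / (2.0 * math.pi)) % 24.0
    return 0.0 if out >= 24.0 else out


def circular_diff_hours(a: float, b: float) -> float:
    """Absolute shortest-arc difference between two clock times, in [0, 12]."""
    d = (a - b) % 24.0
    return min(d, 24.0 - d)


def sleep_timing_dev(
    history: pd.DataFrame,
    d: Date,
    which: str,
    lookback_days: int = 7,
    min_records: int = 3,
) -> float:
    """Deviation of day-``d`` sleep onset/offset clock time from its
    recent norm.

    The norm is the circular mean of the clock times among the
    ``lookback_days`` days strictly preceding ``d``; at least
    ``min_records`` of them must be present.  Returns the absolute circular
    (shortest-arc) deviation in hours, or NaN when unavailable.

    ``history`` is a sleep frame with ``date`` plus ``onset``/``offset``
    timestamp columns.
    """
    if which not in ("onset", "offset"):
        raise ValueError("which must be 'onset' or 'offset'")
    d = pd.Timestamp(d).date()
    by_date = {pd.Timestamp(r["date"]).date(): r for _, r in history.iterrows()}
    if d not in by_date:
        return float("nan")
    prior = [
        by_date[d - timedelta(days=k)]
        for k in range(1, lookback_days + 1)
        if d - timedelta(days=k) in by_date
    ]
    if len(prior) < min_records:
        return float("nan")

    def clock(row) -> float:
        ts = pd.Timestamp(row[which])
        return ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9

    mean = circular_mean_hours(clock(r) for r in prior)
    return circular_diff_hours(clock(by_date[d]), mean)


# ---------------------------------------------------------------------------
# basic features

@dataclass(frozen=True)
class DailyFeatures:
    """The 13 basic features of one patient-day; NaN marks missing."""

    patient_id: str
    date: Date
    values: dict

    def __post_init__(self) -> None:
        assert set(self.values) == set(BASIC_FEATURES)


def _window_dates(start, end):
    lo = pd.Timestamp(start).normalize()
    hi = pd.Timestamp(end) - pd.Timedelta(nanoseconds=1)
    return {ts.date() for ts in pd.date_range(lo, hi.normalize(), freq="D")}


def _window_aggregate(ts: np.ndarray, vals: np.ndarray, start, end, how: str, present_dates=None) -> float:
    """Aggregate values whose timestamps fall in [start, end).

    For ``how='sum'`` an empty window counts as 0 provided the stream has
    *any* sample on a calendar date overlapped by the window (a counter
    stream with no events is a genuine zero); with no overlapping dates the
    stream is treated as absent and NaN is returned.  Means of empty
    windows are always NaN.
    """
    lo = np.searchsorted(ts, np.datetime64(start), side="left")
    hi = np.searchsorted(ts, np.datetime64(end), side="left")
    seg = vals[lo:hi]
    if how == "sum":
        if len(seg):
            return float(seg.sum())
        if present_dates is not None and _window_dates(start, end) & present_dates:
            return 0.0
        return float("nan")
    if len(seg) == 0:
        return float("nan")
    return float(seg.mean())


def _resting_hr(day_hr: pd.Series, smooth_minutes: int = 5) -> float:
    """Minimum of the ``smooth_minutes``-sample rolling mean of day HR."""
    if len(day_hr) < smooth_minutes:
        return float("nan")
    roll = day_hr.rolling(smooth_minutes, min_periods=smooth_minutes).mean()
    m = roll.min()
    return float(m) if pd.notna(m) else float("nan")


def _sorted_stream(df: pd.DataFrame, value_col: str):
    if df is None or len(df) == 0:
        return np.empty(0, dtype="datetime64[ns]"), np.empty(0)
    s = df.sort_values("timestamp")
    return s["timestamp"].to_numpy(dtype="datetime64[ns]"), s[value_col].to_numpy(dtype=float)


def daily_basic_frame(
    bundle,
    calendar: SolarCalendar,
    dates: Optional[list[Date]] = None,
    min_hr_samples: int = 1440,
    resting_smooth_minutes: int = 5,
) -> pd.DataFrame:
    """Compute the 13 basic features for every requested date of one bundle.

    Returns a DataFrame indexed by date with one column per basic feature;
    missing inputs propagate as NaN.
    """
    if dates is None:
        dates = _default_dates(bundle)
    step_ts, step_v = _sorted_stream(bundle.steps, "steps")
    step_dates = {pd.Timestamp(t).date() for t in step_ts}
    light_ts, light_v = _sorted_stream(bundle.light, "lux")
    hr_sorted = bundle.hr.sort_values("timestamp") if len(bundle.hr) else bundle.hr
    hr_ts = hr_sorted["timestamp"].to_numpy(dtype="datetime64[ns]") if len(hr_sorted) else np.empty(0, dtype="datetime64[ns]")
    hr_v = hr_sorted["bpm"].to_numpy(dtype=float) if len(hr_sorted) else np.empty(0)

    sleep = bundle.sleep
    sleep_by_date = {}
    if sleep is not None and len(sleep):
        for _, r in sleep.iterrows():
            sleep_by_date[pd.Timestamp(r["date"]).date()] = r

    rows = []
    for d in dates:
        d = pd.Timestamp(d).date()
        day0 = pd.Timestamp(d)
        feat = dict.fromkeys(BASIC_FEATURES, float("nan"))

        # solar windows; the bedtime window of the feature day ends at
        # sunrise(d) — it is the night preceding the day's wake-up
        try:
            day_win = calendar.daytime_window(d)
            bed_win = calendar.bedtime_window(d - timedelta(days=1))
        except Exception:
            day_win = bed_win = None

        if day_win is not None:
            feat["steps_during_daytime"] = _window_aggregate(step_ts, step_v, day_win.start, day_win.end, "sum", step_dates)
            feat["steps_during_bedtime"] = _window_aggregate(step_ts, step_v, bed_win.start, bed_win.end, "sum", step_dates)
            feat["light_exposure_during_daytime"] = _window_aggregate(light_ts, light_v, day_win.start, day_win.end, "mean")
            feat["light_exposure_during_bedtime"] = _window_aggregate(light_ts, light_v, bed_win.start, bed_win.end, "mean")

        rec = sleep_by_date.get(d)
        if rec is not None:
            onset, offset = pd.Timestamp(rec["onset"]), pd.Timestamp(rec["offset"])
            feat["sleep_length"] = (offset - onset) / pd.Timedelta(hours=1)
            feat["sleep_efficiency"] = float(rec["efficiency"])
            feat["sleep_onset_dev"] = sleep_timing_dev(sleep, d, "onset")
            feat["sleep_offset_dev"] = sleep_timing_dev(sleep, d, "offset")

        # 48-h cosinor window: days d-1 and d
        lo = np.searchsorted(hr_ts, np.datetime64(day0 - pd.Timedelta(days=1)), side="left")
        hi = np.searchsorted(hr_ts, np.datetime64(day0 + pd.Timedelta(days=1)), side="left")
        if hi > lo:
            win = pd.DataFrame({"timestamp": hr_ts[lo:hi], "bpm": hr_v[lo:hi]})
            fit = fit_cosinor(win, min_samples=min_hr_samples)
            if not fit.is_missing:
                feat["HR_CR_amplitude"] = fit.amplitude
                feat["HR_CR_acrophase"] = fit.acrophase if fit.acrophase is not None else float("nan")
                feat["HR_CR_mesor"] = fit.mesor
                feat["HR_CR_rsquared"] = fit.r_squared

        dlo = np.searchsorted(hr_ts, np.datetime64(day0), side="left")
        dhi = np.searchsorted(hr_ts, np.datetime64(day0 + pd.Timedelta(days=1)), side="left")
        if dhi > dlo:
            feat["resting_heart_rate"] = _resting_hr(pd.Series(hr_v[dlo:dhi]), resting_smooth_minutes)

        feat["date"] = d
        rows.append(feat)

    out = pd.DataFrame(rows).set_index("date")
    return out[list(BASIC_FEATURES)]


def basic_features(bundle, calendar: SolarCalendar, d: Date, **kwargs) -> DailyFeatures:
    """The 13 basic features for a single day (convenience wrapper)."""
    frame = daily_basic_frame(bundle, calendar, dates=[d], **kwargs)
    return DailyFeatures(
        patient_id=bundle.patient_id,
        date=pd.Timestamp(d).date(),
        values=frame.iloc[0].to_dict(),
    )


def _default_dates(bundle) -> list[Date]:
    stamps = []
    for df, col in ((bundle.hr, "timestamp"), (bundle.steps, "timestamp"), (bundle.light, "timestamp")):
        if df is not None and len(df):
            stamps.append(pd.Timestamp(df[col].min()).normalize())
            stamps.append(pd.Timestamp(df[col].max()).normalize())
    for df in (bundle.sleep, bundle.mood):
        if df is not None and len(df):
            stamps.append(pd.Timestamp(pd.to_datetime(df["date"]).min()))
            stamps.append(pd.Timestamp(pd.to_datetime(df["date"]).max()))
    if not stamps:
        return []
    lo, hi = min(stamps), max(stamps)
    return [ts.date() for ts in pd.date_range(lo, hi, freq="D")]


# ---------------------------------------------------------------------------
# extended (multi-day window) features

def _unwrap_hours(series: pd.Series, period: float = 24.0) -> pd.Series:
    """Shortest-arc continuation of a wrapped clock-time series.

    NaNs are preserved; continuation chains across them.
    """
    vals = series.to_numpy(dtype=float).copy()
    prev = None
    for i, v in enumerate(vals):
        if np.isnan(v):
            continue
        if prev is not None:
            k = round((prev - v) / period)
            vals[i] = v + k * period
            # nudge to the true shortest arc
            while vals[i] - prev > period / 2:
                vals[i] -= period
            while vals[i] - prev < -period / 2:
                vals[i] += period
        prev = vals[i]
    return pd.Series(vals, index=series.index)


def _rolling_slope(values: pd.Series, w: int) -> pd.Series:
    """OLS slope of value against day index over trailing windows of ``w``
    days; NaN whenever any constituent day is missing."""
    x = np.arange(w, dtype=float)
    x = x - x.mean()
    denom = float((x**2).sum())

    def slope(a: np.ndarray) -> float:
        if np.isnan(a).any():
            return float("nan")
        return float((x * (a - a.mean())).sum() / denom)

    return values.rolling(w, min_periods=w).apply(slope, raw=True)


def extend_features(daily: pd.DataFrame, windows=WINDOWS, stats=STATS) -> pd.DataFrame:
    """Expand a per-day basic-feature frame into the full 130-column row set.

    ``daily`` must be indexed by consecutive calendar dates (one row per
    day) with the 13 basic-feature columns.  A window statistic for day
    ``d`` over window ``w`` covers days ``d-w+1 .. d`` and is NaN if any
    constituent basic value is missing.  Clock-valued features (acrophase)
    are unwrapped before windowed statistics; their windowed mean is
    re-wrapped into ``[0, 24)``.
    """
    idx = pd.to_datetime(pd.Series(daily.index))
    if len(idx) > 1 and not (idx.diff().dropna() == pd.Timedelta(days=1)).all():
        raise ValueError("daily frame must cover consecutive calendar dates")

    out = {b: daily[b] for b in BASIC_FEATURES}
    for b in BASIC_FEATURES:
        col = daily[b]
        circular = b in _CIRCULAR_BASICS
        base = _unwrap_hours(col) if circular else col
        for w in windows:
            if "mean" in stats:
                m = base.rolling(w, min_periods=w).mean()
                if circular:
                    m = m % 24.0
                out[f"{b}_{w}d_mean"] = m
            if "stdev" in stats:
                out[f"{b}_{w}d_stdev"] = base.rolling(w, min_periods=w).std(ddof=1)
            if "gradient" in stats:
                out[f"{b}_{w}d_gradient"] = _rolling_slope(base, w)
    res = pd.DataFrame(out, index=daily.index)
    return res[list(FEATURE_COLUMNS)]


def extract_features(bundle, calendar: SolarCalendar, dates=None, **kwargs) -> pd.DataFrame:
    """Full feature matrix for one bundle: 130 columns, one row per day."""
    daily = daily_basic_frame(bundle, calendar, dates=dates, **kwargs)
    if len(daily) == 0:
        return pd.DataFrame(columns=["patient_id"] + list(FEATURE_COLUMNS))
    full = extend_features(daily)
    full.insert(0, "patient_id", bundle.patient_id)
    return full


# ---------------------------------------------------------------------------

_UNITS = {
    "steps_during_bedtime": "steps (sum over the 8-h night window)",
    "steps_during_daytime": "steps (sum over sunrise..sunset)",
    "light_exposure_during_bedtime": "lux (mean over the 8-h night window)",
    "light_exposure_during_daytime": "lux (mean over sunrise..sunset)",
    "sleep_length": "hours (offset - onset)",
    "sleep_efficiency": "percent, tracker-reported",
    "sleep_onset_dev": "hours; circular deviation from trailing 7-day circular-mean onset",
    "sleep_offset_dev": "hours; circular deviation from trailing 7-day circular-mean offset",
    "HR_CR_amplitude": "bpm; cosinor amplitude of the trailing 48-h HR window",
    "HR_CR_acrophase": "hours-of-day in [0,24); clock time of the cosinor peak",
    "HR_CR_mesor": "bpm; cosinor rhythm-adjusted mean",
    "HR_CR_rsquared": "fraction in [0,1]; cosinor goodness of fit",
    "resting_heart_rate": "bpm; minimum of the 5-min rolling-mean HR of the day",
}


def feature_dictionary() -> str:
    """Markdown documentation of all 130 feature columns."""
    lines = [
        "# Feature dictionary",
        "",
        f"{len(FEATURE_COLUMNS)} predictor columns per patient-day: "
        "13 basic features plus, for each, trailing-window statistics over "
        "3, 6 and 12 days (mean, sample SD with denominator w-1, and the "
        "OLS gradient of value against day index, units per day).",
        "",
        "## Basic features",
        "",
    ]
    for b in BASIC_FEATURES:
        lines.append(f"- `{b}` — {_UNITS[b]}")
    lines += [
        "",
        "## Extended features",
        "",
        "For every basic feature `F`, window `w` in {3, 6, 12} days and "
        "statistic `s` in {mean, stdev, gradient}: `F_<w>d_<s>` computed over "
        "days d-w+1..d; missing if any constituent day is missing. "
        "`HR_CR_acrophase` windows are unwrapped (shortest-arc continuation) "
        "before SD/gradient; the windowed mean is re-wrapped into [0, 24).",
        "",
    ]
    return "\n".join(lines)
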