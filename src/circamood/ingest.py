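"""File schemas, per-patient bundle assembly, and the complete-row filter.

CSV schemas (all timestamps ISO-8601 with explicit UTC offset; dates
``YYYY-MM-DD``):

* ``hr.csv``       — ``patient_id,timestamp,bpm``
* ``steps.csv``    — ``patient_id,timestamp,steps``
* ``light.csv``    — ``patient_id,timestamp,lux``
* ``sleep.csv``    — ``patient_id,date,onset,offset,efficiency``
* ``mood.csv``     — ``patient_id,date,score``
* ``episodes.csv`` — ``patient_id,start,end,type``
* ``site.yaml``    — ``latitude, longitude, tz`` and optionally ``suntimes``
  (path to a ``date,sunrise,sunset`` CSV overriding computed solar times)

Internally timestamps are naive local civil time at the site; the fixed UTC
offset lives in :class:`Site`.  Rows failing validation are rejected and
counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .features import FAMILIES, FEATURE_COLUMNS, family_columns
from .solar import SolarCalendar

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "SensorBundle",
    "Cohort",
    "EPISODE_TYPES",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "filter_complete_rows",
    "missingness_breakdown",
]

EPISODE_TYPES = ("DE", "ME", "HME")

STREAM_FILES = {
    "hr": ("hr.csv", ["patient_id", "timestamp", "bpm"]),
    "steps": ("steps.csv", ["patient_id", "timestamp", "steps"]),
    "light": ("light.csv", ["patient_id", "timestamp", "lux"]),
    "sleep": ("sleep.csv", ["patient_id", "date", "onset", "offset", "efficiency"]),
    "mood": ("mood.csv", ["patient_id", "date", "score"]),
    "episodes": ("episodes.csv", ["patient_id", "start", "end", "type"]),
}


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


@dataclass(frozen=True)
class Site:
    latitude: float
    longitude: float
    tz: float  # fixed UTC offset, hours
    suntimes: Optional[pd.DataFrame] = None

    def calendar(self) -> SolarCalendar:
        return SolarCalendar(self.latitude, self.longitude, self.tz, suntimes=self.suntimes)

    @property
    def offset_str(self) -> str:
        sign = "+" if self.tz >= 0 else "-"
        h = int(abs(self.tz))
        m = int(round((abs(self.tz) - h) * 60))
        return f"{sign}{h:02d}:{m:02d}"


@dataclass
class SensorBundle:
    """All raw streams of one patient plus the site descriptor.

    Stream frames use naive local timestamps (``datetime64[ns]``); empty
    frames are valid.
    """

    patient_id: str
    hr: pd.DataFrame
    steps: pd.DataFrame
    light: pd.DataFrame
    sleep: pd.DataFrame
    mood: pd.DataFrame
    episodes: pd.DataFrame
    site: Site

    def copy(self) -> "SensorBundle":
        return replace(
            self,
            hr=self.hr.copy(),
            steps=self.steps.copy(),
            light=self.light.copy(),
            sleep=self.sleep.copy(),
            mood=self.mood.copy(),
            episodes=self.episodes.copy(),
        )


@dataclass
class Cohort:
    bundles: dict
    site: Site
    rejections: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.bundles.values())

    def __len__(self):
        return len(self.bundles)


# ---------------------------------------------------------------------------
# reading

def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


def _parse_local(series: pd.Series, tz: float) -> pd.Series:
    """Parse ISO-8601 timestamps (with offsets) into naive local time."""
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return (ts + pd.Timedelta(hours=tz)).dt.tz_localize(None)


def _validate_stream(df: pd.DataFrame, value_col: str, lower, strict_lower: bool, fname: str, rejections: dict):
    vals = pd.to_numeric(df[value_col], errors="coerce")
    ok = vals.notna()
    ok &= (vals > lower) if strict_lower else (vals >= lower)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d out-of-range/unparseable rows", fname, n_bad)
        rejections[fname] = rejections.get(fname, 0) + n_bad
    out = df.loc[ok].copy()
    out[value_col] = vals[ok]
    return out


def _check_monotone(df: pd.DataFrame, col: str, fname: str, pid: str) -> None:
    ts = df[col]
    if len(ts) > 1 and not ts.is_monotonic_increasing:
        raise SchemaError(f"{fname}: non-monotone timestamps for patient {pid!r}")
    if len(ts) > 1 and ts.duplicated().any():
        raise SchemaError(f"{fname}: duplicate timestamps for patient {pid!r}")


def read_site(path: Path) -> Site:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    suntimes = None
    if raw.get("suntimes"):
        sp = Path(raw["suntimes"])
        if not sp.is_absolute():
            sp = Path(path).parent / sp
        suntimes = pd.read_csv(sp)
    return Site(
        latitude=float(raw["latitude"]),
        longitude=float(raw["longitude"]),
        tz=float(raw["tz"]),
        suntimes=suntimes,
    )


def read_cohort(directory, site: Optional[Site] = None) -> Cohort:
    """Read every stream file under ``directory`` and assemble one
    :class:`SensorBundle` per patient id seen in any stream."""
    directory = Path(directory)
    if site is None:
        site = read_site(directory / "site.yaml")
    rejections: dict = {}

    frames: dict[str, pd.DataFrame] = {}
    for stream, (fname, cols) in STREAM_FILES.items():
        path = directory / fname
        if not path.exists():
            frames[stream] = pd.DataFrame(columns=cols)
            continue
        df = pd.read_csv(path, dtype={"patient_id": str})
        _require_columns(df, cols, fname)
        frames[stream] = _parse_stream(df, stream, site, fname, rejections)

    ids = sorted(set().union(*(set(f["patient_id"]) for f in frames.values())))
    bundles = {}
    for pid in ids:
        parts = {s: f[f["patient_id"] == pid].drop(columns=["patient_id"]).reset_index(drop=True) for s, f in frames.items()}
        for s in ("hr", "steps", "light"):
            _check_monotone(parts[s], "timestamp", STREAM_FILES[s][0], pid)
        bundles[pid] = SensorBundle(patient_id=pid, site=site, **parts)
    return Cohort(bundles=bundles, site=site, rejections=rejections)


def _parse_stream(df: pd.DataFrame, stream: str, site: Site, fname: str, rejections: dict) -> pd.DataFrame:
    df = df.copy()
    if stream in ("hr", "steps", "light"):
        df["timestamp"] = _parse_local(df["timestamp"], site.tz)
        value_col, lower, strict = {"hr": ("bpm", 0, True), "steps": ("steps", 0, False), "light": ("lux", 0, False)}[stream]
        df = _validate_stream(df, value_col, lower, strict, fname, rejections)
    elif stream == "sleep":
        df["date"] = pd.to_datetime(df["date"]).dt.date
        df["onset"] = _parse_local(df["onset"], site.tz)
        df["offset"] = _parse_local(df["offset"], site.tz)
        eff = pd.to_numeric(df["efficiency"], errors="coerce")
        ok = eff.notna() & (eff >= 0) & (eff <= 100) & (df["onset"] < df["offset"])
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: rejected %d invalid rows", fname, n_bad)
            rejections[fname] = rejections.get(fname, 0) + n_bad
        df = df.loc[ok].copy()
        df["efficiency"] = eff[ok]
    elif stream == "mood":
        df["date"] = pd.to_datetime(df["date"]).dt.date
        score = pd.to_numeric(df["score"], errors="coerce")
        ok = score.notna() & (score == score.round()) & (score >= -3) & (score <= 3)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: rejected %d out-of-range mood rows", fname, n_bad)
            rejections[fname] = rejections.get(fname, 0) + n_bad
        df = df.loc[ok].copy()
        df["score"] = score[ok].astype(int)
    elif stream == "episodes":
        df["start"] = pd.to_datetime(df["start"]).dt.date
        df["end"] = pd.to_datetime(df["end"]).dt.date
        ok = df["type"].isin(EPISODE_TYPES) & (df["start"] <= df["end"])
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: rejected %d invalid episode rows", fname, n_bad)
            rejections[fname] = rejections.get(fname, 0) + n_bad
        df = df.loc[ok].copy()
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# writing

def _fmt_ts(series: pd.Series, site: Site) -> pd.Series:
    return series.dt.strftime("%Y-%m-%dT%H:%M:%S") + site.offset_str


def write_cohort(cohort, directory) -> None:
    """Write all bundles of a cohort (dict or :class:`Cohort`) to the
    documented CSV schemas plus ``site.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundles = cohort.bundles if isinstance(cohort, Cohort) else cohort
    site = next(iter(bundles.values())).site

    def gather(stream: str) -> pd.DataFrame:
        parts = []
        for pid in sorted(bundles):
            df = getattr(bundles[pid], stream).copy()
            df.insert(0, "patient_id", pid)
            parts.append(df)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=STREAM_FILES[stream][1])

    for stream, (fname, cols) in STREAM_FILES.items():
        df = gather(stream)
        if stream in ("hr", "steps", "light") and len(df):
            df["timestamp"] = _fmt_ts(df["timestamp"], site)
        elif stream == "sleep" and len(df):
            df["date"] = pd.to_datetime(df["date"]).astype(str)
            df["onset"] = _fmt_ts(df["onset"], site)
            df["offset"] = _fmt_ts(df["offset"], site)
        elif stream == "mood" and len(df):
            df["date"] = pd.to_datetime(df["date"]).astype(str)
        elif stream == "episodes" and len(df):
            df["start"] = pd.to_datetime(df["start"]).astype(str)
            df["end"] = pd.to_datetime(df["end"]).astype(str)
        df[cols].to_csv(directory / fname, index=False)

    site_doc = {"latitude": site.latitude, "longitude": site.longitude, "tz": site.tz}
    if site.suntimes is not None:
        site.suntimes.to_csv(directory / "suntimes.csv", index=False)
        site_doc["suntimes"] = "suntimes.csv"
    with open(directory / "site.yaml", "w") as fh:
        yaml.safe_dump(site_doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# complete-row filter

def filter_complete_rows(matrix: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """Keep only rows where all 130 features and the mood score are present.

    Row order is preserved; the operation is idempotent.  The per-family
    missingness breakdown is logged for the pipeline report.
    """
    cols = [c for c in FEATURE_COLUMNS if c in matrix.columns]
    if len(cols) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(cols)
        raise SchemaError(f"feature matrix lacks {len(missing)} feature columns, e.g. {sorted(missing)[:3]}")
    if "mood_score" not in matrix.columns:
        raise SchemaError("feature matrix lacks mood_score column")
    subset = list(FEATURE_COLUMNS) + ["mood_score"]
    keep = matrix[subset].notna().all(axis=1)
    if log:
        bd = missingness_breakdown(matrix)
        logger.info(
            "complete-row filter: %d/%d rows kept; missing-value shares by family: %s",
            int(keep.sum()), len(matrix), bd,
        )
    return matrix.loc[keep]


def missingness_breakdown(matrix: pd.DataFrame) -> dict:
    """Share of all missing cells attributable to each sensor family (and
    the mood score), as fractions summing to 1 when anything is missing."""
    counts = {}
    for fam in FAMILIES:
        cols = family_columns(fam)
        counts[fam] = int(matrix[cols].isna().sum().sum())
    counts["mood"] = int(matrix["mood_score"].isna().sum()) if "mood_score" in matrix.columns else 0
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}
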