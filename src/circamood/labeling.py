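"""Mood-state and episode labels.

* AMS (absolute mood score) = ``|daily score|`` on a 0..3 scale; higher is
  more unstable in either direction.
* The 2-class mood-state label splits days on a percentile cutoff of the
  *forward* 3-day mean AMS: days in the top ``cutoff``% are ``biased``,
  the rest ``neutral``.  Ties at the threshold go to ``biased``.
* The 4-class episode label comes from clinician intervals (inclusive date
  ranges); any day outside all intervals is ``NE``.
"""

from __future__ import annotations

import logging
import warnings
from datetime import date as Date
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .ingest import EPISODE_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "compute_ams",
    "forward_mean_ams",
    "mood_state_threshold",
    "label_mood_state",
    "label_episode",
    "build_labeled_matrix",
    "NEUTRAL",
    "BIASED",
    "STANDARD_CUTOFFS",
]

NEUTRAL = "neutral"
BIASED = "biased"
STANDARD_CUTOFFS = (10, 30, 50)
FORWARD_DAYS = 3


def compute_ams(score: int) -> int:
    """Absolute mood score: |score|, valid for integer scores in -3..+3."""
    s = int(score)
    if s != score or not -3 <= s <= 3:
        raise ValueError(f"mood score must be an integer in [-3, 3], got {score!r}")
    return abs(s)


def forward_mean_ams(mood: pd.DataFrame, horizon: int = FORWARD_DAYS) -> pd.Series:
    """Mean AMS over days ``d+1 .. d+horizon`` for each date of one patient.

    Returns a Series indexed by date; NaN wherever any of the following
    ``horizon`` days' scores is absent.
    """
    if len(mood) == 0:
        return pd.Series(dtype=float)
    dates = pd.to_datetime(mood["date"])
    ams = mood["score"].abs().astype(float)
    s = pd.Series(ams.to_numpy(), index=dates).sort_index()
    full = s.reindex(pd.date_range(s.index.min(), s.index.max() + pd.Timedelta(days=horizon), freq="D"))
    fwd = sum(full.shift(-k) for k in range(1, horizon + 1)) / horizon
    fwd = fwd.loc[s.index]
    fwd.index = [ts.date() for ts in fwd.index]
    return fwd


def mood_state_threshold(reference: Iterable[float], cutoff_pct: float) -> float:
    """The (100 - cutoff)-th linear-interpolation percentile of the
    reference forward-AMS distribution (NaNs ignored)."""
    ref = np.asarray(list(reference), dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) == 0:
        raise ValueError("reference distribution is empty")
    return float(np.quantile(ref, 1.0 - cutoff_pct / 100.0))


def label_mood_state(
    fwd_ams: pd.Series,
    cutoff_pct: float = 50,
    reference: Optional[Iterable[float]] = None,
) -> pd.Series:
    """Two-class mood-state labels from forward 3-day mean AMS.

    ``biased`` iff ``fwd_ams >= threshold`` where the threshold is the
    (100 - cutoff)-th percentile of ``reference`` (defaults to ``fwd_ams``
    itself).  Rows with missing ``fwd_ams`` get missing labels.
    """
    if cutoff_pct not in STANDARD_CUTOFFS:
        warnings.warn(f"non-standard mood-state cutoff {cutoff_pct}%", stacklevel=2)
    thr = mood_state_threshold(fwd_ams if reference is None else reference, cutoff_pct)
    vals = pd.to_numeric(fwd_ams, errors="coerce")
    out = pd.Series(
        np.where(vals >= thr, BIASED, NEUTRAL), index=fwd_ams.index, dtype=object
    )
    out[vals.isna()] = None
    if (out.dropna() == BIASED).all() and out.notna().any():
        warnings.warn("degenerate labeling: every labeled day is 'biased'", stacklevel=2)
    return out


def label_episode(d: Date, episodes: pd.DataFrame) -> str:
    """Episode label of one day from inclusive clinician intervals."""
    d = pd.Timestamp(d).date()
    if len(episodes) == 0:
        return "NE"
    starts = pd.to_datetime(episodes["start"]).dt.date
    ends = pd.to_datetime(episodes["end"]).dt.date
    _check_no_overlap(starts, ends)
    hit = episodes.loc[(starts <= d) & (d <= ends), "type"]
    if len(hit) == 0:
        return "NE"
    return str(hit.iloc[0])


def _check_no_overlap(starts, ends) -> None:
    order = np.argsort(starts.to_numpy())
    s, e = starts.to_numpy()[order], ends.to_numpy()[order]
    for i in range(1, len(s)):
        if s[i] <= e[i - 1]:
            raise ValueError(f"overlapping episode intervals: {s[i]} <= {e[i - 1]}")


def episode_series(dates: Iterable[Date], episodes: pd.DataFrame) -> pd.Series:
    dates = [pd.Timestamp(d).date() for d in dates]
    if len(episodes) == 0:
        return pd.Series(["NE"] * len(dates), index=dates, dtype=object)
    starts = pd.to_datetime(episodes["start"]).dt.date.to_numpy()
    ends = pd.to_datetime(episodes["end"]).dt.date.to_numpy()
    _check_no_overlap(pd.Series(starts), pd.Series(ends))
    types = episodes["type"].to_numpy()
    out = []
    for d in dates:
        mask = (starts <= d) & (d <= ends)
        out.append(str(types[mask][0]) if mask.any() else "NE")
    return pd.Series(out, index=dates, dtype=object)


def build_labeled_matrix(features: pd.DataFrame, bundle) -> pd.DataFrame:
    """Join a per-day 130-column feature frame of one patient with its mood
    score, AMS, forward 3-day AMS and episode label.

    The mood-state label is *not* attached here: under the leak-free
    default it is computed per evaluation round from the training window's
    forward-AMS distribution (see the modeling module).
    """
    out = features.copy()
    dates = [pd.Timestamp(d).date() for d in out.index]
    out.index = pd.Index(dates, name="date")

    mood = bundle.mood
    score = pd.Series(dtype=float)
    if len(mood):
        score = pd.Series(mood["score"].to_numpy(dtype=float), index=[pd.Timestamp(x).date() for x in mood["date"]])
    out["mood_score"] = score.reindex(out.index)
    out["ams"] = out["mood_score"].abs()
    fwd = forward_mean_ams(mood) if len(mood) else pd.Series(dtype=float)
    out["fwd3_ams"] = fwd.reindex(out.index)
    out["episode"] = episode_series(out.index, bundle.episodes).to_numpy()
    return out
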