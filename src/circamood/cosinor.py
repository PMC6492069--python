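"""Single-component cosinor fit of heart-rate windows.

Fits ``y = M + beta1*cos(w t) + beta2*sin(w t)`` by ordinary least squares,
with ``w = 2*pi/period`` and ``t`` expressed in hours aligned to the local
clock (``t mod 24`` is hour-of-day).  The linearized fit is exactly
equivalent to fitting ``M + A*cos(w (t - phi))`` with ``A >= 0`` and
``phi`` the clock time of the peak (acrophase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CosinorFit", "fit_cosinor", "DEFAULT_PERIOD_H"]

DEFAULT_PERIOD_H = 24.0


@dataclass(frozen=True)
class CosinorFit:
    """The four rhythm parameters of one fitted window.

    ``acrophase`` is the clock time of the fitted peak in ``[0, 24)`` hours;
    it is ``None`` for a degenerate (flat) fit.  ``n_samples`` is
    bookkeeping, not a rhythm parameter.
    """

    mesor: Optional[float]
    amplitude: Optional[float]
    acrophase: Optional[float]
    r_squared: Optional[float]
    n_samples: int = 0

    #: names of the rhythm parameters proper
    PARAMETER_NAMES = ("mesor", "amplitude", "acrophase", "r_squared")

    @property
    def is_missing(self) -> bool:
        return self.mesor is None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.PARAMETER_NAMES}


_MISSING_FIT = CosinorFit(None, None, None, None, 0)


def _to_hours(timestamps) -> np.ndarray:
    """Convert timestamps to float hours aligned with the local clock."""
    ts = pd.to_datetime(pd.Series(timestamps))
    if len(ts) == 0:
        return np.empty(0)
    anchor = ts.iloc[0].normalize()
    return ((ts - anchor) / pd.Timedelta(hours=1)).to_numpy(dtype=float)


def fit_cosinor(
    hr_window: Sequence | pd.DataFrame,
    period: float = DEFAULT_PERIOD_H,
    min_samples: int = 48,
) -> CosinorFit:
    """Least-squares cosinor fit of one heart-rate window.

    Parameters
    ----------
    hr_window :
        Either a DataFrame with ``timestamp``/``bpm`` columns or a sequence
        of ``(timestamp, bpm)`` pairs.  The window is expected to span at
        most 48 h.
    period :
        Rhythm period in hours (default 24).
    min_samples :
        Minimum number of samples required; fewer returns a missing fit.

    Returns
    -------
    CosinorFit
        Missing-marked (all parameters ``None``) when preconditions fail.
        For a constant series: ``amplitude = 0``, ``acrophase`` missing,
        ``r_squared = 0``.
    """
    if isinstance(hr_window, pd.DataFrame):
        t = _to_hours(hr_window["timestamp"])
        y = hr_window["bpm"].to_numpy(dtype=float)
    else:
        pairs = list(hr_window)
        if not pairs:
            return _MISSING_FIT
        t = _to_hours([p[0] for p in pairs])
        y = np.asarray([p[1] for p in pairs], dtype=float)

    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(y)
    if n < max(min_samples, 3):
        return CosinorFit(None, None, None, None, n)

    omega = 2.0 * math.pi / period
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = beta
    amplitude = float(math.hypot(b1, b2))

    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0.0:
        # constant series: flat fit, phase undefined
        return CosinorFit(float(y.mean()), 0.0, None, 0.0, n)
    r2 = max(0.0, min(1.0, 1.0 - sse / sst))

    if amplitude == 0.0:
        return CosinorFit(float(mesor), 0.0, None, r2, n)
    acrophase = (math.atan2(b2, b1) / omega) % period
    return CosinorFit(float(mesor), amplitude, float(acrophase), r2, n)
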