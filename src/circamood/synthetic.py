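"""Synthetic multi-patient sensor cohort with known circadian structure.

Each patient-day carries a latent *instability* in [0, 1] driven by a
4-state episode Markov chain (NE/DE/ME/HME) through an AR(1) filter.  A
single ``coupling`` knob scales how strongly instability disrupts the
generated streams:

* night (bedtime-window) steps and light go **up**,
* daytime steps and light go **down**,
* sleep-timing jitter goes up and sleep efficiency down,
* the heart-rate cosinor acrophase shifts later by ``coupling *
  instability`` hours.

Daily mood score is ``round(polarity * 3 * instability) + integer noise``
clipped to -3..+3, with polarity negative in DE, positive in ME/HME, and a
random sign in NE — so the absolute mood score grows with instability and
``coupling = 0`` makes mood independent of every sensor stream.

All generator distributions are artifact choices for testability, not
claims about any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import timedelta
import warnings

import numpy as np
import pandas as pd
import yaml

from .ingest import SensorBundle, Site, Cohort
from .solar import SolarCalendar

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "inject_missingness", "STATES"]

STATES = ("NE", "DE", "ME", "HME")

_DEFAULT_TRANSITION = {
    "NE": {"NE": 0.96, "DE": 0.025, "ME": 0.0075, "HME": 0.0075},
    "DE": {"NE": 0.06, "DE": 0.94, "ME": 0.0, "HME": 0.0},
    "ME": {"NE": 0.10, "DE": 0.0, "ME": 0.90, "HME": 0.0},
    "HME": {"NE": 0.10, "DE": 0.0, "ME": 0.0, "HME": 0.90},
}

#: latent-instability set point per episode state
_INSTABILITY_TARGET = {"NE": 0.12, "DE": 0.80, "ME": 0.85, "HME": 0.70}
_POLARITY = {"NE": 0, "DE": -1, "ME": 1, "HME": 1}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 8
    n_days: int = 90
    start_date: str = "2023-03-01"
    # site (default: Seoul)
    latitude: float = 37.5665
    longitude: float = 126.978
    tz: float = 9.0
    # heart rate
    hr_mesor: float = 75.0
    hr_amplitude: float = 8.0
    hr_acrophase: float = 15.0  # hours-of-day of the HR peak
    hr_noise_sd: float = 5.0
    # sleep schedule
    sleep_onset_hour: float = 23.5
    sleep_offset_hour: float = 7.5
    sleep_jitter_sd: float = 0.4
    # activity / light levels
    day_step_rate: float = 12.0   # Poisson steps per daytime minute
    night_step_rate: float = 0.5  # baseline steps per bedtime minute
    day_lux_log_mean: float = 6.9   # ~1000 lux
    night_lux_log_mean: float = 0.0  # ~1 lux
    lux_log_sd: float = 0.6
    light_sample_minutes: int = 10
    # episode / instability dynamics
    transition: dict = field(default_factory=lambda: {s: dict(r) for s, r in _DEFAULT_TRANSITION.items()})
    instability_ar: float = 0.6
    instability_noise_sd: float = 0.06
    # disruption coupling (unitless, >= 0)
    coupling: float = 1.0
    # per-stream day-granular missingness fractions
    missing_rates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_days < 1:
            raise ConfigurationError("n_patients and n_days must be positive")
        if self.hr_amplitude < 0:
            raise ConfigurationError("hr_amplitude must be >= 0")
        if self.coupling < 0:
            raise ConfigurationError("coupling must be >= 0")
        mat = self.transition_matrix()
        if (mat < 0).any() or (mat > 1).any():
            raise ConfigurationError("transition probabilities must be in [0, 1]")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("transition matrix rows must sum to 1")
        for stream, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missing rate for {stream!r} outside [0, 1]")
        if self.n_days < 13:
            warnings.warn("n_days < 13: extended 12-day features will be incomplete", stacklevel=2)

    def transition_matrix(self) -> np.ndarray:
        return np.array([[self.transition[a].get(b, 0.0) for b in STATES] for a in STATES], dtype=float)

    def site(self) -> Site:
        return Site(latitude=self.latitude, longitude=self.longitude, tz=self.tz)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Latent per-patient-day truth: instability, episode state, and the HR
    cosinor parameters actually used by the generator."""

    table: pd.DataFrame  # patient_id, date, instability, episode_state,
    #                      true_mesor, true_amplitude, true_acrophase

    def for_patient(self, pid: str) -> pd.DataFrame:
        return self.table[self.table["patient_id"] == pid].reset_index(drop=True)

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out["date"] = pd.to_datetime(out["date"]).astype(str)
        out.to_csv(path, index=False)


def _simulate_states(n_days: int, mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Episode state indices; the chain starts from its stationary law."""
    evals, evecs = np.linalg.eig(mat.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    states = np.empty(n_days, dtype=int)
    states[0] = rng.choice(len(STATES), p=pi)
    for t in range(1, n_days):
        states[t] = rng.choice(len(STATES), p=mat[states[t - 1]])
    return states


def _simulate_instability(states: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    rho = cfg.instability_ar
    inst = np.empty(len(states))
    x = _INSTABILITY_TARGET[STATES[states[0]]]
    for t, s in enumerate(states):
        target = _INSTABILITY_TARGET[STATES[s]]
        x = rho * x + (1 - rho) * target + rng.normal(0.0, cfg.instability_noise_sd)
        x = float(np.clip(x, 0.0, 1.0))
        inst[t] = x
    return inst


def _episode_intervals(states: np.ndarray, dates: list) -> pd.DataFrame:
    rows = []
    i = 0
    while i < len(states):
        s = STATES[states[i]]
        j = i
        while j + 1 < len(states) and states[j + 1] == states[i]:
            j += 1
        if s != "NE":
            rows.append({"start": dates[i], "end": dates[j], "type": s})
        i = j + 1
    return pd.DataFrame(rows, columns=["start", "end", "type"])


def _simulate_patient(pid: str, cfg: SimConfig, calendar: SolarCalendar, rng: np.random.Generator):
    start = pd.Timestamp(cfg.start_date)
    dates = [(start + pd.Timedelta(days=k)).date() for k in range(cfg.n_days)]
    states = _simulate_states(cfg.n_days, cfg.transition_matrix(), rng)
    inst = _simulate_instability(states, cfg, rng)
    c = cfg.coupling

    minute_h = np.arange(1440) / 60.0  # hour-of-day of each minute
    hr_parts, step_parts, light_parts = [], [], []
    sleep_rows, mood_rows, truth_rows = [], [], []

    for k, d in enumerate(dates):
        day0 = pd.Timestamp(d)
        ts = day0 + pd.to_timedelta(np.arange(1440), unit="m")
        disruption = min(c * inst[k], 1.0) if c > 0 else 0.0

        # --- heart rate: cosinor with instability-shifted acrophase
        acro = (cfg.hr_acrophase + c * inst[k]) % 24.0
        hr = cfg.hr_mesor + cfg.hr_amplitude * np.cos(2 * np.pi * (minute_h - acro) / 24.0)
        if cfg.hr_noise_sd > 0:
            hr = hr + rng.normal(0.0, cfg.hr_noise_sd, size=1440)
        hr_parts.append(pd.DataFrame({"timestamp": ts, "bpm": np.maximum(hr, 30.0)}))

        # --- window membership for this calendar day
        day_win = calendar.daytime_window(d)
        bed_prev = calendar.bedtime_window(d - timedelta(days=1))  # night ending this morning
        bed_next = calendar.bedtime_window(d)  # night starting this evening
        in_day = np.asarray((ts >= day_win.start) & (ts < day_win.end))
        in_bed = np.asarray(
            ((ts >= bed_prev.start) & (ts < bed_prev.end)) | ((ts >= bed_next.start) & (ts < bed_next.end))
        )

        # --- steps: disruption moves activity from daytime into the night
        day_rate = cfg.day_step_rate * (1.0 - 0.6 * disruption)
        night_rate = cfg.night_step_rate + 8.0 * c * inst[k]
        other_rate = 0.5 * cfg.day_step_rate
        rates = np.where(in_day, day_rate, np.where(in_bed, night_rate, other_rate))
        step_parts.append(pd.DataFrame({"timestamp": ts, "steps": rng.poisson(np.maximum(rates, 0.0))}))

        # --- light: log-normal lux, sampled every few minutes
        sel = np.arange(0, 1440, cfg.light_sample_minutes)
        log_mean = np.where(
            in_day[sel],
            cfg.day_lux_log_mean + np.log(max(1.0 - 0.6 * disruption, 1e-3)),
            np.where(in_bed[sel], cfg.night_lux_log_mean + np.log1p(5.0 * c * inst[k]), cfg.day_lux_log_mean - 2.0),
        )
        lux = np.exp(rng.normal(log_mean, cfg.lux_log_sd))
        light_parts.append(pd.DataFrame({"timestamp": ts[sel], "lux": lux}))

        # --- sleep: onset on the previous evening, offset this morning
        jit = cfg.sleep_jitter_sd * (1.0 + 2.0 * c * inst[k])
        onset_h = cfg.sleep_onset_hour + rng.normal(0.0, jit)
        offset_h = cfg.sleep_offset_hour + rng.normal(0.0, jit)
        onset = day0 - pd.Timedelta(days=1) + pd.Timedelta(hours=float(onset_h))
        offset = day0 + pd.Timedelta(hours=float(max(offset_h, 0.1)))
        if offset <= onset:
            offset = onset + pd.Timedelta(hours=1)
        efficiency = float(np.clip(rng.normal(93.0 - 15.0 * disruption, 2.0), 50.0, 100.0))
        sleep_rows.append({"date": d, "onset": onset, "offset": offset, "efficiency": efficiency})

        # --- mood
        pol = _POLARITY[STATES[states[k]]]
        if pol == 0:
            pol = int(rng.choice([-1, 1]))
        score = int(np.clip(round(pol * 3.0 * inst[k]) + rng.integers(-1, 2), -3, 3))
        mood_rows.append({"date": d, "score": score})

        truth_rows.append(
            {
                "patient_id": pid,
                "date": d,
                "instability": inst[k],
                "episode_state": STATES[states[k]],
                "true_mesor": cfg.hr_mesor,
                "true_amplitude": cfg.hr_amplitude,
                "true_acrophase": acro,
            }
        )

    episodes = _episode_intervals(states, dates)

    bundle = SensorBundle(
        patient_id=pid,
        hr=pd.concat(hr_parts, ignore_index=True),
        steps=pd.concat(step_parts, ignore_index=True),
        light=pd.concat(light_parts, ignore_index=True),
        sleep=pd.DataFrame(sleep_rows),
        mood=pd.DataFrame(mood_rows),
        episodes=episodes,
        site=cfg.site(),
    )
    return bundle, pd.DataFrame(truth_rows)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate the full synthetic cohort deterministically from
    ``config.seed``; per-stream missingness is then injected day-granularly
    according to ``config.missing_rates``."""
    config.validate()
    calendar = config.site().calendar()
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients + 1)
    bundles, truths = {}, []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(patient_seeds[i])
        bundle, truth = _simulate_patient(pid, config, calendar, rng)
        bundles[pid] = bundle
        truths.append(truth)
    if any(r > 0 for r in config.missing_rates.values()):
        miss_rng = np.random.default_rng(patient_seeds[-1])
        for pid in sorted(bundles):
            bundles[pid], _ = _inject(bundles[pid], config.missing_rates, miss_rng)
    cohort = Cohort(bundles=bundles, site=config.site())
    return cohort, GroundTruth(pd.concat(truths, ignore_index=True))


# ---------------------------------------------------------------------------
# missingness

_STREAMS = ("hr", "steps", "light", "sleep", "mood")


def _bundle_dates(bundle) -> list:
    dates = set()
    for df in (bundle.sleep, bundle.mood):
        if len(df):
            dates.update(pd.Timestamp(x).date() for x in df["date"])
    for df in (bundle.hr, bundle.steps, bundle.light):
        if len(df):
            dates.update(pd.Timestamp(x).date() for x in df["timestamp"].dt.normalize().unique())
    return sorted(dates)


def _inject(bundle, rates: dict, rng: np.random.Generator):
    dates = _bundle_dates(bundle)
    removed: dict[str, set] = {}
    out = bundle.copy()
    for stream in _STREAMS:
        rate = rates.get(stream, 0.0)
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {stream!r} outside [0, 1]")
        if rate == 0.0 or len(dates) == 0:
            removed[stream] = set()
            continue
        mask = rng.random(len(dates)) < rate
        gone = {d for d, m in zip(dates, mask) if m}
        removed[stream] = gone
        df = getattr(out, stream)
        if len(df) == 0:
            continue
        if stream in ("sleep", "mood"):
            keep = ~df["date"].map(lambda x: pd.Timestamp(x).date()).isin(gone)
        else:
            keep = ~df["timestamp"].dt.date.isin(gone)
        setattr(out, stream, df.loc[keep].reset_index(drop=True))
    return out, removed


def inject_missingness(bundle: SensorBundle, rates: dict, seed: int) -> tuple[SensorBundle, dict]:
    """Remove whole days of individual streams at the given per-stream
    rates (Bernoulli per day).  Returns the thinned bundle and the mapping
    ``stream -> set of removed dates`` for test oracles."""
    rng = np.random.default_rng(seed)
    return _inject(bundle, rates, rng)
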