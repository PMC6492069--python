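"""High-level pipeline entry points shared by the CLI, tests and reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .features import BASIC_FEATURES, FEATURE_COLUMNS, extract_features
from .ingest import Cohort, filter_complete_rows, read_cohort, write_cohort
from .labeling import build_labeled_matrix
from .synthetic import GroundTruth, SimConfig, simulate_cohort

__all__ = [
    "config_hash",
    "cohort_matrix",
    "simulate_matrix",
    "write_matrix",
    "read_matrix",
    "hams_lams_comparison",
]

LABEL_COLUMNS = ("mood_score", "ams", "fwd3_ams", "episode")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cohort_matrix(cohort: Cohort, **kwargs) -> pd.DataFrame:
    """Pooled labeled feature matrix for a cohort: one row per
    patient-day with the 130 predictors plus mood/episode label inputs."""
    calendar = cohort.site.calendar()
    parts = []
    for pid in sorted(cohort.bundles):
        bundle = cohort.bundles[pid]
        feats = extract_features(bundle, calendar, **kwargs)
        if len(feats) == 0:
            continue
        labeled = build_labeled_matrix(feats, bundle)
        labeled = labeled.reset_index()
        parts.append(labeled)
    if not parts:
        return pd.DataFrame(columns=["patient_id", "date", *FEATURE_COLUMNS, *LABEL_COLUMNS])
    out = pd.concat(parts, ignore_index=True)
    return out[["patient_id", "date", *FEATURE_COLUMNS, *LABEL_COLUMNS]]


def simulate_matrix(config: SimConfig) -> tuple[pd.DataFrame, Cohort, GroundTruth]:
    """Simulate a cohort and run it through feature extraction + labeling."""
    cohort, truth = simulate_cohort(config)
    return cohort_matrix(cohort), cohort, truth


def write_matrix(matrix: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a feature matrix CSV; provenance (e.g. config hash) goes into
    leading ``#`` comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        out = matrix.copy()
        out["date"] = pd.to_datetime(out["date"]).astype(str)
        out.to_csv(fh, index=False)


def read_matrix(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, dtype={"patient_id": str})
    df["date"] = pd.to_datetime(df["date"])
    return df, meta


def hams_lams_comparison(matrix: pd.DataFrame, cutoffs=(10, 30, 50)) -> pd.DataFrame:
    """Mean of each basic feature in the high- vs low-AMS day groups.

    For each cutoff c, HAMS(c) is the top c% of days by forward 3-day mean
    AMS and LAMS(c) the bottom c%; rows are restricted to complete feature
    rows with a forward AMS.
    """
    df = filter_complete_rows(matrix, log=False).dropna(subset=["fwd3_ams"])
    if len(df) == 0:
        raise ValueError("no complete rows with forward AMS available")
    vals = df["fwd3_ams"].to_numpy(dtype=float)
    rows = []
    for c in cutoffs:
        hi_thr = np.quantile(vals, 1.0 - c / 100.0)
        lo_thr = np.quantile(vals, c / 100.0)
        hams = df[df["fwd3_ams"] >= hi_thr]
        lams = df[df["fwd3_ams"] <= lo_thr]
        for b in BASIC_FEATURES:
            rows.append(
                {
                    "feature": b,
                    "cutoff_pct": c,
                    "hams_mean": float(hams[b].mean()),
                    "lams_mean": float(lams[b].mean()),
                    "hams_n": len(hams),
                    "lams_n": len(lams),
                }
            )
    return pd.DataFrame(rows)
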