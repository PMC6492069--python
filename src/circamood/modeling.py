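"""Random-forest mood prediction under rolling-origin evaluation.

A round at origin ``t`` trains on complete rows dated in ``[t-p, t]`` and
tests on rows dated in ``[t+1, t+q]``; ``t`` advances by ``step`` days
(default ``q``, i.e. non-overlapping test windows).  Reported metrics are
arithmetic means over rounds.  Mood-state labels are, by default, derived
per round from the *training window's* forward-AMS distribution so the
test window never informs the threshold; a global-reference mode derives
one threshold from the whole matrix instead.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_COLUMNS, FAMILIES, family_columns
from .labeling import BIASED, NEUTRAL, mood_state_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "RollingScheme",
    "RFConfig",
    "LabelSpec",
    "Metrics",
    "EvalRound",
    "EvalReport",
    "compute_metrics",
    "auc_score",
    "rolling_evaluate",
    "sweep_pq",
    "feature_importance_with_direction",
    "aggregate_importance_to_families",
    "ablate_family",
    "compare_general_personalized",
    "audit_no_leakage",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "auc")


@dataclass(frozen=True)
class RollingScheme:
    p: int  # training-window length, days
    q: int  # test-window length, days
    step: Optional[int] = None  # origin advance; defaults to q

    def __post_init__(self) -> None:
        if self.p < 1 or self.q < 1 or (self.step is not None and self.step < 1):
            raise ValueError("p, q and step must all be >= 1")

    @property
    def stride(self) -> int:
        return self.q if self.step is None else self.step


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 500
    max_features: str | float = "sqrt"
    class_weight: Optional[str] = None
    n_jobs: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            class_weight=self.class_weight,
            n_jobs=self.n_jobs,
            random_state=int(seed),
        )


@dataclass(frozen=True)
class LabelSpec:
    """What to predict.

    ``kind='mood_state'`` — 2-class biased/neutral at ``cutoff`` percent;
    ``kind='episode'``    — 4-class forest, one-vs-rest metrics for ``target``.
    """

    kind: str = "mood_state"
    cutoff: float = 50
    target: str = "DE"
    global_reference: bool = False
    #: exclude the last ``embargo`` days of each training window, whose
    #: forward 3-day labels are not yet observable at the round origin (and
    #: would share mood scores with the test window).  ``None`` = label
    #: horizon for mood_state, 0 for episode labels; 0 reproduces the
    #: verbatim [t-p, t] window.
    embargo: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("mood_state", "episode"):
            raise ValueError(f"unknown label kind {self.kind!r}")

    @property
    def effective_embargo(self) -> int:
        if self.embargo is not None:
            return int(self.embargo)
        return 3 if self.kind == "mood_state" else 0


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    n_test: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "n_test": self.n_test,
        }


@dataclass
class EvalRound:
    t: object  # origin date
    train_start: object
    train_end: object
    test_start: object
    test_end: object
    n_train: int
    metrics: Metrics


@dataclass
class EvalReport:
    scheme: RollingScheme
    label: LabelSpec
    rounds: list = field(default_factory=list)
    skipped: int = 0

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(r.metrics, name) for r in self.rounds], dtype=float)

    def mean(self, name: str) -> float:
        vals = self.metric_values(name)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    def sd(self, name: str) -> float:
        vals = self.metric_values(name)
        vals = vals[np.isfinite(vals)]
        return float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")

    def summary(self) -> dict:
        return {
            "scheme": {"p": self.scheme.p, "q": self.scheme.q, "step": self.scheme.stride},
            "label": {"kind": self.label.kind, "cutoff": self.label.cutoff, "target": self.label.target},
            "n_rounds": self.n_rounds,
            "skipped_rounds": self.skipped,
            "means": {m: self.mean(m) for m in METRIC_NAMES},
            "sds": {m: self.sd(m) for m in METRIC_NAMES},
        }

    def to_json_dict(self) -> dict:
        out = self.summary()
        out["rounds"] = [
            {
                "t": str(r.t),
                "train": [str(r.train_start), str(r.train_end)],
                "test": [str(r.test_start), str(r.test_end)],
                "n_train": r.n_train,
                **{k: (None if v is None or (isinstance(v, float) and not np.isfinite(v)) else v) for k, v in r.metrics.as_dict().items()},
            }
            for r in self.rounds
        ]
        return out


class EmptyReportError(RuntimeError):
    """No evaluation round could be formed from the data."""


# ---------------------------------------------------------------------------
# metrics

def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank statistic (Mann-Whitney), ties counted half."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(y_true, y_pred, scores, positive) -> Metrics:
    """Confusion-matrix metrics plus rank-based AUC for one test window.

    ``scores`` are positive-class probabilities; for multiclass problems the
    caller merges everything outside ``positive`` into one rest class.
    """
    yt = np.asarray(y_true) == positive
    yp = np.asarray(y_pred) == positive
    n = len(yt)
    if n == 0:
        raise ValueError("empty test window")
    tp = int((yt & yp).sum())
    tn = int((~yt & ~yp).sum())
    fp = int((~yt & yp).sum())
    fn = int((yt & ~yp).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n
    return Metrics(sens, spec, acc, auc_score(yt, scores), n)


# ---------------------------------------------------------------------------
# rolling evaluation

def _round_seed(global_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(global_seed), int(index)]).generate_state(1)[0] % (2**31 - 1))


def _prepare(matrix: pd.DataFrame, feature_cols: Sequence[str]) -> pd.DataFrame:
    df = matrix.reset_index() if "date" not in matrix.columns else matrix.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date", kind="mergesort").reset_index(drop=True)
    complete = df[list(feature_cols)].notna().all(axis=1)
    return df.loc[complete].reset_index(drop=True)


def _mood_state_vectors(train: pd.DataFrame, test: pd.DataFrame, label: LabelSpec, full: pd.DataFrame):
    ref = full["fwd3_ams"] if label.global_reference else train["fwd3_ams"]
    ref = ref.dropna()
    if len(ref) == 0:
        return None
    thr = mood_state_threshold(ref, label.cutoff)
    tr = train.dropna(subset=["fwd3_ams"])
    te = test.dropna(subset=["fwd3_ams"])
    y_tr = np.where(tr["fwd3_ams"] >= thr, BIASED, NEUTRAL)
    y_te = np.where(te["fwd3_ams"] >= thr, BIASED, NEUTRAL)
    return tr, te, y_tr, y_te, BIASED


def _episode_vectors(train: pd.DataFrame, test: pd.DataFrame, label: LabelSpec):
    tr = train.dropna(subset=["episode"])
    te = test.dropna(subset=["episode"])
    return tr, te, tr["episode"].to_numpy(), te["episode"].to_numpy(), label.target


def rolling_evaluate(
    matrix: pd.DataFrame,
    scheme: RollingScheme,
    label: LabelSpec = LabelSpec(),
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> EvalReport:
    """Evaluate a random forest over every rolling-origin round.

    ``matrix`` is a labeled feature matrix (possibly pooling patients) with
    ``date``, the feature columns, and ``fwd3_ams`` / ``episode`` label
    inputs.  Rounds whose training window is empty or single-class are
    skipped and counted, not zero-filled.
    """
    feature_cols = list(feature_cols)
    if not feature_cols:
        raise ValueError("no predictor columns")
    df = _prepare(matrix, feature_cols)
    if len(df) == 0:
        raise EmptyReportError("no complete rows to evaluate")
    dmin, dmax = df["date"].min(), df["date"].max()
    report = EvalReport(scheme=scheme, label=label)
    t = dmin + pd.Timedelta(days=scheme.p)
    index = 0
    while t + pd.Timedelta(days=scheme.q) <= dmax:
        origin = t
        tr_lo = t - pd.Timedelta(days=scheme.p)
        tr_hi = t - pd.Timedelta(days=label.effective_embargo)
        te_lo, te_hi = t + pd.Timedelta(days=1), t + pd.Timedelta(days=scheme.q)
        train = df[(df["date"] >= tr_lo) & (df["date"] <= tr_hi)]
        test = df[(df["date"] >= te_lo) & (df["date"] <= te_hi)]
        index += 1
        t = t + pd.Timedelta(days=scheme.stride)
        if len(train) == 0 or len(test) == 0:
            report.skipped += 1
            continue
        vecs = (
            _mood_state_vectors(train, test, label, df)
            if label.kind == "mood_state"
            else _episode_vectors(train, test, label)
        )
        if vecs is None:
            report.skipped += 1
            continue
        tr, te, y_tr, y_te, positive = vecs
        if len(tr) == 0 or len(te) == 0 or len(np.unique(y_tr)) < 2 or positive not in y_tr:
            report.skipped += 1
            continue
        model = rf.build(_round_seed(seed, index))
        model.fit(tr[feature_cols].to_numpy(), y_tr)
        X_te = te[feature_cols].to_numpy()
        y_pred = model.predict(X_te)
        pos_idx = list(model.classes_).index(positive)
        scores = model.predict_proba(X_te)[:, pos_idx]
        m = compute_metrics(y_te, y_pred, scores, positive)
        report.rounds.append(
            EvalRound(
                t=origin.date(),
                train_start=tr["date"].min().date(),
                train_end=tr["date"].max().date(),
                test_start=te["date"].min().date(),
                test_end=te["date"].max().date(),
                n_train=len(tr),
                metrics=m,
            )
        )
    if report.n_rounds == 0:
        raise EmptyReportError(
            f"no valid evaluation round for scheme p={scheme.p}, q={scheme.q} ({report.skipped} skipped)"
        )
    audit_no_leakage(report)
    return report


def audit_no_leakage(report: EvalReport) -> None:
    """Assert max(train dates) < min(test dates) in every round."""
    for r in report.rounds:
        if not r.train_end < r.test_start:
            raise AssertionError(
                f"temporal leakage: train ends {r.train_end}, test starts {r.test_start}"
            )


def sweep_pq(
    matrix: pd.DataFrame,
    p_values: Sequence[int],
    q_values: Sequence[int],
    label: LabelSpec = LabelSpec(),
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    criterion: str = "accuracy",
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> tuple[dict, tuple[int, int]]:
    """Evaluate every (p, q) on the grid; return the reports and the pair
    maximizing the mean of ``criterion`` (ties go to the first pair in
    iteration order)."""
    grid: dict[tuple[int, int], EvalReport] = {}
    best, best_val = None, -np.inf
    for p in p_values:
        for q in q_values:
            try:
                rep = rolling_evaluate(matrix, RollingScheme(p=p, q=q), label, rf, seed, feature_cols)
            except EmptyReportError:
                continue
            grid[(p, q)] = rep
            val = rep.mean(criterion)
            if np.isfinite(val) and val > best_val:
                best, best_val = (p, q), val
    if best is None:
        raise EmptyReportError("no (p, q) pair produced a valid report")
    return grid, best


# ---------------------------------------------------------------------------
# importance / ablation / personalization

def feature_importance_with_direction(
    model: RandomForestClassifier,
    matrix: pd.DataFrame,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
    ams_col: str = "ams",
    undirected_below: float = 0.1,
) -> pd.DataFrame:
    """Impurity importances (normalized to sum 1) with the sign of each
    feature's Pearson correlation against AMS; |r| < 0.1 is 'undirected'."""
    feature_cols = list(feature_cols)
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    rows = []
    df = matrix.dropna(subset=[ams_col])
    ams = df[ams_col].to_numpy(dtype=float)
    for name, w in zip(feature_cols, imp):
        x = df[name].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(ams)
        r = float("nan")
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(ams[ok]) > 0:
            r = float(np.corrcoef(x[ok], ams[ok])[0, 1])
        if not np.isfinite(r) or abs(r) < undirected_below:
            direction = "undirected"
        else:
            direction = "positive" if r > 0 else "negative"
        rows.append({"feature": name, "importance": float(w), "pearson_r": r, "direction": direction})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def aggregate_importance_to_families(importance: pd.DataFrame) -> pd.DataFrame:
    """Sum member importances up to the 13 basic-feature families."""
    from .features import BASIC_FEATURES

    def basic_of(name: str) -> str:
        for b in sorted(BASIC_FEATURES, key=len, reverse=True):
            if name == b or name.startswith(b + "_"):
                return b
        raise KeyError(name)

    df = importance.copy()
    df["basic"] = df["feature"].map(basic_of)
    agg = df.groupby("basic", sort=False)["importance"].sum().reset_index()
    return agg.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class AblationResult:
    family: str
    full: EvalReport
    ablated: EvalReport

    @property
    def auc_delta(self) -> float:
        return self.ablated.mean("auc") - self.full.mean("auc")


def ablate_family(
    matrix: pd.DataFrame,
    family: str,
    scheme: RollingScheme,
    label: LabelSpec = LabelSpec(),
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    full_report: Optional[EvalReport] = None,
) -> AblationResult:
    """Re-evaluate with one sensor family's columns removed and report the
    AUC delta versus the full model."""
    if family not in FAMILIES:
        raise KeyError(f"unknown feature family {family!r}; expected one of {sorted(FAMILIES)}")
    dropped = set(family_columns(family))
    remaining = [c for c in FEATURE_COLUMNS if c not in dropped]
    if not remaining:
        raise ValueError("ablation leaves no predictors")
    if full_report is None:
        full_report = rolling_evaluate(matrix, scheme, label, rf, seed)
    ablated = rolling_evaluate(matrix, scheme, label, rf, seed, feature_cols=remaining)
    return AblationResult(family=family, full=full_report, ablated=ablated)


def compare_general_personalized(
    matrices: dict,
    scheme: RollingScheme,
    label: LabelSpec = LabelSpec(),
    rf: RFConfig = RFConfig(),
    seed: int = 0,
    min_rounds: int = 1,
) -> pd.DataFrame:
    """Per-patient comparison of a personalized model (the patient's own
    rolling windows) against a general model (one forest trained on all
    *other* patients' complete rows, evaluated on the same test windows).

    Returns one row per evaluable patient with mean accuracies and the
    personalized-minus-general advantage; patients without enough rounds
    are skipped with a log entry.
    """
    if len(matrices) < 2:
        raise ValueError("general model undefined with fewer than 2 patients")
    feature_cols = list(FEATURE_COLUMNS)
    prepared = {pid: _prepare(m, feature_cols) for pid, m in matrices.items()}
    rows = []
    for pid, own in prepared.items():
        try:
            personal = rolling_evaluate(own, scheme, label, rf, seed)
        except EmptyReportError:
            logger.info("patient %s skipped: too few rows for personalized rounds", pid)
            continue
        if personal.n_rounds < min_rounds:
            logger.info("patient %s skipped: only %d rounds", pid, personal.n_rounds)
            continue

        others = pd.concat([m for q, m in prepared.items() if q != pid], ignore_index=True)
        if label.kind == "mood_state":
            tr = others.dropna(subset=["fwd3_ams"])
            thr = mood_state_threshold(tr["fwd3_ams"], label.cutoff)
            y_tr = np.where(tr["fwd3_ams"] >= thr, BIASED, NEUTRAL)
            positive = BIASED
        else:
            tr = others.dropna(subset=["episode"])
            y_tr = tr["episode"].to_numpy()
            thr = None
            positive = label.target
        if len(np.unique(y_tr)) < 2 or positive not in y_tr:
            logger.info("patient %s skipped: general training data single-class", pid)
            continue
        gen_model = rf.build(_round_seed(seed, zlib.crc32(pid.encode()) % 10_000))
        gen_model.fit(tr[feature_cols].to_numpy(), y_tr)

        gen_accs = []
        for rnd in personal.rounds:
            te = own[(own["date"] >= pd.Timestamp(rnd.test_start)) & (own["date"] <= pd.Timestamp(rnd.test_end))]
            if label.kind == "mood_state":
                te = te.dropna(subset=["fwd3_ams"])
                y_te = np.where(te["fwd3_ams"] >= thr, BIASED, NEUTRAL)
            else:
                te = te.dropna(subset=["episode"])
                y_te = te["episode"].to_numpy()
            if len(te) == 0:
                continue
            y_pred = gen_model.predict(te[feature_cols].to_numpy())
            gen_accs.append(float((np.asarray(y_pred) == y_te).mean()))
        if not gen_accs:
            continue
        rows.append(
            {
                "patient_id": pid,
                "n_rounds": personal.n_rounds,
                "personalized_accuracy": personal.mean("accuracy"),
                "general_accuracy": float(np.mean(gen_accs)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["advantage"] = out["personalized_accuracy"] - out["general_accuracy"]
    return out
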