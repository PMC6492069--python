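import numpy as np
import pandas as pd
import pytest

from circamood.features import FEATURE_COLUMNS
from circamood.labeling import BIASED, NEUTRAL, mood_state_threshold
from circamood.modeling import (
    AblationResult,
    EmptyReportError,
    LabelSpec,
    Metrics,
    RFConfig,
    RollingScheme,
    ablate_family,
    aggregate_importance_to_families,
    audit_no_leakage,
    auc_score,
    compare_general_personalized,
    compute_metrics,
    feature_importance_with_direction,
    rolling_evaluate,
    sweep_pq,
)

FAST_RF = RFConfig(n_estimators=30)


# ---------------------------------------------------------------------------
# metrics

def test_confusion_arithmetic():
    y_true = np.array([1] * 10 + [0] * 10)
    y_pred = np.array([1] * 9 + [0] + [1] * 2 + [0] * 8)
    scores = y_pred.astype(float)
    m = compute_metrics(y_true, y_pred, scores, positive=1)
    assert m.sensitivity == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.8)
    assert m.accuracy == pytest.approx(0.85)
    assert m.n_test == 20


def test_perfect_separation_auc():
    y = np.array([0, 0, 1, 1])
    s = np.array([0.1, 0.2, 0.8, 0.9])
    assert auc_score(y, s) == 1.0


def test_auc_single_class_missing():
    assert np.isnan(auc_score(np.array([1, 1]), np.array([0.5, 0.6])))


def brute_force_auc(y, s):
    """Pairwise-comparison oracle: ties count half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("n,seed", [(50, 0), (200, 1)])
def test_auc_equals_pairwise_oracle(n, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    y[0], y[1] = 0, 1  # both classes present
    s = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
    assert auc_score(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)


def test_rolling_scheme_validation():
    with pytest.raises(ValueError):
        RollingScheme(p=0, q=3)
    assert RollingScheme(p=18, q=3).stride == 3
    assert RollingScheme(p=18, q=3, step=5).stride == 5


# ---------------------------------------------------------------------------
# rolling evaluation

def test_rolling_audit_and_round_count(small_sim):
    _, matrix, _, _ = small_sim
    scheme = RollingScheme(p=18, q=3, step=3)
    rep = rolling_evaluate(matrix, scheme, LabelSpec(), FAST_RF, seed=0)
    audit_no_leakage(rep)  # raises on violation
    for r in rep.rounds:
        assert r.train_end < r.test_start

    # independent enumeration of candidate origins over the complete-row span
    df = matrix.dropna(subset=list(FEATURE_COLUMNS)).copy()
    df["date"] = pd.to_datetime(df["date"])
    dmin, dmax = df["date"].min(), df["date"].max()
    candidates = 0
    t = dmin + pd.Timedelta(days=scheme.p)
    while t + pd.Timedelta(days=scheme.q) <= dmax:
        candidates += 1
        t += pd.Timedelta(days=scheme.step)
    assert rep.n_rounds + rep.skipped == candidates


def test_round_count_enumeration_30_days(small_sim):
    # 30 days of one patient, p=18, q=3, step=3
    _, matrix, _, _ = small_sim
    one = matrix[matrix["patient_id"] == matrix["patient_id"].iloc[0]].copy()
    one["date"] = pd.to_datetime(one["date"])
    complete = one.dropna(subset=list(FEATURE_COLUMNS))
    start = complete["date"].min()
    window = complete[complete["date"] < start + pd.Timedelta(days=30)]
    scheme = RollingScheme(p=18, q=3, step=3)
    rep = rolling_evaluate(window, scheme, LabelSpec(), FAST_RF, seed=0)
    dmin, dmax = window["date"].min(), window["date"].max()
    expected = 0
    t = dmin + pd.Timedelta(days=18)
    while t + pd.Timedelta(days=3) <= dmax:
        expected += 1
        t += pd.Timedelta(days=3)
    assert rep.n_rounds + rep.skipped == expected
    assert rep.n_rounds >= 1


def test_rolling_deterministic(small_sim):
    _, matrix, _, _ = small_sim
    a = rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=9)
    b = rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=9)
    assert a.summary() == b.summary()


def test_permuted_labels_null(small_sim):
    _, matrix, _, _ = small_sim
    rng = np.random.default_rng(13)
    aucs = []
    for seed in range(3):
        shuffled = matrix.copy()
        vals = shuffled["fwd3_ams"].to_numpy().copy()
        rng.shuffle(vals)
        shuffled["fwd3_ams"] = vals
        rep = rolling_evaluate(shuffled, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=seed)
        aucs.extend(rep.metric_values("auc"))
    a = np.array(aucs)
    a = a[np.isfinite(a)]
    ci = 1.96 * a.std(ddof=1) / np.sqrt(len(a))
    assert abs(a.mean() - 0.5) < max(ci, 0.1)


def test_empty_matrix_errors():
    empty = pd.DataFrame(columns=["patient_id", "date", *FEATURE_COLUMNS, "fwd3_ams", "episode", "mood_score", "ams"])
    with pytest.raises(EmptyReportError):
        rolling_evaluate(empty, RollingScheme(18, 3), LabelSpec(), FAST_RF)


def test_no_predictors_errors(small_sim):
    _, matrix, _, _ = small_sim
    with pytest.raises(ValueError, match="predictor"):
        rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(), FAST_RF, feature_cols=[])


def test_embargo_default_and_override(small_sim):
    _, matrix, _, _ = small_sim
    assert LabelSpec().effective_embargo == 3
    assert LabelSpec(kind="episode").effective_embargo == 0
    rep = rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(embargo=0), FAST_RF, seed=0)
    for r in rep.rounds:
        assert r.train_end < r.test_start  # leakage audit still holds on dates


def test_episode_one_vs_rest(small_sim):
    _, matrix, _, _ = small_sim
    target = None
    for cand in ("DE", "ME", "HME"):
        if (matrix["episode"] == cand).sum() >= 10:
            target = cand
            break
    if target is None:
        pytest.skip("no episode days in this cohort draw")
    try:
        rep = rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(kind="episode", target=target), FAST_RF, seed=0)
    except EmptyReportError:
        pytest.skip("no round with the target class in training")
    assert rep.n_rounds >= 1
    for m in ("sensitivity", "specificity", "accuracy"):
        v = rep.mean(m)
        assert np.isnan(v) or 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# sweep

def test_sweep_single_pair_argmax(small_sim):
    _, matrix, _, _ = small_sim
    grid, best = sweep_pq(matrix, [18], [3], LabelSpec(), FAST_RF, seed=0)
    assert best == (18, 3)
    assert set(grid) == {(18, 3)}


def test_sweep_deterministic(small_sim):
    _, matrix, _, _ = small_sim
    g1, b1 = sweep_pq(matrix, [12, 18], [3], LabelSpec(), FAST_RF, seed=4)
    g2, b2 = sweep_pq(matrix, [12, 18], [3], LabelSpec(), FAST_RF, seed=4)
    assert b1 == b2
    for k in g1:
        assert g1[k].summary() == g2[k].summary()


# ---------------------------------------------------------------------------
# importance

def _importance_setup(small_sim):
    _, matrix, _, _ = small_sim
    df = matrix.dropna(subset=list(FEATURE_COLUMNS) + ["fwd3_ams", "ams"]).copy()
    thr = mood_state_threshold(df["fwd3_ams"], 50)
    y = np.where(df["fwd3_ams"] >= thr, BIASED, NEUTRAL)
    model = FAST_RF.build(0)
    model.fit(df[list(FEATURE_COLUMNS)].to_numpy(), y)
    return df, model


def test_importance_sums_to_one(small_sim):
    df, model = _importance_setup(small_sim)
    imp = feature_importance_with_direction(model, df)
    assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
    assert (imp["importance"] >= 0).all()
    assert len(imp) == 130


def test_importance_direction_rules(small_sim):
    df, model = _importance_setup(small_sim)
    # plant a feature identical to AMS and one with |r| = 0.05 exactly
    df = df.copy()
    z = (df["ams"] - df["ams"].mean()).to_numpy()
    z = z / np.linalg.norm(z)
    rng = np.random.default_rng(0)
    w = rng.normal(size=len(z))
    w -= w @ z * z
    w /= np.linalg.norm(w)
    df["steps_during_bedtime"] = df["ams"]
    df["steps_during_daytime"] = 0.05 * z + np.sqrt(1 - 0.05**2) * w
    imp = feature_importance_with_direction(model, df)
    by_name = imp.set_index("feature")
    assert by_name.loc["steps_during_bedtime", "direction"] == "positive"
    assert by_name.loc["steps_during_bedtime", "pearson_r"] == pytest.approx(1.0)
    assert by_name.loc["steps_during_daytime", "direction"] == "undirected"
    assert abs(by_name.loc["steps_during_daytime", "pearson_r"]) < 0.1


def test_importance_constant_feature_undirected(small_sim):
    df, model = _importance_setup(small_sim)
    df = df.copy()
    df["sleep_length"] = 7.0
    imp = feature_importance_with_direction(model, df).set_index("feature")
    assert imp.loc["sleep_length", "direction"] == "undirected"


def test_importance_family_aggregation(small_sim):
    df, model = _importance_setup(small_sim)
    imp = feature_importance_with_direction(model, df)
    agg = aggregate_importance_to_families(imp)
    assert len(agg) == 13
    assert agg["importance"].sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# ablation

def test_ablation_column_arithmetic(small_sim):
    _, matrix, _, _ = small_sim
    full = rolling_evaluate(matrix, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=0)
    res = ablate_family(matrix, "steps", RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=0, full_report=full)
    assert isinstance(res, AblationResult)
    assert np.isfinite(res.auc_delta)


def test_ablation_unknown_family(small_sim):
    _, matrix, _, _ = small_sim
    with pytest.raises(KeyError):
        ablate_family(matrix, "gps", RollingScheme(18, 3))


# ---------------------------------------------------------------------------
# general vs personalized

def test_compare_requires_two_patients(small_sim):
    _, matrix, _, _ = small_sim
    pid = matrix["patient_id"].iloc[0]
    solo = {pid: matrix[matrix["patient_id"] == pid]}
    with pytest.raises(ValueError):
        compare_general_personalized(solo, RollingScheme(18, 3))


def test_compare_outputs_table(small_sim):
    _, matrix, _, _ = small_sim
    per = {pid: g for pid, g in matrix.groupby("patient_id")}
    table = compare_general_personalized(per, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=0)
    assert {"patient_id", "personalized_accuracy", "general_accuracy", "advantage"} <= set(table.columns)
    assert len(table) >= 1
    assert table["personalized_accuracy"].between(0, 1).all()
    assert table["general_accuracy"].between(0, 1).all()


def test_compare_identical_patients_symmetric(small_sim):
    _, matrix, _, _ = small_sim
    pid = matrix["patient_id"].iloc[0]
    own = matrix[matrix["patient_id"] == pid]
    twin_a = own.copy()
    twin_b = own.copy()
    twin_b["patient_id"] = "TWIN"
    table = compare_general_personalized(
        {pid: twin_a, "TWIN": twin_b}, RollingScheme(18, 3), LabelSpec(), FAST_RF, seed=0
    )
    if len(table) == 2:
        accs = table.set_index("patient_id")["personalized_accuracy"]
        assert accs.iloc[0] == pytest.approx(accs.iloc[1], abs=1e-12)
        gen = table.set_index("patient_id")["general_accuracy"]
        assert gen.iloc[0] == pytest.approx(gen.iloc[1], abs=0.15)
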