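"""Diagnostic models: marker selection, cross-validated scoring, ridge
combination, cutoff rule, evaluation metrics, stage association."""

import numpy as np
import pandas as pd
import pytest

from cfmeth import (
    association_with_stage,
    evaluate,
    select_cutoff,
    select_markers,
    train_cfmeth,
    train_combined,
)


def synthetic_profiles(n=120, n_markers=12, signal=0.15, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.normal(0.05, 0.03, (n, n_markers)).clip(0, 1)
    X[y == 1, : n_markers // 2] += signal  # first half of markers informative
    cols = [f"chr1:{1000 * i}-{1000 * i + 500}" for i in range(n_markers)]
    return pd.DataFrame(X, columns=cols), np.where(y == 1, "malignant", "benign")


# ---------------------------------------------------------------- selection

def test_select_markers_returns_k_best():
    X, y = synthetic_profiles()
    picked = select_markers(X, y, k=10)
    assert len(picked) == 10
    informative = set(X.columns[:6])
    assert informative <= set(picked)
    with pytest.raises(ValueError):
        select_markers(X, y, k=X.shape[1] + 1)


def test_perfectly_separating_marker_ranked_first():
    X, y = synthetic_profiles(signal=0.0)
    X["perfect"] = (y == "malignant").astype(float)
    assert select_markers(X, y, k=1) == ["perfect"]


def test_marker_selection_unstable_under_label_permutation():
    X, y = synthetic_profiles(signal=0.0, seed=3)
    rng = np.random.default_rng(4)
    hits = {}
    for _ in range(20):
        perm = rng.permutation(len(y))
        for m in select_markers(X, y[perm], k=3):
            hits[m] = hits.get(m, 0) + 1
    assert max(hits.values()) <= 0.6 * 20  # no marker is stably "optimal" on noise


# ------------------------------------------------------------------- cfMeth

def test_out_of_fold_bookkeeping_and_determinism():
    X, y = synthetic_profiles(seed=5)
    m1 = train_cfmeth(X, y, n_folds=10, seed=7)
    m2 = train_cfmeth(X, y, n_folds=10, seed=7)
    assert m1.oof_scores.index.equals(X.index)
    assert not m1.oof_scores.isna().any()
    assert np.array_equal(m1.oof_scores.values, m2.oof_scores.values)
    assert np.all((m1.oof_scores >= 0) & (m1.oof_scores <= 1))


def test_separable_profiles_score_near_perfectly():
    from sklearn.metrics import roc_auc_score

    X, y = synthetic_profiles(signal=0.6, seed=6)
    model = train_cfmeth(X, y, n_folds=10, seed=1)
    assert roc_auc_score(y == "malignant", model.oof_scores) >= 0.99


def test_stratification_requires_enough_per_class():
    X, y = synthetic_profiles(n=12)
    with pytest.raises(ValueError):
        train_cfmeth(X, y, n_folds=10, seed=0)


# ----------------------------------------------------------------- combined

def combined_inputs(signal_imaging, n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["malignant"] * (n // 2) + ["benign"] * (n // 2))
    cf = pd.Series(
        np.clip(rng.normal(0.0, 0.15, n) + 0.35 * (y == "malignant"), 0, 1),
        index=[f"s{i}" for i in range(n)], name="cfmeth_score",
    )
    records = pd.DataFrame(
        {
            "mammography_score": np.clip(np.rint(
                2.2 + signal_imaging * (y == "malignant") + rng.normal(0, 1, n)), 1, 5),
            "ultrasound_score": np.clip(np.rint(
                2.2 + signal_imaging * (y == "malignant") + rng.normal(0, 1, n)), 1, 5),
        },
        index=cf.index,
    )
    return cf, records, y


def test_noise_imaging_leaves_cfmeth_auc_intact():
    from sklearn.metrics import roc_auc_score
    from cfmeth import combine_features

    cf, records, y = combined_inputs(signal_imaging=0.0, seed=1)
    model = train_combined(combine_features(cf, records), y, seed=1)
    auc_cf = roc_auc_score(y == "malignant", cf)
    auc_comb = roc_auc_score(y == "malignant", model.oof_scores)
    assert abs(auc_comb - auc_cf) <= 0.03
    assert np.all((model.oof_scores >= 0) & (model.oof_scores <= 1))


def test_informative_imaging_improves_on_both_sources():
    from sklearn.metrics import roc_auc_score
    from cfmeth import combine_features

    cf, records, y = combined_inputs(signal_imaging=1.2, seed=2)
    model = train_combined(combine_features(cf, records), y, seed=2)
    yb = y == "malignant"
    singles = [
        roc_auc_score(yb, cf),
        roc_auc_score(yb, records["mammography_score"]),
        roc_auc_score(yb, records["ultrasound_score"]),
    ]
    assert roc_auc_score(yb, model.oof_scores) >= max(singles) - 0.01


def test_constant_feature_dropped_with_warning():
    from cfmeth import combine_features

    cf, records, y = combined_inputs(signal_imaging=1.0, seed=3)
    records["ultrasound_score"] = 3
    with pytest.warns(UserWarning, match="constant"):
        model = train_combined(combine_features(cf, records), y, seed=3)
    assert "ultrasound_score" not in model.feature_names


# ------------------------------------------------------------------- cutoff

def test_cutoff_on_separated_scores_has_zero_fnr():
    scores = np.array([0.9, 0.8, 0.85, 0.1, 0.2, 0.15])
    labels = ["malignant"] * 3 + ["benign"] * 3
    t = select_cutoff(scores, labels, max_fnr=0.02)
    fnr = np.mean(np.array(scores[:3]) < t)
    assert fnr == 0.0 and t <= 0.8


def test_cutoff_zero_bound_sits_below_lowest_positive():
    rng = np.random.default_rng(0)
    scores = rng.random(50)
    labels = np.where(rng.random(50) < 0.5, "malignant", "benign")
    t = select_cutoff(scores, labels, max_fnr=0.0)
    assert t <= scores[labels == "malignant"].min()


def test_cutoff_postcondition_holds_on_random_scores():
    rng = np.random.default_rng(1)
    for trial in range(10):
        scores = rng.random(80)
        labels = np.where(rng.random(80) < 0.5, "malignant", "benign")
        t = select_cutoff(scores, labels, max_fnr=0.02)
        pos = scores[labels == "malignant"]
        assert np.mean(pos < t) < 0.02
    with pytest.raises(ValueError):
        select_cutoff(scores, labels, max_fnr=1.0)


# --------------------------------------------------------------- evaluation

def test_perfect_classifier_metrics():
    scores = np.array([0.9] * 10 + [0.1] * 10)
    labels = ["malignant"] * 10 + ["benign"] * 10
    r = evaluate(scores, labels, threshold=0.5, n_boot=200, seed=0)
    assert r.auc == 1.0
    assert r.sensitivity == r.specificity == r.accuracy == 1.0
    assert (r.tp, r.fp, r.tn, r.fn) == (10, 0, 10, 0)


def test_null_scores_give_chance_auc():
    rng = np.random.default_rng(2)
    in_band = 0
    for trial in range(20):
        scores = rng.random(200)
        labels = ["malignant"] * 100 + ["benign"] * 100
        r = evaluate(scores, labels, threshold=0.5, n_boot=50, seed=trial)
        in_band += 0.40 <= r.auc <= 0.60
        assert r.tp + r.fp + r.tn + r.fn == 200
    assert in_band >= 19


def test_bootstrap_ci_contains_point_estimate():
    rng = np.random.default_rng(3)
    for trial in range(5):
        n = 60
        labels = ["malignant"] * 30 + ["benign"] * 30
        scores = rng.random(n) + 0.3 * (np.arange(n) < 30)
        r = evaluate(scores, labels, threshold=0.5, n_boot=500, seed=trial)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]


def test_metrics_invariant_to_sample_order():
    rng = np.random.default_rng(4)
    scores = rng.random(100) + 0.4 * (np.arange(100) < 50)
    labels = np.array(["malignant"] * 50 + ["benign"] * 50)
    stages = np.array(["I"] * 25 + ["II"] * 25 + [""] * 50)
    a = evaluate(scores, labels, 0.6, stages=stages, n_boot=10, seed=0)
    perm = rng.permutation(100)
    b = evaluate(scores[perm], labels[perm], 0.6, stages=stages[perm], n_boot=10, seed=0)
    assert a.auc == b.auc and a.confusion == b.confusion
    assert a.stage_detection == b.stage_detection


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        evaluate([0.2, 0.4], ["benign", "benign"], 0.5, n_boot=10)


def test_per_stage_detection_fractions():
    scores = np.array([0.9, 0.9, 0.1, 0.9, 0.1, 0.1])
    labels = ["malignant"] * 4 + ["benign"] * 2
    stages = ["I", "I", "II", "II", None, None]
    r = evaluate(scores, labels, 0.5, stages=stages, n_boot=10)
    assert r.stage_detection == {"I": 1.0, "II": 0.5}


# ---------------------------------------------------------- stage trend

def test_stage_association_signs_and_degenerate_cases():
    stages = ["I"] * 5 + ["II"] * 5 + ["III"] * 5
    rising = np.concatenate([np.full(5, 0.2), np.full(5, 0.5), np.full(5, 0.8)])
    up = association_with_stage(rising, stages)
    down = association_with_stage(-rising, stages)
    assert up.statistic > 0
    assert down.statistic == pytest.approx(-up.statistic)
    flat = association_with_stage(np.full(15, 0.4), stages)
    assert flat.statistic == 0.0
    with pytest.raises(ValueError):
        association_with_stage([0.1, 0.2, 0.3], ["I", "I", "I"])
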