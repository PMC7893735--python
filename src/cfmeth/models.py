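"""Diagnostic modelling on marker profiles.

The cfMeth score is the out-of-fold malignancy probability of a random
forest trained on the selected per-DMR malignant ratios with stratified
10-fold cross-validation; discovery samples are each scored exactly once by
a model that never saw them, and a final refit is applied to held-out
cohorts.  The combined model adds the two ordinal imaging scores
(mammography, ultrasound) through an L2-penalized (ridge) logistic
regression with an internally cross-validated penalty.  The operating
threshold is chosen on discovery scores as the largest cutoff whose
false-negative rate stays strictly below a bound (default 2%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

MALIGNANT = "malignant"
STAGE_ORDER = {"0": 0, "DCIS": 0, "I": 1, "II": 2, "III": 3}


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biu" or y.dtype == bool:
        return y.astype(int)
    return (y == MALIGNANT).astype(int)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def select_markers(ratios: pd.DataFrame, labels, k: int = 10) -> list[str]:
    """Top-k DMR markers by single-marker AUC of malignant ratio vs label.

    Ties broken by rank-test p-value, then by DMR id; discovery labels only.
    """
    if k > ratios.shape[1]:
        raise ValueError(f"k={k} exceeds the {ratios.shape[1]} candidate markers")
    y = _as_binary(labels)
    scored = []
    for col in ratios.columns:
        x = ratios[col].to_numpy(float)
        auc = roc_auc_score(y, x)
        pos, neg = x[y == 1], x[y == 0]
        if np.all(x == x[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
        scored.append((-auc, p, str(col)))
    scored.sort()
    return [name for _, _, name in scored[:k]]


# ---------------------------------------------------------------------------
# cfMeth score
# ---------------------------------------------------------------------------

@dataclass
class CfMethModel:
    """Out-of-fold discovery scores plus the refit model for held-out data."""

    oof_scores: pd.Series  # cfMeth score per discovery sample
    model: RandomForestClassifier  # refit on all discovery data
    markers: list[str]

    def score(self, ratios: pd.DataFrame) -> pd.Series:
        """Apply the refit model (no labels involved)."""
        X = ratios[self.markers].to_numpy(float)
        return pd.Series(self.model.predict_proba(X)[:, 1], index=ratios.index,
                         name="cfmeth_score")


def train_cfmeth(
    ratios: pd.DataFrame,
    labels,
    markers: Sequence[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> CfMethModel:
    """Random-forest cfMeth score with stratified out-of-fold prediction.

    Every discovery sample is scored exactly once, by a forest not trained
    on it; a final forest refit on the full discovery set serves validation.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    markers = list(markers) if markers is not None else list(ratios.columns)
    X = ratios[markers].to_numpy(float)
    y = _as_binary(labels)
    if min(np.sum(y == 1), np.sum(y == 0)) < n_folds:
        raise ValueError("each class needs at least n_folds samples for stratified CV")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = cross_val_predict(rf, X, y, cv=cv, method="predict_proba")[:, 1]
    final = clone(rf).fit(X, y)
    return CfMethModel(
        oof_scores=pd.Series(oof, index=ratios.index, name="cfmeth_score"),
        model=final, markers=markers,
    )


# ---------------------------------------------------------------------------
# combined model (cfMeth + imaging)
# ---------------------------------------------------------------------------

@dataclass
class CombinedModel:
    """Ridge-logistic combination of cfMeth and imaging scores."""

    oof_scores: pd.Series  # out-of-fold combined score per discovery sample
    model: Pipeline  # scaler + LogisticRegressionCV refit on discovery
    feature_names: list[str]
    coefficients: pd.Series

    def score(self, features: pd.DataFrame) -> pd.Series:
        X = features[self.feature_names].to_numpy(float)
        return pd.Series(self.model.predict_proba(X)[:, 1], index=features.index,
                         name="combined_score")


def combine_features(cfmeth_scores: pd.Series, records: pd.DataFrame) -> pd.DataFrame:
    """Feature table [cfMeth, mammography, ultrasound] aligned on sample id."""
    feats = pd.DataFrame(
        {
            "cfmeth_score": cfmeth_scores,
            "mammography_score": records["mammography_score"].astype(float),
            "ultrasound_score": records["ultrasound_score"].astype(float),
        }
    )
    return feats.loc[cfmeth_scores.index]


def train_combined(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_folds: int = 10,
    inner_folds: int = 5,
    Cs=np.logspace(-3, 3, 13),
) -> CombinedModel:
    """Ridge logistic regression over standardized [cfMeth, imaging] features.

    The L2 penalty is chosen by internal stratified CV on discovery data;
    discovery combined scores are produced out-of-fold so the subsequent
    cutoff selection never sees in-sample predictions.  Constant features
    are dropped with a warning.
    """
    y = _as_binary(labels)
    X = features.copy()
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant feature(s): {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    names = list(X.columns)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("ridge", LogisticRegressionCV(
                Cs=Cs, cv=inner, penalty="l2", scoring="roc_auc",
                max_iter=5000, random_state=seed,
            )),
        ]
    )
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # scikit-learn emits FutureWarnings about LogisticRegressionCV
        # parameter renames; behaviour is unaffected
        warnings.simplefilter("ignore", FutureWarning)
        oof = cross_val_predict(pipe, X.to_numpy(float), y, cv=outer,
                                method="predict_proba")[:, 1]
        final = clone(pipe).fit(X.to_numpy(float), y)
    coefs = pd.Series(final.named_steps["ridge"].coef_.ravel(), index=names)
    return CombinedModel(
        oof_scores=pd.Series(oof, index=features.index, name="combined_score"),
        model=final, feature_names=names, coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# operating point and evaluation
# ---------------------------------------------------------------------------

def select_cutoff(scores, labels, max_fnr: float = 0.02) -> float:
    """Largest threshold whose false-negative rate is strictly below max_fnr.

    Classification rule: score >= threshold -> malignant.  FNR(t) is the
    fraction of positives with score < t, so FNR is non-decreasing in t and
    the bound is satisfiable at t = min(scores); if no candidate satisfies it
    (only possible with pathological inputs) the minimal score minus one ulp
    is returned with a warning.
    """
    if not 0.0 <= max_fnr < 1.0:
        raise ValueError("max_fnr must be in [0, 1)")
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pos = s[y == 1]
    if pos.size == 0:
        raise ValueError("cutoff selection requires at least one positive sample")
    candidates = np.unique(s)
    fnr = np.mean(pos[None, :] < candidates[:, None], axis=1)
    ok = np.flatnonzero(fnr < max_fnr)
    if ok.size == 0:
        warnings.warn("no threshold satisfies the FNR bound; returning min(scores) - ulp",
                      stacklevel=2)
        return float(np.nextafter(s.min(), -np.inf))
    return float(candidates[ok[-1]])


@dataclass
class ModelResult:
    """Evaluation summary of one score vector against labels."""

    auc: float
    auc_ci: tuple[float, float]
    roc: list[tuple[float, float]]  # ordered (FPR, TPR)
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    stage_detection: dict[str, float] = field(default_factory=dict)
    scores: pd.Series | None = None

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)


def evaluate(
    scores,
    labels,
    threshold: float,
    stages=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> ModelResult:
    """ROC/AUC with stratified-bootstrap CI plus threshold-level metrics.

    Per-stage detection is the fraction of malignant samples of each stage
    scored at or above the threshold (stage "0", DCIS, reported separately).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        boots[b] = roc_auc_score(y[idx], s[idx])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / y.size

    stage_detection: dict[str, float] = {}
    if stages is not None:
        stages = np.asarray([("" if v is None else str(v)) for v in stages])
        for stage in sorted({str(v) for v in stages[y == 1] if v}):
            sel = (y == 1) & (stages == stage)
            stage_detection[str(stage)] = float(np.mean(pred[sel]))

    score_series = scores if isinstance(scores, pd.Series) else pd.Series(s)
    return ModelResult(
        auc=auc, auc_ci=ci, roc=list(zip(fpr.tolist(), tpr.tolist())),
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=float(sens), specificity=float(spec), accuracy=float(acc),
        stage_detection=stage_detection, scores=score_series,
    )


@dataclass
class StageTrend:
    statistic: float  # Kendall tau-b of score vs ordinal stage
    p_value: float
    n: int


def association_with_stage(scores, stages) -> StageTrend:
    """Ordinal trend of cfMeth score with tumor stage (Kendall rank correlation).

    Requires at least two stages with >= 3 samples each; samples with no
    stage (benign) are excluded.
    """
    s = np.asarray(scores, dtype=float)
    st = np.asarray([None if v in (None, "", "nan") else str(v) for v in stages], dtype=object)
    keep = np.array([v is not None for v in st])
    s, st = s[keep], st[keep]
    ords = np.array([STAGE_ORDER[v] for v in st])
    values, counts = np.unique(ords, return_counts=True)
    if np.sum(counts >= 3) < 2:
        raise ValueError("need at least 2 stages with >= 3 samples each")
    if np.all(s == s[0]):
        return StageTrend(statistic=0.0, p_value=1.0, n=s.size)
    tau, p = stats.kendalltau(s, ords)
    return StageTrend(statistic=float(tau), p_value=float(p), n=s.size)
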