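"""Tumor/normal classification from GAPF profiles.

The threshold model is deliberately simple: a sample's decision statistic
is the maximum per-chromosome count among its top-K high-coverage bins, and
the sample is called GAPF-positive when that maximum reaches a global
threshold on any one chromosome. The operating threshold is chosen on a ROC
curve by Youden's J statistic (sensitivity + specificity - 1), and the
model is evaluated with seeded stratified k-fold cross-validation. A
simplified machine-learning comparison trains standard classifiers on the
23-chromosome count vector (chr1-22 + chrX) and explains them with
permutation feature importance, combined across algorithms into a composite
importance weighted by each algorithm's median AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

ML_FEATURE_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
DEFAULT_SEEDS = (22, 32, 42)


# ---------------------------------------------------------------------------
# ROC / Youden machinery on integer sample scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep of the max-chromosome-count statistic.

    ``points`` has one row per candidate threshold (every distinct score plus
    an all-negative sentinel above the maximum), with the sensitivity and
    specificity of calling positive at score >= threshold. ``auc`` is the
    trapezoidal area under sensitivity vs (1 - specificity).
    """

    points: pd.DataFrame
    auc: float
    optimal_threshold: int
    youden_j: float


def sample_scores(X: np.ndarray) -> np.ndarray:
    """Decision statistic per sample: the maximum per-chromosome HCB count."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("expected a samples x chromosomes count matrix")
    return X.max(axis=1)


def classify_threshold(scores, threshold: int, strict_gt: bool = False) -> np.ndarray:
    """GAPF-positive iff score >= threshold (or > threshold with strict_gt)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = np.asarray(scores)
    return scores > threshold if strict_gt else scores >= threshold


def roc_from_scores(scores, y, strict_gt: bool = False) -> ROCResult:
    """ROC over all distinct decision thresholds, trapezoidal AUC, Youden J.

    ``y`` is binary with 1 = tumor (positive class). Threshold ties on J
    break toward the smallest (most sensitive) threshold.
    """
    scores = np.asarray(scores)
    y = np.asarray(y).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.concatenate([np.unique(scores), [scores.max() + 1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pos = classify_threshold(scores, t, strict_gt=strict_gt)
        sens[i] = (pos & (y == 1)).sum() / n_pos
        spec[i] = (~pos & (y == 0)).sum() / n_neg
    points = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})
    fpr = 1.0 - spec
    # sort by fpr then sensitivity so vertical ROC segments are traversed
    # upward; the staircase then integrates to the Mann-Whitney statistic
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (= smallest threshold) on ties
    return ROCResult(
        points=points,
        auc=auc,
        optimal_threshold=int(thresholds[best]),
        youden_j=float(j[best]),
    )


def roc_curve(X, y, strict_gt: bool = False) -> ROCResult:
    """ROC of the threshold model on a samples x chromosomes count matrix."""
    return roc_from_scores(sample_scores(X), y, strict_gt=strict_gt)


# ---------------------------------------------------------------------------
# The threshold model as an sklearn estimator
# ---------------------------------------------------------------------------

class MaxChromosomeThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Binary GAPF-positive/negative caller on per-chromosome HCB counts.

    ``fit`` sweeps the max-chromosome-count statistic over all observed
    thresholds and stores the Youden-optimal one; ``predict`` calls a sample
    positive when its statistic reaches that threshold. A fixed threshold
    may be supplied to bypass fitting-time selection.

    Parameters
    ----------
    threshold : int or None
        Fixed decision threshold; if None (default) it is learned by
        Youden's J on the training data.
    strict_gt : bool
        Call positive on score > threshold instead of >=.

    Attributes
    ----------
    threshold_ : int
        Operating threshold after ``fit``.
    roc_ : ROCResult
        Training-data ROC sweep.
    auc_ : float
        Training-data trapezoidal AUC.
    """

    def __init__(self, threshold: int | None = None, strict_gt: bool = False):
        self.threshold = threshold
        self.strict_gt = strict_gt

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("threshold model requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(int)
        self.roc_ = roc_from_scores(sample_scores(X), y01, strict_gt=self.strict_gt)
        self.auc_ = self.roc_.auc
        self.threshold_ = self.roc_.optimal_threshold if self.threshold is None else int(self.threshold)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        X = check_array(X)
        return sample_scores(X).astype(float)

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        X = check_array(X)
        pos = classify_threshold(sample_scores(X), self.threshold_, strict_gt=self.strict_gt)
        return self.classes_[pos.astype(int)]


# ---------------------------------------------------------------------------
# Cross-validation of the threshold model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    """Seeded stratified k-fold evaluation of the threshold model.

    ``records`` holds one row per (seed, fold) with the held-out AUC and the
    sensitivity/specificity at the threshold fitted on the training folds.
    Summary statistics are given both pooled over all seed x fold values and
    as seed-level means; the whole-cohort Youden threshold (fit on all
    samples, no CV) is reported alongside.
    """

    folds: int
    seeds: tuple[int, ...]
    records: pd.DataFrame
    mean_auc: float
    sd_auc: float
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    seed_mean_auc: pd.Series
    sd_auc_seed_level: float
    full_cohort_threshold: int
    full_cohort_auc: float

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seeds": list(self.seeds),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_sensitivity": self.mean_sensitivity,
            "sd_sensitivity": self.sd_sensitivity,
            "mean_specificity": self.mean_specificity,
            "sd_specificity": self.sd_specificity,
            "sd_auc_seed_level": self.sd_auc_seed_level,
            "full_cohort_threshold": self.full_cohort_threshold,
            "full_cohort_auc": self.full_cohort_auc,
            "records": self.records.to_dict(orient="records"),
        }


def _fold_eval(scores_tr, y_tr, scores_te, y_te, strict_gt: bool) -> dict | None:
    if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
        return None
    roc_tr = roc_from_scores(scores_tr, y_tr, strict_gt=strict_gt)
    t = roc_tr.optimal_threshold
    pos = classify_threshold(scores_te, t, strict_gt=strict_gt)
    sens = (pos & (y_te == 1)).sum() / (y_te == 1).sum()
    spec = (~pos & (y_te == 0)).sum() / (y_te == 0).sum()
    auc = roc_from_scores(scores_te, y_te, strict_gt=strict_gt).auc
    return {"threshold": t, "auc": auc, "sensitivity": float(sens), "specificity": float(spec)}


def cross_validate_threshold(
    X,
    y,
    folds: int = 3,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    strict_gt: bool = False,
) -> CVReport:
    """Evaluate the threshold model with stratified k-fold CV over seeds.

    For each seed the samples are shuffled and dealt into ``folds``
    class-stratified groups; for each fold the Youden threshold is refit on
    the training folds and AUC/sensitivity/specificity are measured on the
    held-out fold. Identical seeds give identical partitions and results.
    Folds missing a class are reported as missing and excluded from the
    aggregates with a warning.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    for cls in (0, 1):
        if (y == cls).sum() < folds:
            raise ValueError(f"need at least {folds} samples of class {cls} for {folds}-fold CV")
    scores = sample_scores(X)
    rows = []
    n_missing = 0
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            res = _fold_eval(scores[tr], y[tr], scores[te], y[te], strict_gt)
            if res is None:
                n_missing += 1
                continue
            rows.append({"seed": seed, "fold": fold, **res})
    if n_missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d folds lacked both classes and were excluded", n_missing
        )
    records = pd.DataFrame(rows)
    full = roc_from_scores(scores, y, strict_gt=strict_gt)
    seed_means = records.groupby("seed")["auc"].mean()
    return CVReport(
        folds=folds,
        seeds=tuple(seeds),
        records=records,
        mean_auc=float(records["auc"].mean()),
        sd_auc=float(records["auc"].std(ddof=1)),
        mean_sensitivity=float(records["sensitivity"].mean()),
        sd_sensitivity=float(records["sensitivity"].std(ddof=1)),
        mean_specificity=float(records["specificity"].mean()),
        sd_specificity=float(records["specificity"].std(ddof=1)),
        seed_mean_auc=seed_means,
        sd_auc_seed_level=float(seed_means.std(ddof=1)),
        full_cohort_threshold=full.optimal_threshold,
        full_cohort_auc=full.auc,
    )


# ---------------------------------------------------------------------------
# Simplified ML comparison
# ---------------------------------------------------------------------------

def _model_factory(name: str, seed: int):
    # fixed documented defaults; no hyperparameter sweep
    if name == "naive-bayes":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if name == "random-forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "gradient-boosting":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200, random_state=seed, eval_metric="logloss", verbosity=0
        )
    raise ValueError(f"unknown algorithm {name!r}")


def _prob_auc(model, X, y) -> float:
    from sklearn.metrics import roc_auc_score

    if hasattr(model, "predict_proba"):
        s = model.predict_proba(X)[:, 1]
    else:
        s = model.decision_function(X)
    return float(roc_auc_score(y, s))


def evaluate_ml_models(
    X,
    y,
    algorithms: Sequence[str] = ("naive-bayes", "random-forest", "gradient-boosting"),
    folds: int = 3,
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> dict[str, pd.DataFrame]:
    """Seeded k-fold AUC comparison of standard classifiers on HCB counts.

    Returns per algorithm a DataFrame with one row per (seed, fold) holding
    the held-out AUC. Hyperparameters are fixed defaults; the comparison is
    about the feature signal, not model tuning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    out: dict[str, pd.DataFrame] = {}
    for name in algorithms:
        _model_factory(name, 0)  # validate the name up front
        rows = []
        for seed in seeds:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for fold, (tr, te) in enumerate(skf.split(X, y)):
                model = _model_factory(name, seed)
                model.fit(X[tr], y[tr])
                rows.append({"seed": seed, "fold": fold, "auc": _prob_auc(model, X[te], y[te])})
        out[name] = pd.DataFrame(rows)
    return out


def permutation_importance_auc(
    model,
    X,
    y,
    repeats: int = 20,
    seed: int = 0,
    score: Callable | None = None,
) -> np.ndarray:
    """Per-feature importance: baseline AUC minus mean AUC after shuffling.

    Each feature column is permuted ``repeats`` times (seeded) in the test
    data and the drop in AUC is averaged; features the model ignores score
    ~0, features it relies on score the AUC they carry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("permutation importance undefined on a single-class test set")
    scorer = score if score is not None else _prob_auc
    rng = np.random.default_rng(seed)
    baseline = scorer(model, X, y)
    imp = np.zeros(X.shape[1])
    for f in range(X.shape[1]):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            drops.append(baseline - scorer(model, Xp, y))
        imp[f] = np.mean(drops)
    return imp


def composite_importance(
    raw_scores: Mapping[str, np.ndarray], median_auc: Mapping[str, float]
) -> np.ndarray:
    """Combine per-algorithm permutation importances into one ranking.

    Within each algorithm, negative raw scores are floored at 0 and the rest
    divided by the algorithm's maximum positive score (0-1 normalization);
    the normalized scores are weighted by that algorithm's median AUC and
    summed across algorithms per feature, so accurate models count more.
    """
    if not raw_scores:
        raise ValueError("need at least one algorithm")
    n = len(next(iter(raw_scores.values())))
    total = np.zeros(n)
    for name, scores in raw_scores.items():
        s = np.maximum(np.asarray(scores, dtype=float), 0.0)
        m = s.max()
        if m > 0:
            total += (s / m) * float(median_auc[name])
    return total


def chrx_hcb_compare(groups: Mapping[str, pd.DataFrame]) -> dict[str, list[int]]:
    """Extract per-sample chrX HCB counts for each group of profiles.

    ``groups`` maps a group name (e.g. 'PCa cfDNA', 'buffy coat') to a
    samples x chromosomes count table. The downstream rank tests are left to
    standard statistics routines.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    out: dict[str, list[int]] = {}
    for name, table in groups.items():
        if len(table) == 0:
            raise ValueError(f"group {name!r} is empty")
        if "chrX" not in table.columns:
            raise ValueError(f"group {name!r} has no chrX column")
        out[name] = [int(v) for v in table["chrX"]]
    return out
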