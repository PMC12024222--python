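"""Locomotion-score classification experiments.

Reproduces the comparative experiment design: each of three classifier
families (linear-kernel SVM, entropy decision tree, multinomial logistic
regression) is trained on single kinematic features and on all six
features under stratified fivefold cross-validation, with per-fold
z-score normalisation fitted on the training fold only (no leakage).
Weight-based feature importance, a three-feature model (step overlap,
supporting phase, back arch) and a hierarchical cascade (back arch first
to flag severe lameness, then step overlap + supporting phase to split
sound from mildly lame among the predicted non-severe cows) complete
the suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .gait_features import FEATURE_NAMES
from .metrics import ClassMetrics, class_metrics, confusion_matrix

ALGORITHMS: tuple[str, ...] = ("svm", "tree", "logreg")

#: The three most discriminative features (cascade / reduced model inputs).
KEY_FEATURES: tuple[str, ...] = ("step_overlap_cm", "supporting_phase_ms", "back_arch")

SEVERE_SCORE = 3


def make_classifier(algorithm: str, penalty: float = 1.0, seed: int = 0):
    """Instantiate one of the three classifier families.

    ``penalty`` is the inverse L2 regularisation strength (C) for the
    linear models; the tree is regularised by a minimum leaf size instead.
    """
    if algorithm == "svm":
        return LinearSVC(C=penalty, dual=False, max_iter=10000)
    if algorithm == "tree":
        return DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        )
    if algorithm == "logreg":
        # multinomial by default for multiclass targets
        return LogisticRegression(C=penalty, max_iter=5000)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _check_cohort(cohort: pd.DataFrame, feature_subset) -> tuple[np.ndarray, np.ndarray]:
    unknown = [f for f in feature_subset if f not in cohort.columns]
    if unknown:
        raise ValueError(
            f"unknown feature(s) {unknown}; available: {list(FEATURE_NAMES)}"
        )
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    if "score" not in cohort.columns:
        raise ValueError("cohort must have a 'score' column")
    X = cohort[list(feature_subset)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cohort has missing feature values; preprocess first")
    y = cohort["score"].to_numpy(dtype=int)
    return X, y


def stratified_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per row).

    Per-fold class counts differ from exact proportionality by less than
    one cow.  A class with fewer than ``k`` members is rejected.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2 (k={k} leaves no held-out data)")
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < k]
    if len(short):
        raise ValueError(
            f"class(es) {short.tolist()} have fewer than k={k} members; "
            "stratified k-fold is impossible"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test_idx] = i
    return fold


def zscore_preprocess(train: np.ndarray, test: np.ndarray):
    """Standardise columns to mean 0 / variance 1 using *training* statistics.

    The test block is transformed with the training mean and SD only, so a
    transformed test column generally has non-zero mean (that asymmetry is
    the leakage guarantee).  Zero-variance training columns are passed
    through centred, with a warning.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)  # population SD, matching standard scalers
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance training column(s) at index {np.flatnonzero(zero).tolist()}; "
            "passing through centred",
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


@dataclass
class CVReport:
    """Per-fold and pooled results of one cross-validated experiment."""

    algorithm: str
    features: tuple[str, ...]
    seed: int
    k: int
    fold_assignments: np.ndarray
    fold_cms: list[np.ndarray]
    fold_metrics: list[ClassMetrics]
    pooled_cm: np.ndarray
    pooled: ClassMetrics

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "features": list(self.features),
            "seed": self.seed,
            "k": self.k,
            "pooled": self.pooled.to_dict(),
            "folds": [m.to_dict() for m in self.fold_metrics],
        }


def train_eval_cv(
    cohort: pd.DataFrame,
    feature_subset,
    algorithm: str,
    k: int = 5,
    seed: int = 0,
    penalty: float = 1.0,
) -> CVReport:
    """Stratified k-fold evaluation of one classifier on one feature subset."""
    X, y = _check_cohort(cohort, feature_subset)
    fold = stratified_folds(y, k=k, seed=seed)
    fold_cms, fold_metrics = [], []
    for i in range(k):
        tr, te = fold != i, fold == i
        Xtr, Xte = zscore_preprocess(X[tr], X[te])
        clf = make_classifier(algorithm, penalty=penalty, seed=seed)
        clf.fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        cm = confusion_matrix(y[te], pred)
        fold_cms.append(cm)
        fold_metrics.append(class_metrics(cm))
    pooled_cm = np.sum(fold_cms, axis=0)
    return CVReport(
        algorithm=algorithm,
        features=tuple(feature_subset),
        seed=seed,
        k=k,
        fold_assignments=fold,
        fold_cms=fold_cms,
        fold_metrics=fold_metrics,
        pooled_cm=pooled_cm,
        pooled=class_metrics(pooled_cm),
    )


@dataclass
class ImportanceTable:
    """Cross-validated weight-based feature importances for one algorithm."""

    algorithm: str
    feature_names: tuple[str, ...]
    per_fold: np.ndarray  # k x n_features
    mean: pd.Series

    def ranking(self) -> list[str]:
        return list(self.mean.sort_values(ascending=False).index)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "mean": {f: float(v) for f, v in self.mean.items()},
            "per_fold": self.per_fold.tolist(),
        }


def _importance_vector(clf, algorithm: str) -> np.ndarray:
    if algorithm == "tree":
        return np.asarray(clf.feature_importances_, dtype=float)
    # linear machines: mean |coefficient| per feature across the per-class rows
    coef = np.atleast_2d(clf.coef_)
    return np.abs(coef).mean(axis=0)


def feature_importance(
    cohort: pd.DataFrame,
    algorithm: str,
    k: int = 5,
    seed: int = 0,
    penalty: float = 1.0,
    feature_subset=FEATURE_NAMES,
) -> ImportanceTable:
    """Per-fold importances on standardised training folds, averaged over folds."""
    X, y = _check_cohort(cohort, feature_subset)
    fold = stratified_folds(y, k=k, seed=seed)
    per_fold = np.zeros((k, X.shape[1]))
    for i in range(k):
        tr = fold != i
        Xtr, _ = zscore_preprocess(X[tr], X[tr])
        clf = make_classifier(algorithm, penalty=penalty, seed=seed)
        clf.fit(Xtr, y[tr])
        per_fold[i] = _importance_vector(clf, algorithm)
    mean = pd.Series(per_fold.mean(axis=0), index=list(feature_subset))
    return ImportanceTable(
        algorithm=algorithm,
        feature_names=tuple(feature_subset),
        per_fold=per_fold,
        mean=mean,
    )


def three_feature_model(
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    penalty: float = 1.0,
    algorithm: str = "svm",
    feature_subset=KEY_FEATURES,
) -> CVReport:
    """Linear-SVM model on the three most discriminative features."""
    return train_eval_cv(
        cohort, feature_subset, algorithm, k=k, seed=seed, penalty=penalty
    )


@dataclass
class HierarchicalReport:
    """Cascade results: severe-first stage, then sound-vs-mild stage."""

    seed: int
    k: int
    fold_assignments: np.ndarray
    stage1_cm: np.ndarray          # rows/cols: (non-severe, severe)
    stage1: ClassMetrics
    stage2_cm: np.ndarray          # rows/cols: (score 1, score 2)
    stage2: ClassMetrics
    combined_cm: np.ndarray        # full 3x3
    combined: ClassMetrics

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "k": self.k,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "combined": self.combined.to_dict(),
        }


def hierarchical_train_eval(
    cohort: pd.DataFrame, k: int = 5, seed: int = 0, penalty: float = 1.0
) -> HierarchicalReport:
    """Two-stage cascade classifier under stratified k-fold CV.

    Stage 1: linear SVM on back arch alone, severe (score 3) vs rest.
    Stage 2: linear SVM on (step overlap, supporting phase), trained on the
    *true* non-severe training cows, applied to stage-1 test negatives.
    Stage-1 positives are labelled score 3; combined predictions are scored
    as three-class, and each stage is also reported as a binary problem
    (stage 2 on the stage-1 negatives whose true score is 1 or 2).
    """
    X1, y = _check_cohort(cohort, ("back_arch",))
    X2, _ = _check_cohort(cohort, ("step_overlap_cm", "supporting_phase_ms"))
    fold = stratified_folds(y, k=k, seed=seed)

    s1_true, s1_pred = [], []
    s2_true, s2_pred = [], []
    all_true, all_pred = [], []
    for i in range(k):
        tr, te = fold != i, fold == i
        severe_tr = (y[tr] == SEVERE_SCORE).astype(int)
        if severe_tr.sum() == 0:
            raise ValueError(
                f"fold {i}: no severe cows in training data (stratification failure)"
            )
        Xtr1, Xte1 = zscore_preprocess(X1[tr], X1[te])
        stage1 = make_classifier("svm", penalty=penalty, seed=seed)
        stage1.fit(Xtr1, severe_tr)
        pred_severe = stage1.predict(Xte1).astype(bool)

        nonsevere_tr = tr & (y != SEVERE_SCORE)
        te_idx = np.flatnonzero(te)
        neg_idx = te_idx[~pred_severe]
        combined = np.full(te.sum(), SEVERE_SCORE, dtype=int)
        if len(neg_idx):
            Xtr2, Xte2 = zscore_preprocess(X2[nonsevere_tr], X2[neg_idx])
            stage2 = make_classifier("svm", penalty=penalty, seed=seed)
            stage2.fit(Xtr2, y[nonsevere_tr])
            pred2 = stage2.predict(Xte2)
            combined[~pred_severe] = pred2
            mild_truth = np.isin(y[neg_idx], (1, 2))
            s2_true.extend(y[neg_idx][mild_truth].tolist())
            s2_pred.extend(pred2[mild_truth].tolist())

        s1_true.extend((y[te] == SEVERE_SCORE).astype(int).tolist())
        s1_pred.extend(pred_severe.astype(int).tolist())
        all_true.extend(y[te].tolist())
        all_pred.extend(combined.tolist())

    stage1_cm = confusion_matrix(s1_true, s1_pred, labels=(0, 1))
    stage2_cm = confusion_matrix(s2_true, s2_pred, labels=(1, 2))
    combined_cm = confusion_matrix(all_true, all_pred)
    return HierarchicalReport(
        seed=seed,
        k=k,
        fold_assignments=fold,
        stage1_cm=stage1_cm,
        stage1=class_metrics(stage1_cm, labels=(0, 1)),
        stage2_cm=stage2_cm,
        stage2=class_metrics(stage2_cm, labels=(1, 2)),
        combined_cm=combined_cm,
        combined=class_metrics(combined_cm),
    )


# ---------------------------------------------------------------------------
# experiment suite
# ---------------------------------------------------------------------------

def run_experiment_suite(
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    penalty: float = 1.0,
    algorithms=ALGORITHMS,
) -> dict:
    """Run the full comparative experiment battery on one cohort."""
    suite: dict = {
        "single": {},
        "multi": {},
        "importance": {},
    }
    for feat in FEATURE_NAMES:
        suite["single"][feat] = {
            alg: train_eval_cv(cohort, (feat,), alg, k=k, seed=seed, penalty=penalty)
            for alg in algorithms
        }
    for alg in algorithms:
        suite["multi"][alg] = train_eval_cv(
            cohort, FEATURE_NAMES, alg, k=k, seed=seed, penalty=penalty
        )
        suite["importance"][alg] = feature_importance(
            cohort, alg, k=k, seed=seed, penalty=penalty
        )
    suite["three_feature"] = three_feature_model(cohort, k=k, seed=seed, penalty=penalty)
    suite["hierarchical"] = hierarchical_train_eval(cohort, k=k, seed=seed, penalty=penalty)
    return suite


def summary_table(suite: dict) -> pd.DataFrame:
    """Flat summary (one row per input/algorithm) of pooled CV metrics."""
    rows = []

    def row(label, alg, report: CVReport):
        m = report.pooled
        rows.append(
            {
                "input": label,
                "algorithm": alg,
                "accuracy_pct": m.accuracy_pct,
                "sens_1": m.per_class[1]["sensitivity"],
                "spec_1": m.per_class[1]["specificity"],
                "sens_2": m.per_class[2]["sensitivity"],
                "spec_2": m.per_class[2]["specificity"],
                "sens_3": m.per_class[3]["sensitivity"],
                "spec_3": m.per_class[3]["specificity"],
                "macro_f1": m.macro_f1,
            }
        )

    for feat, by_alg in suite["single"].items():
        for alg, rep in by_alg.items():
            row(feat, alg, rep)
    for alg, rep in suite["multi"].items():
        row("all_six", alg, rep)
    row("three_feature", suite["three_feature"].algorithm, suite["three_feature"])
    h = suite["hierarchical"]
    m = h.combined
    rows.append(
        {
            "input": "hierarchical",
            "algorithm": "svm_cascade",
            "accuracy_pct": m.accuracy_pct,
            "sens_1": m.per_class[1]["sensitivity"],
            "spec_1": m.per_class[1]["specificity"],
            "sens_2": m.per_class[2]["sensitivity"],
            "spec_2": m.per_class[2]["specificity"],
            "sens_3": m.per_class[3]["sensitivity"],
            "spec_3": m.per_class[3]["specificity"],
            "macro_f1": m.macro_f1,
        }
    )
    return pd.DataFrame(rows)
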