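"""Train, cross-validate and introspect CRM classifiers.

M1/M2/M3 are Random Forests of 151 Gini-impurity decision trees with
``max_features = sqrt(p)`` and bootstrap resampling; the prediction is the
fraction of trees voting for the positive class, so scores live in [0, 1]
with resolution 1/151.  M0 is the single-PWM baseline whose "prediction"
is the normalized best-site score itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .training_data import FeatureSpec, LabeledSet

N_TREES_DEFAULT = 151

_FORMAT_VERSION = 1


@dataclass
class CrmModel:
    """A trained CRM classifier (or the M0 PWM baseline).

    ``window_length`` is the mean length of the positive training regions,
    used for genome scanning and variant-window placement.
    """

    model_class: str
    feature_spec: FeatureSpec
    window_length: int
    forest: RandomForestClassifier | None = None
    vote_fraction: bool = True
    training_meta: dict = field(default_factory=dict)
    name: str = "model"

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for an n x p feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_spec.n_features:
            raise ValueError(
                f"expected {self.feature_spec.n_features} features, got {X.shape[1]}"
            )
        if self.model_class == "M0":
            return X[:, 0].copy()
        if self.forest is None:
            raise ValueError("model is not trained")
        if self.vote_fraction:
            pos_label = list(self.forest.classes_).index(1)
            votes = np.zeros(X.shape[0])
            for tree in self.forest.estimators_:
                votes += (tree.predict(X) == self.forest.classes_[pos_label])
            return votes / len(self.forest.estimators_)
        return self.forest.predict_proba(X)[:, list(self.forest.classes_).index(1)]

    def save(self, path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "model_class": self.model_class,
            "feature_spec": self.feature_spec,
            "window_length": self.window_length,
            "forest": self.forest,
            "vote_fraction": self.vote_fraction,
            "training_meta": self.training_meta,
            "name": self.name,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "CrmModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        payload.pop("format_version")
        return cls(**payload)


def m0_model(pwm_name: str, window_length: int, name: str | None = None) -> CrmModel:
    """The single-PWM baseline; its feature vector is [best_site_score]."""
    spec = FeatureSpec(motif_features=[pwm_name], model_class="M0")
    return CrmModel("M0", spec, window_length, name=name or f"M0_{pwm_name}")


def train_model(
    data: LabeledSet,
    n_trees: int = N_TREES_DEFAULT,
    seed: int = 0,
    vote_fraction: bool = True,
    name: str = "model",
) -> CrmModel:
    """Fit the Random Forest on a labeled set.

    Gini criterion, ``max_features = sqrt(p)``, bootstrap per tree, no depth
    limit; deterministic under ``seed``.
    """
    labels = np.unique(data.labels)
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    if data.spec is None:
        raise ValueError("LabeledSet has no FeatureSpec")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(data.feature_matrix, data.labels)
    positive_lengths = [
        r.length for r, y in zip(data.regions, data.labels) if y == 1
    ]
    window_length = int(round(float(np.mean(positive_lengths))))
    return CrmModel(
        model_class=data.spec.model_class,
        feature_spec=data.spec,
        window_length=window_length,
        forest=forest,
        vote_fraction=vote_fraction,
        training_meta={
            "seed": seed,
            "n_trees": n_trees,
            "n_positives": int(data.labels.sum()),
            "n_negatives": int((data.labels == 0).sum()),
        },
        name=name,
    )


def predict_score(model: CrmModel, feature_vector: np.ndarray) -> float:
    """Score a single feature vector."""
    return float(model.predict(np.atleast_2d(feature_vector))[0])


@dataclass
class CvReport:
    """Pooled out-of-fold cross-validation performance."""

    au_pr: float
    au_roc: float
    fold_au_pr: list[float]
    fold_au_roc: list[float]
    y_true: np.ndarray
    y_score: np.ndarray
    pr_curve: tuple[np.ndarray, np.ndarray]
    roc_curve: tuple[np.ndarray, np.ndarray]


def score_report(labels: np.ndarray, scores: np.ndarray) -> CvReport:
    """Performance report for precomputed scores (used for the M0 baseline,
    which has no training step: the curves come from varying its threshold)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    precision, recall, _ = precision_recall_curve(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    return CvReport(
        au_pr=float(average_precision_score(labels, scores)),
        au_roc=float(roc_auc_score(labels, scores)),
        fold_au_pr=[],
        fold_au_roc=[],
        y_true=labels,
        y_score=scores,
        pr_curve=(precision, recall),
        roc_curve=(fpr, tpr),
    )


def cross_validate(
    data: LabeledSet,
    k: int = 5,
    seed: int = 0,
    n_trees: int = N_TREES_DEFAULT,
    vote_fraction: bool = True,
) -> CvReport:
    """Stratified k-fold CV; AuPR/AuROC on pooled out-of-fold predictions.

    AuPR uses step interpolation (average precision); AuROC the trapezoid
    rule.  Folds are stratified by label so every fold holds positives even
    at 1:20 imbalance.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.labels.sum() < k:
        # behaves like leave-one-out on the positives; still valid
        pass
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_score = np.empty(len(data.labels))
    fold_au_pr, fold_au_roc = [], []
    for fold, (train_idx, test_idx) in enumerate(
        skf.split(data.feature_matrix, data.labels)
    ):
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=seed + fold,
            n_jobs=1,
        )
        forest.fit(data.feature_matrix[train_idx], data.labels[train_idx])
        if vote_fraction:
            pos = list(forest.classes_).index(1)
            votes = np.zeros(len(test_idx))
            for tree in forest.estimators_:
                votes += (
                    tree.predict(data.feature_matrix[test_idx])
                    == forest.classes_[pos]
                )
            scores = votes / n_trees
        else:
            pos = list(forest.classes_).index(1)
            scores = forest.predict_proba(data.feature_matrix[test_idx])[:, pos]
        y_score[test_idx] = scores
        y_fold = data.labels[test_idx]
        if len(np.unique(y_fold)) == 2:
            fold_au_pr.append(float(average_precision_score(y_fold, scores)))
            fold_au_roc.append(float(roc_auc_score(y_fold, scores)))
    report = score_report(data.labels, y_score)
    report.fold_au_pr = fold_au_pr
    report.fold_au_roc = fold_au_roc
    return report


@dataclass
class ImportanceReport:
    """Gini feature importances averaged across trees."""

    importances: dict[str, float]
    std: dict[str, float]
    group_sums: dict[str, float]


def feature_importance(model: CrmModel) -> ImportanceReport:
    """Per-feature Gini importance (sums to 1), its std across trees, and
    group sums (query motifs / co-regulatory motifs / tracks)."""
    if model.model_class == "M0" or model.forest is None:
        raise ValueError("feature importance requires a tree ensemble (M1/M2/M3)")
    names = model.feature_spec.feature_names
    mean_imp = model.forest.feature_importances_
    per_tree = np.array(
        [tree.feature_importances_ for tree in model.forest.estimators_]
    )
    std_imp = per_tree.std(axis=0)
    importances = dict(zip(names, mean_imp.tolist()))
    std = dict(zip(names, std_imp.tolist()))
    group_sums = {
        group: float(sum(importances[n] for n in members))
        for group, members in model.feature_spec.groups().items()
    }
    return ImportanceReport(importances, std, group_sums)
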