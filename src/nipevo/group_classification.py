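"""Supervised discrimination of taxa groups from NIP descriptor profiles.

A training table pairs each taxon's 52-descriptor vector with its group
label for one contrast (e.g. kingdom, motility). A roster of standard
classifiers is evaluated by stratified 10-fold cross-validation; each model
is scored by accuracy and Cohen's kappa both on the pooled CV predictions
and on whole-set resubstitution, and models are ranked by CV accuracy then
CV kappa — the top model plays the role of the best classifier for the
contrast. Greedy forward selection then finds a small descriptor subset
whose CV kappa comes within a tolerance of the full 52-descriptor kappa.

Per-fold preprocessing (median imputation + standardization) is fit on
training folds only, so no information leaks across the CV split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .descriptors import DESCRIPTOR_IDS
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingTable",
    "EvaluationResult",
    "FeatureSubset",
    "OneRClassifier",
    "MODEL_IDS",
    "build_training_table",
    "kappa",
    "evaluate_models",
    "select_features",
]


@dataclass
class TrainingTable:
    """Descriptor matrix X (taxa x descriptors) and group labels y for one contrast."""

    X: pd.DataFrame
    y: pd.Series
    contrast: str
    constant_columns: list[str] = field(default_factory=list)


def build_training_table(
    descriptors: pd.DataFrame, metadata, contrast: str
) -> TrainingTable:
    """Join a descriptor table with group labels for one contrast.

    ``metadata`` is either a mapping taxon_id -> TaxonRecord or a DataFrame
    with one column per contrast. Taxa unlabeled for the contrast are
    dropped; constant-valued descriptor columns are flagged (but kept, so the
    column set stays the full registry).
    """
    if isinstance(metadata, pd.DataFrame):
        labels = metadata[contrast] if contrast in metadata else pd.Series(dtype=object)
    else:
        labels = pd.Series(
            {t: rec.groups.get(contrast) for t, rec in metadata.items()}, dtype=object
        )
    labels = labels.reindex(descriptors.index).replace("", np.nan).dropna()
    if labels.empty:
        raise ValidationError(f"no taxon is labeled for contrast {contrast!r}")
    X = descriptors.loc[labels.index]
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if constant:
        logger.info("contrast %r: %d constant descriptor columns", contrast, len(constant))
    return TrainingTable(X=X, y=labels.astype(str), contrast=contrast, constant_columns=constant)


def kappa(confusion) -> float:
    """Cohen's kappa from a k x k confusion matrix of counts.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = trace/N`` and chance agreement ``p_e = sum_i row_i col_i / N^2``;
    returns 0 when ``p_e = 1`` (a single occupied class).
    """
    c = np.asarray(confusion, dtype=float)
    if (c < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


class OneRClassifier(BaseEstimator, ClassifierMixin):
    """One-rule baseline: the best single-feature threshold rule.

    For every feature and every candidate threshold (midpoints between
    sorted unique values, capped at ``max_thresholds`` quantile candidates),
    predicts the majority class on each side; keeps the (feature, threshold)
    pair with the highest training accuracy. Deterministic: ties resolve to
    the lowest feature index and threshold.
    """

    def __init__(self, max_thresholds: int = 32):
        self.max_thresholds = max_thresholds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        best = (-1.0, 0, -np.inf, 0, 0)  # acc, feature, threshold, left cls, right cls
        n = len(y_enc)
        k = len(self.classes_)
        for j in range(X.shape[1]):
            col = X[:, j]
            col = np.where(np.isfinite(col), col, 0.0)
            uniq = np.unique(col)
            if len(uniq) > self.max_thresholds + 1:
                qs = np.quantile(col, np.linspace(0, 1, self.max_thresholds + 1))
                uniq = np.unique(qs)
            thresholds = (uniq[:-1] + uniq[1:]) / 2.0
            for t in thresholds:
                left = col <= t
                counts_l = np.bincount(y_enc[left], minlength=k)
                counts_r = np.bincount(y_enc[~left], minlength=k)
                acc = (counts_l.max() + counts_r.max()) / n
                if acc > best[0] + 1e-12:
                    best = (acc, j, t, int(counts_l.argmax()), int(counts_r.argmax()))
        if best[0] < 0:  # all columns constant: majority class rule
            maj = int(np.bincount(y_enc, minlength=k).argmax())
            best = (0.0, 0, np.inf, maj, maj)
        _, self.feature_, self.threshold_, self.left_class_, self.right_class_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        col = X[:, self.feature_]
        col = np.where(np.isfinite(col), col, 0.0)
        idx = np.where(col <= self.threshold_, self.left_class_, self.right_class_)
        return self.classes_[idx]


def _make_model(model_id: str, seed: int):
    if model_id == "logistic":
        est = LogisticRegression(max_iter=2000)
    elif model_id == "mlp":
        est = MLPClassifier(hidden_layer_sizes=(16,), max_iter=600, random_state=seed)
    elif model_id == "rule_tree":
        est = DecisionTreeClassifier(max_depth=5, random_state=seed)
    elif model_id == "oner":
        est = OneRClassifier()
    elif model_id == "knn1":
        est = KNeighborsClassifier(n_neighbors=1)
    elif model_id == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif model_id == "svm":
        est = SVC(kernel="rbf", C=1.0, random_state=seed)
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("model", est),
        ]
    )


MODEL_IDS = ("logistic", "mlp", "rule_tree", "oner", "knn1", "random_forest", "svm")


@dataclass
class EvaluationResult:
    """Cross-validated and resubstitution performance of one model."""

    model_id: str
    cv_accuracy: float
    cv_kappa: float
    train_accuracy: float
    train_kappa: float
    confusion: np.ndarray
    classes: list[str]
    seed: int
    folds: int


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    c = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[idx[t], idx[p]] += 1
    return c


def _effective_folds(y: pd.Series, folds: int) -> int:
    smallest = int(y.value_counts().min())
    if smallest < folds:
        logger.warning(
            "smallest class has %d members < %d folds; using %d folds",
            smallest,
            folds,
            max(2, smallest),
        )
        return max(2, smallest)
    return folds


def _cv_scores(table: TrainingTable, model, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = sorted(table.y.unique())
    y_cv = cross_val_predict(clone(model), table.X.values, table.y.values, cv=skf)
    conf = _confusion(table.y.values, y_cv, classes)
    return conf, classes


def evaluate_models(
    table: TrainingTable,
    models=MODEL_IDS,
    folds: int = 10,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Stratified k-fold evaluation of each model, ranked best first.

    Ranking is by CV accuracy, ties broken by CV kappa and then by position
    in the model roster (so the ranking is deterministic for a given seed).
    """
    classes = sorted(table.y.unique())
    if len(classes) < 2:
        raise ValidationError(
            f"contrast {table.contrast!r} has a single class {classes}; nothing to discriminate"
        )
    smallest = int(table.y.value_counts().min())
    if smallest < 2:
        raise ValidationError("every class needs at least 2 members for stratified CV")
    eff_folds = _effective_folds(table.y, folds)

    results = []
    for pos, model_id in enumerate(models):
        model = _make_model(model_id, seed)
        conf, cls = _cv_scores(table, model, eff_folds, seed)
        cv_acc = float(np.trace(conf) / conf.sum())
        cv_kap = kappa(conf)
        fitted = clone(model).fit(table.X.values, table.y.values)
        y_hat = fitted.predict(table.X.values)
        conf_tr = _confusion(table.y.values, y_hat, cls)
        results.append(
            EvaluationResult(
                model_id=model_id,
                cv_accuracy=cv_acc,
                cv_kappa=cv_kap,
                train_accuracy=float(np.trace(conf_tr) / conf_tr.sum()),
                train_kappa=kappa(conf_tr),
                confusion=conf,
                classes=cls,
                seed=seed,
                folds=eff_folds,
            )
        )
    order = {m: i for i, m in enumerate(models)}
    results.sort(key=lambda r: (-r.cv_accuracy, -r.cv_kappa, order[r.model_id]))
    return results


@dataclass
class FeatureSubset:
    """Minimal descriptor subset found by greedy forward selection."""

    descriptor_ids: list[str]
    cv_kappa_with_subset: float
    full_cv_kappa: float
    tolerance: float
    reached_tolerance: bool


def select_features(
    table: TrainingTable,
    best_model: str,
    tolerance: float = 0.01,
    folds: int = 10,
    seed: int = 0,
) -> FeatureSubset:
    """Greedy forward selection of descriptors maximizing CV kappa.

    Starting empty, repeatedly adds the descriptor (registry order breaks
    ties) that maximizes the subset's CV kappa, stopping as soon as the
    subset is within ``tolerance`` of the full-set kappa, or when no
    candidate improves it further (degenerate tables, flagged by
    ``reached_tolerance``).
    """
    eff_folds = _effective_folds(table.y, folds)
    model = _make_model(best_model, seed)

    def cv_kappa_of(columns: list[str]) -> float:
        sub = TrainingTable(table.X[columns], table.y, table.contrast)
        conf, _ = _cv_scores(sub, model, eff_folds, seed)
        return kappa(conf)

    feature_order = [c for c in DESCRIPTOR_IDS if c in table.X.columns]
    feature_order += [c for c in table.X.columns if c not in feature_order]
    full_kappa = cv_kappa_of(list(table.X.columns))

    selected: list[str] = []
    current = -np.inf
    while len(selected) < len(feature_order):
        best_candidate, best_k = None, -np.inf
        for f in feature_order:
            if f in selected:
                continue
            k = cv_kappa_of(selected + [f])
            if k > best_k + 1e-12:
                best_candidate, best_k = f, k
        if selected and best_k <= current + 1e-12:
            break  # no further gain
        selected.append(best_candidate)
        current = best_k
        if current >= full_kappa - tolerance:
            break
    reached = current >= full_kappa - tolerance
    if not reached:
        logger.warning(
            "forward selection stalled at kappa %.3f (full set %.3f)", current, full_kappa
        )
    return FeatureSubset(
        descriptor_ids=selected,
        cv_kappa_with_subset=float(current),
        full_cv_kappa=float(full_kappa),
        tolerance=tolerance,
        reached_tolerance=reached,
    )
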