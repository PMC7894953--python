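"""Classifier harness and evaluation for the assembled training sets.

Four classifier families are supported — decision tree, random forest,
RBF-kernel SVM and RUSBoost — evaluated with stratified 5-fold
cross-validation or a stratified 70:30 holdout.  Reported metrics per
fold: ROC-AUC, F1, G-mean = sqrt(sensitivity * specificity), sensitivity,
specificity and the misclassified fraction, plus the raw confusion counts
so every derived score can be recomputed from the report.

Default hyperparameters follow grid-search optima for this task: DT
(gini, depth 9, min split 6), RF (gini, depth 20, min leaf 3, min split 8,
200 trees), SVM (RBF, C=10, gamma=0.1), RUSBoost (500 stumps, learning
rate 1.0); tree learners use sqrt(n_features) features per split.

Also here: the threshold-sweep experiment driver, and group-averaged
feature-importance selection (XGBoost + random forest importances averaged
over balanced group pairs, top-k features kept).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .resampler import SamplingThresholds, TrainingSet, assemble_training_set, threshold_sample

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "EvalReport",
    "RUSBoostClassifier",
    "gmean",
    "evaluate",
    "threshold_sweep",
    "select_features_by_grouped_importance",
]

FAMILIES = ("decision_tree", "random_forest", "svm_rbf", "rusboost")


def gmean(tp: int, fn: int, tn: int, fp: int) -> float:
    """Geometric mean of sensitivity and specificity from confusion counts.

    sensitivity = tp / (tp + fn); specificity = tn / (tn + fp).
    """
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if tp + fn == 0:
        raise ValueError("no actual positives")
    if tn + fp == 0:
        raise ValueError("no actual negatives")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return math.sqrt(sens * spec)


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting with random under-sampling of the majority class.

    At every boosting round the majority class is randomly under-sampled to
    the minority size (draws weighted by the current boosting weights), a
    shallow decision tree is fit on the balanced draw, and AdaBoost-style
    weight updates are computed on the *full* training set.  This keeps each
    weak learner from drowning in the majority class while the ensemble
    still sees every sample.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        learning_rate: float = 1.0,
        max_depth: int = 1,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("RUSBoostClassifier supports exactly two classes")
        rng = np.random.default_rng(self.random_state)
        n = y.shape[0]
        counts = [(y == c).sum() for c in self.classes_]
        minority = self.classes_[int(np.argmin(counts))]
        min_idx = np.flatnonzero(y == minority)
        maj_idx = np.flatnonzero(y != minority)
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for _ in range(self.n_estimators):
            if maj_idx.size > min_idx.size:
                p = w[maj_idx] / w[maj_idx].sum()
                take = rng.choice(maj_idx, size=min_idx.size, replace=False, p=p)
                sel = np.concatenate([min_idx, take])
            else:
                sel = np.arange(n)
            est = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            est.fit(X[sel], y[sel], sample_weight=w[sel])
            miss = est.predict(X) != y
            err = float(w[miss].sum() / w.sum())
            if err <= 1e-12:
                self.estimators_.append(est)
                self.alphas_.append(self.learning_rate * 10.0)
                break
            if err >= 0.5:
                if not self.estimators_:
                    self.estimators_.append(est)
                    self.alphas_.append(1e-6)
                break
            alpha = self.learning_rate * 0.5 * math.log((1.0 - err) / err)
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * miss)
            w /= w.sum()
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], 2))
        for est, alpha in zip(self.estimators_, self.alphas_):
            pred = est.predict(X)
            for c_i, c in enumerate(self.classes_):
                votes[:, c_i] += alpha * (pred == c)
        total = votes.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return votes / total

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ClassifierSpec:
    """A classifier family plus hyperparameter overrides and a seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def build(self, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.family == "decision_tree":
            kw = dict(
                criterion="gini",
                max_depth=9,
                min_samples_leaf=1,
                min_samples_split=6,
                max_features="sqrt",
                random_state=seed,
            )
            kw.update(self.params)
            return DecisionTreeClassifier(**kw)
        if self.family == "random_forest":
            kw = dict(
                criterion="gini",
                n_estimators=200,
                max_depth=20,
                min_samples_leaf=3,
                min_samples_split=8,
                max_features="sqrt",
                random_state=seed,
            )
            kw.update(self.params)
            return RandomForestClassifier(**kw)
        if self.family == "svm_rbf":
            kw = dict(kernel="rbf", C=10.0, gamma=0.1, random_state=seed)
            kw.update(self.params)
            return SVC(**kw)
        kw = dict(n_estimators=500, learning_rate=1.0, random_state=seed)
        kw.update(self.params)
        return RUSBoostClassifier(**kw)


@dataclass
class EvalReport:
    """Per-fold metrics and their means for one classifier run."""

    per_fold: pd.DataFrame
    scheme: str
    family: str
    score_source: str  # "predict_proba" or "decision_function"

    @property
    def means(self) -> dict:
        cols = ["auc", "f1", "gmean", "sensitivity", "specificity", "error"]
        return {c: float(self.per_fold[c].mean()) for c in cols}


def _fold_metrics(fold, model, X_test, y_test) -> dict:
    if hasattr(model, "predict_proba"):
        score = model.predict_proba(X_test)[:, 1]
        source = "predict_proba"
    else:
        score = model.decision_function(X_test)
        source = "decision_function"
    pred = model.predict(X_test)
    tn, fp, fn, tp = confusion_matrix(y_test, pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "fold": fold,
        "auc": roc_auc_score(y_test, score),
        "f1": f1_score(y_test, pred),
        "gmean": gmean(tp, fn, tn, fp),
        "sensitivity": sens,
        "specificity": spec,
        "error": (fp + fn) / y_test.shape[0],
        "tp": int(tp),
        "fn": int(fn),
        "tn": int(tn),
        "fp": int(fp),
    }, source


def evaluate(
    ts: TrainingSet | tuple,
    spec: ClassifierSpec,
    scheme: str = "cv5",
    seed: int = 0,
) -> EvalReport:
    """Train and score a classifier under stratified CV or holdout.

    ``scheme`` is "cv5" (stratified 5-fold cross-validation) or "holdout70"
    (a single stratified 70:30 train/test split).
    """
    if isinstance(ts, TrainingSet):
        X, y = ts.X, ts.y
    else:
        X, y = np.asarray(ts[0], dtype=float), np.asarray(ts[1], dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    if scheme == "cv5":
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    elif scheme == "holdout70":
        idx = np.arange(y.shape[0])
        tr, te = train_test_split(idx, test_size=0.3, stratify=y, random_state=seed)
        splits = [(tr, te)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows, source = [], "predict_proba"
    for fold, (tr, te) in enumerate(splits):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            raise ValueError(f"degenerate fold {fold}: a class is missing")
        model = spec.build(seed=spec.seed + fold)
        model.fit(X[tr], y[tr])
        row, source = _fold_metrics(fold, model, X[te], y[te])
        rows.append(row)
    return EvalReport(pd.DataFrame(rows), scheme, spec.family, source)


def threshold_sweep(
    approved,
    candidates,
    scores: np.ndarray,
    thresholds: Sequence[float],
    spec: ClassifierSpec,
    t_p: float = 0.95,
    seed: int = 0,
    balance: bool = True,
) -> pd.DataFrame:
    """Evaluate the pipeline tail for a grid of selection thresholds t_q.

    ``approved`` and ``candidates`` are (X, ids) blocks; ``scores`` are the
    candidates' FRUA degrees.  For each t_q the candidates are partitioned,
    a training set assembled, and the classifier evaluated under a
    stratified 70:30 holdout.  Thresholds admitting zero negatives (or not
    satisfying t_q < t_p) yield a row flagged "skipped".
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=float)
    Xc, idc = candidates
    Xc = np.asarray(Xc, dtype=float)
    rows = []
    for t_q in thresholds:
        base = {"threshold": float(t_q), "status": "ok"}
        if not 0.0 <= t_q < t_p:
            rows.append({**base, "status": "skipped", "auc": np.nan, "f1": np.nan, "gmean": np.nan})
            continue
        th = SamplingThresholds(t_p, t_q)
        prom, neg, _ = threshold_sample(s, th)
        if neg.size == 0:
            rows.append({**base, "status": "skipped", "auc": np.nan, "f1": np.nan, "gmean": np.nan})
            continue
        ts = assemble_training_set(
            approved,
            (Xc[prom], [idc[i] for i in prom]),
            (Xc[neg], [idc[i] for i in neg]),
            balance=balance,
            seed=seed,
        )
        report = evaluate(ts, spec, scheme="holdout70", seed=seed)
        m = report.means
        rows.append({**base, "auc": m["auc"], "f1": m["f1"], "gmean": m["gmean"]})
    return pd.DataFrame(rows)


def select_features_by_grouped_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_groups: int = 1,
    top_k: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Top-k features by group-averaged XGBoost + random-forest importance.

    Positives and negatives are each shuffled (seeded) and split into
    ``n_groups`` chunks; chunk i of each class forms a balanced group pair.
    Both importance learners are fit on every group pair, each importance
    vector is normalized to sum to 1, and all vectors are averaged.  The
    indices of the top-k mean importances are returned, ties broken by
    ascending index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    d = X.shape[1]
    if top_k > d:
        raise ValueError(f"top_k={top_k} exceeds n_features={d}")
    rng = np.random.default_rng(seed)
    pos = rng.permutation(np.flatnonzero(y == 1))
    neg = rng.permutation(np.flatnonzero(y == 0))
    pos_groups = np.array_split(pos, n_groups)
    neg_groups = np.array_split(neg, n_groups)
    vectors = []
    for g, (pg, ng) in enumerate(zip(pos_groups, neg_groups)):
        if pg.size == 0 or ng.size == 0:
            raise ValueError(f"group pair {g} is missing a class; reduce n_groups")
        sel = np.concatenate([pg, ng])
        Xg, yg = X[sel], y[sel]
        learners = [
            XGBClassifier(
                n_estimators=60,
                max_depth=3,
                learning_rate=0.3,
                verbosity=0,
                random_state=seed + g,
                eval_metric="logloss",
            ),
            RandomForestClassifier(
                n_estimators=100, max_features="sqrt", random_state=seed + g
            ),
        ]
        for learner in learners:
            learner.fit(Xg, yg)
            imp = np.asarray(learner.feature_importances_, dtype=float)
            total = imp.sum()
            if total > 0:
                imp = imp / total
            vectors.append(imp)
    mean_imp = np.mean(vectors, axis=0)
    order = np.lexsort((np.arange(d), -mean_imp))
    return order[:top_k]
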