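"""Task-performance classification from microstate features.

The harness mirrors a standard imbalanced-cohort protocol: balanced random
downsampling (250 epochs per group), recursive feature elimination (RFE)
repeated over re-drawn subsamples to find a stable optimal feature count,
and stratified five-fold cross-validation reporting accuracy, AUC,
sensitivity and specificity with per-fold ROC curves.

Eight classifiers are provided: logistic regression; SVM with linear,
polynomial and RBF kernels; kNN with k = 2, 5, 10; and a random forest.
Features are z-scored inside training folds only (they mix ms, Hz, % and
uV scales), and RFE rankings are likewise computed on training data only,
so no information leaks from test folds.  For models exposing coefficients
the RFE ranking is |coefficient| on standardised features; for the others
it is permutation importance (accuracy drop on a held-out validation
split when one feature is shuffled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = [
    "ClassifierSpec",
    "RFEResult",
    "ClassificationReport",
    "classifier_suite",
    "downsample_balance",
    "rfe_select",
    "crossval_evaluate",
]

POSITIVE_CLASS = "good"  # sensitivity = recall of the good-performer class


@dataclass
class ClassifierSpec:
    """A named classifier with documented default hyperparameters."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def build(self, seed: int | None = None) -> Pipeline:
        if self.kind == "logistic":
            est = LogisticRegression(max_iter=2000, **self.params)
        elif self.kind == "svm":
            est = SVC(random_state=seed, **self.params)
        elif self.kind == "knn":
            est = KNeighborsClassifier(**self.params)
        elif self.kind == "forest":
            est = RandomForestClassifier(random_state=seed, **self.params)
        else:
            raise ValueError(f"unknown classifier kind: {self.kind}")
        return Pipeline([("scale", StandardScaler()), ("model", est)])

    @property
    def has_coefficients(self) -> bool:
        return self.kind == "logistic" or (
            self.kind == "svm" and self.params.get("kernel") == "linear"
        )


def classifier_suite() -> list[ClassifierSpec]:
    """The eight classifiers: LR, SVM (lin/poly/RBF), kNN (2/5/10), RF."""
    return [
        ClassifierSpec("LR", "logistic", {"C": 1.0}),
        ClassifierSpec("SVM-Lin", "svm", {"kernel": "linear", "C": 1.0}),
        ClassifierSpec("SVM-Poly", "svm", {"kernel": "poly", "degree": 3, "C": 1.0}),
        ClassifierSpec("SVM-RBF", "svm", {"kernel": "rbf", "C": 1.0, "gamma": "scale"}),
        ClassifierSpec("kNN-2", "knn", {"n_neighbors": 2}),
        ClassifierSpec("kNN-5", "knn", {"n_neighbors": 5}),
        ClassifierSpec("kNN-10", "knn", {"n_neighbors": 10}),
        ClassifierSpec("RF", "forest", {"n_estimators": 500}),
    ]


@dataclass
class RFEResult:
    classifier: str
    feature_counts: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    optimal_count: int
    selected_features: tuple[str, ...]
    selection_frequency: pd.Series
    per_rep_selected: tuple[tuple[str, ...], ...] = ()


@dataclass
class ClassificationReport:
    classifier: str
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    fold_aucs: tuple[float, ...]
    roc_points: pd.DataFrame
    seed: int | None = None


def downsample_balance(
    table: pd.DataFrame, n_per_group: int = 250, seed: int | None = None
) -> pd.DataFrame:
    """Uniform random subset without replacement, ``n_per_group`` per group."""
    rng = np.random.default_rng(seed)
    parts = []
    for group, sub in table.groupby("group", sort=True):
        if len(sub) < n_per_group:
            raise ValueError(
                f"group '{group}' has only {len(sub)} epochs; need {n_per_group}"
            )
        idx = rng.choice(len(sub), size=n_per_group, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def _scores(pipe: Pipeline, x: np.ndarray) -> np.ndarray:
    """Continuous decision scores for ROC (margin or positive-class proba)."""
    model = pipe[-1]
    if hasattr(model, "decision_function"):
        return pipe.decision_function(x)
    proba = pipe.predict_proba(x)
    return proba[:, list(pipe.classes_).index(1)]


def _rank_features(
    spec: ClassifierSpec,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    seed: int | None,
) -> np.ndarray:
    """Importance score per feature (higher = more important), train data only."""
    if spec.has_coefficients:
        pipe = spec.build(seed)
        pipe.fit(x, y)
        return np.abs(np.ravel(pipe[-1].coef_))
    # permutation importance on a held-out third of the training data
    n = len(y)
    perm = rng.permutation(n)
    cut = max(n // 3, 2)
    val, tr = perm[:cut], perm[cut:]
    pipe = spec.build(seed)
    pipe.fit(x[tr], y[tr])
    base = (pipe.predict(x[val]) == y[val]).mean()
    drops = np.empty(x.shape[1])
    xv = x[val].copy()
    for j in range(x.shape[1]):
        saved = xv[:, j].copy()
        xv[:, j] = saved[rng.permutation(len(saved))]
        drops[j] = base - (pipe.predict(xv) == y[val]).mean()
        xv[:, j] = saved
    return drops


def _rfe_path(
    spec: ClassifierSpec,
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    x_te: np.ndarray | None,
    y_te: np.ndarray | None,
    features: list[str],
    rng: np.random.Generator,
    seed: int | None,
) -> tuple[dict[int, float], dict[int, list[str]]]:
    """One full elimination path fit on training data only.

    Returns test accuracy and the retained feature list per feature count.
    With ``x_te=None`` only the retained sets are computed (final refit).
    """
    active = list(range(x_tr.shape[1]))
    acc: dict[int, float] = {}
    kept: dict[int, list[str]] = {}
    while active:
        pipe = spec.build(seed)
        pipe.fit(x_tr[:, active], y_tr)
        if x_te is not None:
            acc[len(active)] = float((pipe.predict(x_te[:, active]) == y_te).mean())
        kept[len(active)] = [features[j] for j in active]
        if len(active) == 1:
            break
        if spec.has_coefficients:
            imp = np.abs(np.ravel(pipe[-1].coef_))
        else:
            imp = _rank_features(spec, x_tr[:, active], y_tr, rng, seed)
        active.pop(int(np.argmin(imp)))  # ties: first (stable feature order)
    return acc, kept


def _encode(table: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    x = table[features].to_numpy(dtype=float)
    y = (table["group"] == POSITIVE_CLASS).to_numpy().astype(int)
    return x, y


def rfe_select(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    n_repetitions: int = 100,
    folds: int = 5,
    seed: int | None = None,
    n_per_group: int | None = 250,
    features: list[str] | None = None,
) -> RFEResult:
    """Repeated recursive feature elimination.

    Each repetition re-draws the balanced subsample (when ``n_per_group``
    is set) and runs a fold-nested elimination: within every CV fold the
    ranking and elimination use the training part only, and the held-out
    fold is scored at each feature count — so the accuracy curve carries
    no selection bias.  The optimal count maximises the mean accuracy
    across repetitions; each repetition's reported selected set comes from
    an elimination path refit on its whole subsample, and the overall
    selected set is the most frequently retained features at the optimum.
    """
    features = features or [f for f in FEATURE_NAMES if f in table.columns]
    m = len(features)
    ss = np.random.SeedSequence(seed)
    acc = np.zeros((n_repetitions, m))  # column i: accuracy with (i+1) features
    keep_counts = pd.Series(0.0, index=features)
    rep_paths: list[dict[int, list[str]]] = []
    for rep, child in enumerate(ss.spawn(n_repetitions)):
        rng = np.random.default_rng(child)
        rep_seed = int(rng.integers(2**31 - 1))
        sub = (
            downsample_balance(table, n_per_group, seed=rep_seed)
            if n_per_group is not None
            else table
        )
        x, y = _encode(sub, list(features))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_acc = np.zeros((folds, m))
        for f_i, (tr, te) in enumerate(skf.split(x, y)):
            a, _ = _rfe_path(spec, x[tr], y[tr], x[te], y[te], list(features), rng, rep_seed)
            for count, value in a.items():
                fold_acc[f_i, count - 1] = value
        acc[rep] = fold_acc.mean(axis=0)
        _, kept = _rfe_path(spec, x, y, None, None, list(features), rng, rep_seed)
        rep_paths.append(kept)
    mean_acc = acc.mean(axis=0)
    sd_acc = acc.std(axis=0, ddof=1) if n_repetitions > 1 else np.zeros(m)
    optimal = int(np.argmax(mean_acc)) + 1
    per_rep = []
    for kept in rep_paths:
        sel = tuple(kept[optimal])
        per_rep.append(sel)
        for f in sel:
            keep_counts[f] += 1
    keep_counts /= n_repetitions
    selected = tuple(keep_counts.sort_values(ascending=False).index[:optimal])
    return RFEResult(
        classifier=spec.name,
        feature_counts=np.arange(1, m + 1),
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        optimal_count=optimal,
        selected_features=selected,
        selection_frequency=keep_counts,
        per_rep_selected=tuple(per_rep),
    )


def crossval_evaluate(
    table: pd.DataFrame,
    features: list[str],
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int | None = None,
) -> ClassificationReport:
    """Stratified k-fold evaluation of one classifier on chosen features.

    Sensitivity is the recall of the good-performer class, specificity the
    recall of the poor-performer class; AUC is the mean of per-fold AUCs
    computed from continuous decision scores.  ROC points of every fold
    are returned for plotting.
    """
    unknown = [f for f in features if f not in table.columns]
    if unknown:
        raise ValueError(f"unknown features: {unknown}")
    x, y = _encode(table, list(features))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, sens, spcs, aucs = [], [], [], []
    roc_rows = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[te])) < 2:
            raise ValueError("a fold contains a single class; re-stratify")
        pipe = spec.build(seed)
        pipe.fit(x[tr], y[tr])
        pred = pipe.predict(x[te])
        score = _scores(pipe, x[te])
        accs.append((pred == y[te]).mean())
        sens.append((pred[y[te] == 1] == 1).mean())
        spcs.append((pred[y[te] == 0] == 0).mean())
        aucs.append(roc_auc_score(y[te], score))
        fpr, tpr, _ = roc_curve(y[te], score)
        roc_rows.append(pd.DataFrame({"fold": fold, "fpr": fpr, "tpr": tpr}))
    return ClassificationReport(
        classifier=spec.name,
        accuracy=float(np.mean(accs)),
        auc=float(np.mean(aucs)),
        sensitivity=float(np.mean(sens)),
        specificity=float(np.mean(spcs)),
        fold_aucs=tuple(float(a) for a in aucs),
        roc_points=pd.concat(roc_rows, ignore_index=True),
        seed=seed,
    )
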