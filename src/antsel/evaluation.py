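"""Subset fitness evaluation: classifiers, confusion metrics, cross-validation.

The wrapper search scores a candidate feature subset by the Matthews
correlation coefficient (MCC) of a classifier under stratified k-fold
cross-validation, with confusion counts pooled across folds before the
metrics are computed (micro-averaging; per-fold averaging is available
via ``pooled=False``). A small registry of reference classifiers covers
the six broad families commonly benchmarked for this task: tree, rule,
boosted meta-ensemble, lazy (nearest-neighbour), function
(logistic / RBF) and Bayes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from antsel._seeds import derive_seed


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float, float]:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).

    A zero factor in the MCC denominator yields MCC = 0 (the standard
    convention for a degenerate margin); an empty positive (or negative)
    class makes Sn (or Sp) undefined, reported as None.
    """
    if c.total == 0:
        raise ValueError("metrics require at least one evaluated sample")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


@dataclass
class EvalReport:
    sn: float | None
    sp: float | None
    acc: float
    mcc: float
    per_fold: list[ConfusionCounts]
    classifier_name: str
    subset: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "per_fold": [asdict(c) for c in self.per_fold],
            "classifier_name": self.classifier_name,
            "subset": list(map(int, self.subset)),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


EMPTY_SUBSET_FITNESS = -1.0  # sentinel: an ant that selected nothing


def _sentinel_report(classifier_name: str) -> EvalReport:
    return EvalReport(
        sn=None,
        sp=None,
        acc=0.0,
        mcc=EMPTY_SUBSET_FITNESS,
        per_fold=[],
        classifier_name=classifier_name,
        subset=[],
    )


def classifier_registry() -> dict[str, object]:
    """Reference classifiers, one per broad family.

    Unfitted prototypes; callers clone before fitting. The rule-family
    entry is a depth-limited decision tree (an axis-aligned rule table);
    the function family contributes both a logistic model and an
    RBF-kernel machine.
    """
    return {
        "decision_tree": DecisionTreeClassifier(random_state=0),
        "rule_table": DecisionTreeClassifier(max_depth=4, random_state=0),
        "boosted_trees": AdaBoostClassifier(n_estimators=50, random_state=0),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "logistic": LogisticRegression(max_iter=1000),
        "rbf_svm": SVC(kernel="rbf", gamma="scale", random_state=0),
        "naive_bayes": GaussianNB(),
    }


def get_classifier(name: str):
    reg = classifier_registry()
    try:
        return reg[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; available: {sorted(reg)}"
        ) from None


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    classifier=None,
    k: int = 5,
    seed: int = 0,
    pooled: bool = True,
) -> EvalReport:
    """Stratified k-fold CV of a classifier restricted to a feature subset.

    ``subset`` is a binary mask over columns of X. ``k=1`` is the
    degenerate holdout: fit and score on the full data in a single pass.
    An empty subset returns the sentinel report (mcc = -1, never fitted).
    Deterministic under ``seed`` (drives the fold shuffle).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    subset = np.asarray(subset).astype(bool).ravel()
    if subset.shape[0] != X.shape[1]:
        raise ValueError(
            f"subset length {subset.shape[0]} != feature count {X.shape[1]}"
        )
    if classifier is None:
        classifier = DecisionTreeClassifier(random_state=0)
    name = type(classifier).__name__

    if not subset.any():
        return _sentinel_report(name)
    Xs = X[:, subset]

    folds: list[ConfusionCounts] = []
    if k <= 1:
        model = clone(classifier)
        model.fit(Xs, y)
        folds.append(_confusion(y, model.predict(Xs)))
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        for train, test in skf.split(Xs, y):
            if len(np.unique(y[train])) < 2:
                raise ValueError("a training fold lost one of the classes")
            model = clone(classifier)
            model.fit(Xs[train], y[train])
            folds.append(_confusion(y[test], model.predict(Xs[test])))

    if pooled:
        total = folds[0]
        for c in folds[1:]:
            total = total + c
        sn, sp, acc, mcc = metrics(total)
    else:
        per = [metrics(c) for c in folds]
        sn = float(np.mean([m[0] for m in per if m[0] is not None])) if any(
            m[0] is not None for m in per
        ) else None
        sp = float(np.mean([m[1] for m in per if m[1] is not None])) if any(
            m[1] is not None for m in per
        ) else None
        acc = float(np.mean([m[2] for m in per]))
        mcc = float(np.mean([m[3] for m in per]))
    return EvalReport(
        sn=sn,
        sp=sp,
        acc=acc,
        mcc=mcc,
        per_fold=folds,
        classifier_name=name,
        subset=np.flatnonzero(subset).tolist(),
    )


def select_best_classifier(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[str, EvalReport]:
    """Evaluate every registry classifier with all features; return the
    highest-MCC entry (ties broken by registry order)."""
    full = np.ones(np.asarray(X).shape[1], dtype=bool)
    best_name, best_report = None, None
    for name, proto in classifier_registry().items():
        report = evaluate_subset(X, y, full, classifier=proto, k=k, seed=seed)
        if best_report is None or report.mcc > best_report.mcc:
            best_name, best_report = name, report
    return best_name, best_report


class SubsetEvaluator:
    """Callable fitness function: subset mask -> cross-validated MCC.

    Wraps a dataset, a classifier prototype and CV settings; memoizes by
    subset bytes, which matters because the GA repeatedly re-proposes
    near-converged populations. The fold split is fixed by the seed, so a
    subset's fitness is a pure function of the mask.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        classifier=None,
        k: int = 5,
        seed: int = 0,
        pooled: bool = True,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int).ravel()
        self.classifier = (
            classifier
            if classifier is not None
            else DecisionTreeClassifier(random_state=0)
        )
        self.k = k
        self.seed = derive_seed(seed, "folds")
        self.pooled = pooled
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0  # classifier fits actually performed (cache misses)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def report(self, subset: np.ndarray) -> EvalReport:
        return evaluate_subset(
            self.X,
            self.y,
            subset,
            classifier=self.classifier,
            k=self.k,
            seed=self.seed,
            pooled=self.pooled,
        )

    def __call__(self, subset: np.ndarray) -> float:
        key = np.asarray(subset).astype(bool).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        mcc = self.report(subset).mcc
        self.n_evaluations += 1
        self._cache[key] = mcc
        return mcc
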