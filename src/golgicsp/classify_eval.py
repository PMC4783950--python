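"""Random-forest classification and the evaluation harness.

The classifier is an ensemble of fully grown (unpruned) decision trees,
each trained on a bootstrap sample, splitting on a random subset of m_try
features per node; a new protein is labelled by majority vote and its
positive-class score is the fraction of trees voting positive.

Evaluation follows the standard two-class protocol: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, Matthews correlation
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)), and the ROC
curve of sensitivity against 1-specificity with trapezoidal AUC.
Cross-validation is stratified k-fold by default; folds = n gives the
jackknife (leave-one-out) test.  Held-out predictions are pooled over folds
before the confusion table is formed (the canonical protocol); a per-fold
AUC average is also reported when folds are large enough to support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .imbalance import LabeledFeatureTable, smote_balance

__all__ = [
    "ForestSpec",
    "TrainedForest",
    "train_forest",
    "ConfusionCounts",
    "Metrics",
    "confusion_metrics",
    "roc_auc",
    "EvalReport",
    "cross_validate",
]

#: score at or above which a protein is called positive (cis)
DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyper-parameters.

    ``m_try`` is the number of candidate features per split; ``None`` means
    floor(sqrt(d)).  ``weka_compat`` mirrors the historical WEKA defaults
    (10 trees, floor(log2 d) + 1 candidate features).
    """

    n_trees: int = 100
    m_try: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.m_try is not None and self.m_try < 1:
            raise ValueError("m_try must be >= 1")

    @classmethod
    def weka_compat(cls, n_features: int, seed: int = 0) -> "ForestSpec":
        return cls(n_trees=10, m_try=int(np.log2(n_features)) + 1, seed=seed)

    def resolve_m_try(self, n_features: int) -> int:
        if self.m_try is None:
            return max(1, int(np.sqrt(n_features)))
        return min(self.m_try, n_features)


@dataclass
class TrainedForest:
    """A fitted forest exposing majority-vote labels and vote-fraction scores."""

    forest: RandomForestClassifier
    spec: ForestSpec

    def score_positive(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.forest.estimators_:
            votes += (tree.predict(X) == 1)
        return votes / len(self.forest.estimators_)

    def predict(self, X) -> np.ndarray:
        return (self.score_positive(X) >= DECISION_THRESHOLD).astype(int)


def train_forest(table: LabeledFeatureTable, spec: ForestSpec) -> TrainedForest:
    """Train an unpruned bootstrap forest on a labelled table."""
    n_pos, n_neg = table.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training table must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.resolve_m_try(table.n_features),
        bootstrap=True,
        random_state=spec.seed,
    )
    rf.fit(table.X, table.y)
    return TrainedForest(forest=rf, spec=spec)


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


class Metrics(NamedTuple):
    sn: float
    sp: float
    acc: float
    mcc: float
    #: names of metrics whose denominator was zero and were reported as 0
    zero_denominator: tuple[str, ...] = ()


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    A metric whose denominator is zero is reported as 0 and listed in
    ``zero_denominator``.
    """
    tp, fp, tn, fn = c
    flags: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sn = safe(tp, tp + fn, "sn")
    sp = safe(tn, tn + fp, "sp")
    acc = safe(tp + tn, tp + fp + tn + fn, "acc")
    mcc_den = np.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = safe(tp * tn - fp * fn, mcc_den, "mcc")
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc, zero_denominator=tuple(flags))


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from scores and binary labels.

    The curve is the threshold sweep over the distinct score values, as
    points (1 - Sp, Sn) from (0, 0) to (1, 1).  The trapezoidal area equals
    the Mann-Whitney concordance probability (ties counted half).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct-score boundary
    distinct = np.nonzero(np.diff(s))[0]
    cuts = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y == 1)[cuts]
    fps = np.cumsum(y == 0)[cuts]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class EvalReport:
    """Pooled evaluation result of one run (CV, jackknife or held-out test)."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    roc: np.ndarray = field(repr=False)
    auc: float = float("nan")
    zero_denominator: tuple[str, ...] = ()
    folds: int = 0
    n: int = 0
    auc_per_fold_mean: float | None = None

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, scores, folds: int = 0
    ) -> "EvalReport":
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        m = confusion_metrics(counts)
        roc, auc = roc_auc(scores, y_true)
        return cls(
            counts=counts,
            sn=m.sn,
            sp=m.sp,
            acc=m.acc,
            mcc=m.mcc,
            roc=roc,
            auc=auc,
            zero_denominator=m.zero_denominator,
            folds=folds,
            n=len(np.asarray(y_true)),
        )

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts._asdict()),
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "auc_per_fold_mean": self.auc_per_fold_mean,
            "zero_denominator": list(self.zero_denominator),
            "folds": self.folds,
            "n": self.n,
            "roc": self.roc.tolist(),
        }

    def to_text(self) -> str:
        c = self.counts
        lines = [
            f"n = {self.n}   folds = {self.folds or 'n/a'}",
            f"TP = {c.tp}  FP = {c.fp}  TN = {c.tn}  FN = {c.fn}",
            f"Sn  = {self.sn:.3f}",
            f"Sp  = {self.sp:.3f}",
            f"Acc = {self.acc:.3f}",
            f"MCC = {self.mcc:.3f}",
            f"AUC = {self.auc:.3f}",
        ]
        if self.zero_denominator:
            lines.append(f"zero-denominator metrics: {', '.join(self.zero_denominator)}")
        return "\n".join(lines)


FoldFeatureFn = Callable[[np.ndarray, np.ndarray], tuple[LabeledFeatureTable, np.ndarray]]


def _fold_indices(y: np.ndarray, folds: int, seed: int, stratified: bool):
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    if folds == n:
        return [(tr, te) for tr, te in LeaveOneOut().split(np.zeros(n))]
    if stratified:
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n), y))
    from sklearn.model_selection import KFold

    return list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.zeros(n)))


def cross_validate(
    table: LabeledFeatureTable,
    folds: int,
    seed: int,
    *,
    forest: ForestSpec | None = None,
    smote: bool = False,
    smote_k: int = 5,
    stratified: bool = True,
    fold_features: FoldFeatureFn | None = None,
    select_features: Callable[[LabeledFeatureTable, int], list[str]] | None = None,
) -> EvalReport:
    """Stratified k-fold (or jackknife, folds = n) evaluation.

    All data-dependent stages run inside each fold on the training portion
    only: ``fold_features`` (if given) rebuilds the feature table from raw
    inputs per fold (used by the pipeline to refit the CSP projection
    without leakage), then SMOTE balancing, then optional feature selection
    via ``select_features(train_table, seed) -> kept feature names``, then
    forest training.  Held-out predictions are pooled.
    """
    forest = forest or ForestSpec(seed=seed)
    y = table.y
    splits = None
    for attempt in range(10):
        candidate = _fold_indices(y, folds, seed + attempt, stratified)
        if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
            splits = candidate
            break
    if splits is None:
        raise ValueError(
            "could not form folds with both classes in every training portion"
        )

    n = table.n
    y_pred = np.empty(n, int)
    scores = np.empty(n, float)
    fold_aucs: list[float] = []
    for tr, te in splits:
        if fold_features is not None:
            train_tab, X_test = fold_features(tr, te)
        else:
            train_tab = table.subset_rows(tr)
            X_test = table.X[te]
        if smote:
            train_tab = smote_balance(train_tab, k=smote_k, seed=seed)
        if select_features is not None:
            kept = select_features(train_tab, seed)
            pos = [train_tab.feature_names.index(f) for f in kept]
            train_tab = train_tab.subset_features(kept)
            X_test = np.asarray(X_test)[:, pos]
        model = train_forest(train_tab, forest)
        sc = model.score_positive(X_test)
        scores[te] = sc
        y_pred[te] = (sc >= DECISION_THRESHOLD).astype(int)
        if len(te) > 1 and len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_auc(sc, y[te])[1])

    report = EvalReport.from_predictions(y, y_pred, scores, folds=folds)
    if fold_aucs:
        report.auc_per_fold_mean = float(np.mean(fold_aucs))
    return report
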