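"""Recursive feature elimination driven by random-forest importance (RF-RFE).

Starting from the full feature set, one forest is fitted per iteration and
the feature with the lowest importance is removed; with N features the
procedure runs N iterations and yields a complete ranking (the first
feature removed is the least important, the survivor of the last iteration
the most important).  A second pass then evaluates nested prefixes of the
ranking by cross-validation and keeps the prefix with the highest accuracy.

The default importance criterion is out-of-bag permutation importance:
for each tree, accuracy on its out-of-bag samples is compared with the
accuracy after permuting one feature column, and the drops are averaged
over trees.  Ties are broken by removing the feature with the larger
original column index, so the ranking is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify_eval import ForestSpec, train_forest
from .imbalance import LabeledFeatureTable

__all__ = ["RankList", "rf_rfe", "select_optimal_prefix"]


@dataclass(frozen=True)
class RankList:
    """Feature ranking, most important first (index 0 = last eliminated)."""

    names: tuple[str, ...]
    #: out-of-bag accuracy of the forest fitted at each elimination
    #: iteration (first entry = full feature set)
    oob_accuracy_trace: tuple[float, ...] = ()

    def top(self, k: int) -> tuple[str, ...]:
        return self.names[:k]


def _bootstrap_oob_mask(tree, n: int) -> np.ndarray:
    """Out-of-bag sample mask for one tree.

    Reconstructs the bootstrap indices the same way scikit-learn draws them
    (``RandomState(tree.random_state).randint(0, n, n)``).
    """
    rs = np.random.RandomState(tree.random_state)
    sampled = rs.randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return mask


def _oob_permutation_importance(
    trained, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Per-feature mean OOB accuracy drop under column permutation.

    Returns (importances, mean OOB accuracy of the unpermuted forest).
    """
    n, d = X.shape
    drops = np.zeros(d)
    base_accs: list[float] = []
    n_used = 0
    for tree in trained.forest.estimators_:
        oob = np.nonzero(_bootstrap_oob_mask(tree, n))[0]
        if oob.size == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y[oob]
        base = float((tree.predict(Xo) == yo).mean())
        base_accs.append(base)
        perm = rng.permutation(oob.size)
        # batch all single-column permutations into chunked predict calls
        chunk = max(1, 20000 // max(1, oob.size))
        for start in range(0, d, chunk):
            cols = range(start, min(start + chunk, d))
            stacked = np.tile(Xo, (len(cols), 1, 1))
            for b, j in enumerate(cols):
                stacked[b, :, j] = Xo[perm, j]
            preds = tree.predict(stacked.reshape(-1, d)).reshape(len(cols), -1)
            accs = (preds == yo[None, :]).mean(axis=1)
            drops[start : start + len(cols)] += base - accs
    if n_used == 0:
        raise ValueError("no out-of-bag samples; cannot compute importance")
    return drops / n_used, float(np.mean(base_accs))


def rf_rfe(
    table: LabeledFeatureTable,
    seed: int,
    forest: ForestSpec | None = None,
    criterion: str = "permutation",
) -> RankList:
    """Rank all features by iterated elimination of the least important one."""
    if table.n_features < 2:
        raise ValueError("RF-RFE needs at least 2 features")
    if len(np.unique(table.y)) < 2:
        raise ValueError("labels are constant; importance is undefined")
    if criterion not in ("permutation", "impurity"):
        raise ValueError(f"unknown criterion {criterion!r}")
    forest = forest or ForestSpec(seed=seed)
    rng = np.random.default_rng(seed)

    remaining = list(range(table.n_features))
    eliminated: list[int] = []
    trace: list[float] = []
    X_full, y = table.X, table.y
    while remaining:
        X = X_full[:, remaining]
        sub = LabeledFeatureTable(
            X=X,
            y=y,
            feature_names=tuple(table.feature_names[j] for j in remaining),
        )
        trained = train_forest(sub, forest)
        if criterion == "permutation":
            imp, oob_acc = _oob_permutation_importance(trained, X, y, rng)
        else:
            imp = trained.forest.feature_importances_
            oob_acc = float("nan")
        trace.append(oob_acc)
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        # ties: drop the feature later in canonical (original column) order
        worst_local = int(np.nonzero(imp == imp.min())[0].max())
        eliminated.append(remaining.pop(worst_local))

    ranked = tuple(table.feature_names[j] for j in reversed(eliminated))
    return RankList(names=ranked, oob_accuracy_trace=tuple(trace))


def select_optimal_prefix(
    table: LabeledFeatureTable,
    rank: RankList,
    folds: int,
    seed: int,
    forest: ForestSpec | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the prefix of the ranking with the highest CV accuracy.

    The same stratified fold partition is reused for every prefix size
    (a paired comparison), and ties go to the smallest prefix.  Returns
    ``(k_best, accuracy_curve)`` with ``accuracy_curve[k-1]`` the pooled
    k-fold accuracy of the top-k features.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    forest = forest or ForestSpec(seed=seed)
    n_feat = table.n_features
    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(np.zeros(table.n), table.y))

    col_of = {name: i for i, name in enumerate(table.feature_names)}
    order = [col_of[name] for name in rank.names]
    curve = np.empty(n_feat)
    for k in range(1, n_feat + 1):
        cols = order[:k]
        correct = 0
        for tr, te in splits:
            sub = LabeledFeatureTable(
                X=table.X[np.ix_(tr, cols)],
                y=table.y[tr],
                feature_names=tuple(rank.names[:k]),
            )
            model = train_forest(sub, forest)
            pred = model.predict(table.X[np.ix_(te, cols)])
            correct += int((pred == table.y[te]).sum())
        curve[k - 1] = correct / table.n
    k_best = int(np.argmax(curve)) + 1   # argmax takes the first (smallest k) tie
    return k_best, curve
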