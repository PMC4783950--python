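"""Labeled feature tables and SMOTE minority oversampling.

SMOTE (synthetic minority over-sampling) equalises class sizes by creating
new minority-class points along line segments between a minority point x
and one of its k nearest minority neighbours x_nn:

    x_new = x + u * (x_nn - x),   u ~ Uniform[0, 1].

Every synthetic point therefore lies inside the convex hull of the minority
class; majority rows are never touched.  Base points are cycled round-robin
so the oversampling load is spread evenly, with the non-integer remainder
assigned by a seeded shuffle (87 positives vs 217 negatives needs 130
synthetics, i.e. one full cycle plus 43 extra).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabeledFeatureTable", "smote_balance"]

PROVENANCE_REAL = "real"
PROVENANCE_SMOTE = "synthetic-SMOTE"


@dataclass(frozen=True)
class LabeledFeatureTable:
    """Feature matrix with binary labels (1 = positive/cis, 0 = negative/trans)."""

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]
    ids: tuple[str, ...] = ()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match number of rows")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match X width")
        ids = self.ids or tuple(f"row{i}" for i in range(X.shape[0]))
        prov = self.provenance or tuple(PROVENANCE_REAL for _ in range(X.shape[0]))
        if len(ids) != X.shape[0] or len(prov) != X.shape[0]:
            raise ValueError("ids/provenance length must match number of rows")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "ids", tuple(ids))
        object.__setattr__(self, "provenance", tuple(prov))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        return int((self.y == 1).sum()), int((self.y == 0).sum())

    def subset_rows(self, idx) -> "LabeledFeatureTable":
        idx = np.asarray(idx)
        return LabeledFeatureTable(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=self.feature_names,
            ids=tuple(self.ids[i] for i in idx),
            provenance=tuple(self.provenance[i] for i in idx),
        )

    def subset_features(self, names) -> "LabeledFeatureTable":
        pos = [self.feature_names.index(n) for n in names]
        return replace(
            self, X=self.X[:, pos], feature_names=tuple(names)
        )

    # -- CSV round trip -----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "id", list(self.ids))
        df["label"] = self.y
        df["provenance"] = list(self.provenance)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledFeatureTable":
        df = pd.read_csv(path)
        meta = [c for c in ("id", "label", "provenance") if c in df.columns]
        if "label" not in meta:
            raise ValueError(f"{path}: no 'label' column")
        feats = [c for c in df.columns if c not in meta]
        return cls(
            X=df[feats].to_numpy(float),
            y=df["label"].to_numpy(int),
            feature_names=tuple(feats),
            ids=tuple(map(str, df["id"])) if "id" in meta else (),
            provenance=tuple(df["provenance"]) if "provenance" in meta else (),
        )


def smote_balance(
    table: LabeledFeatureTable, k: int = 5, seed: int = 0
) -> LabeledFeatureTable:
    """Oversample the minority class to parity with SMOTE.

    Returns the input table unchanged when classes are already balanced.
    Deterministic for a fixed seed.  ``k`` is clamped (with a warning) to
    minority size minus one when the minority class is too small.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_pos, n_neg = table.class_counts()
    if n_pos == n_neg:
        return table
    minority_label = 1 if n_pos < n_neg else 0
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min < 2:
        raise ValueError(
            f"minority class has {n_min} member(s); SMOTE needs at least 2"
        )
    k_eff = min(k, n_min - 1)
    if k_eff < k:
        warnings.warn(
            f"k={k} exceeds minority size - 1; clamped to {k_eff}", stacklevel=2
        )

    rng = np.random.default_rng(seed)
    min_idx = np.nonzero(table.y == minority_label)[0]
    Xmin = table.X[min_idx]
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neighbors = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self

    need = n_maj - n_min
    cycles, remainder = divmod(need, n_min)
    bases = np.concatenate(
        [np.tile(np.arange(n_min), cycles),
         rng.permutation(n_min)[:remainder]]
    ).astype(int)

    new_rows = np.empty((need, table.n_features))
    for out, b in enumerate(bases):
        nb = neighbors[b, rng.integers(k_eff)]
        u = rng.uniform()
        new_rows[out] = Xmin[b] + u * (Xmin[nb] - Xmin[b])

    return LabeledFeatureTable(
        X=np.vstack([table.X, new_rows]),
        y=np.concatenate([table.y, np.full(need, minority_label, int)]),
        feature_names=table.feature_names,
        ids=table.ids + tuple(f"smote{i}" for i in range(need)),
        provenance=table.provenance + tuple(PROVENANCE_SMOTE for _ in range(need)),
    )
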