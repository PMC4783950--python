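"""Two-class Common Spatial Patterns (CSP) projection of evolutionary matrices.

CSP finds a linear basis in which the variance carried by one class is
maximal exactly where the variance carried by the other class is minimal.
Given per-protein 20 x 20 descriptors E, each is first summarised by its
normalised covariance

    R = E E' / trace(E E'),

class means R1bar and R2bar are formed, and their sum Rc = R1bar + R2bar is
whitened: with Rc = Uc diag(lc) Uc', the whitening map P = diag(lc)^(-1/2) Uc'
makes P Rc P' the identity.  In the whitened space S1 = P R1bar P' and
S2 = P R2bar P' share eigenvectors B, and their eigenvalues are
complementary (l1 + l2 = 1 pairwise), so the extreme eigenvectors are the
most discriminative directions.  The projection W = (B' P)' maps a
descriptor to Z = W E, and the classification features are the normalised
log variances of the 20 columns of Z:

    f_j = log( var(Z_j) / sum_i var(Z_i) ).

The log-variance ratio is invariant to a global rescaling of E, which makes
the features robust to per-protein score magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._shared import DegenerateInputError
from .pssm_features import EvoMatrix

__all__ = [
    "CSPModel",
    "normalized_covariance",
    "fit_csp",
    "csp_features",
    "csp_feature_names",
]

#: relative floor applied to eigenvalues of the composite covariance
EIGENVALUE_FLOOR = 1e-10
#: absolute floor on the variance ratio before the log
VARIANCE_RATIO_FLOOR = 1e-300

_SERIAL_VERSION = 1


def _as_matrix(m) -> np.ndarray:
    return m.values if isinstance(m, EvoMatrix) else np.asarray(m, dtype=float)


def normalized_covariance(m) -> np.ndarray:
    """R = E E' / trace(E E'); symmetric PSD with unit trace."""
    E = _as_matrix(m)
    G = E @ E.T
    t = np.trace(G)
    if not np.isfinite(t) or t <= 0.0:
        raise DegenerateInputError(
            "normalized covariance undefined: trace(E E') = "
            f"{t} (zero or non-finite descriptor)"
        )
    R = G / t
    return 0.5 * (R + R.T)


@dataclass(frozen=True)
class CSPModel:
    """A fitted CSP projection for one descriptor kind.

    ``W`` is the 20 x 20 projection matrix; ``eigvals_class1`` the
    whitened-space eigenvalues of the positive class, sorted descending
    (each in [0, 1], complementary to the negative class's eigenvalues).
    """

    kind: str
    W: np.ndarray = field(repr=False)
    eigvals_class1: np.ndarray = field(repr=False)
    fitted_on: tuple[int, int] = (0, 0)
    orientation: str = "paper"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        ev = np.asarray(self.eigvals_class1, dtype=float)
        if W.shape != (20, 20):
            raise ValueError(f"W must be 20 x 20, got {W.shape}")
        if ev.shape != (20,):
            raise ValueError(f"need 20 eigenvalues, got {ev.shape}")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "eigvals_class1", ev)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "golgicsp-csp-model",
            "version": _SERIAL_VERSION,
            "kind": self.kind,
            "orientation": self.orientation,
            "W_row_major": self.W.reshape(-1).tolist(),
            "eigvals_class1": self.eigvals_class1.tolist(),
            "fitted_on": {"n_class1": self.fitted_on[0], "n_class2": self.fitted_on[1]},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSPModel":
        if d.get("format") != "golgicsp-csp-model":
            raise ValueError("not a CSP model document")
        return cls(
            kind=d["kind"],
            W=np.asarray(d["W_row_major"], dtype=float).reshape(20, 20),
            eigvals_class1=np.asarray(d["eigvals_class1"], dtype=float),
            fitted_on=(d["fitted_on"]["n_class1"], d["fitted_on"]["n_class2"]),
            orientation=d.get("orientation", "paper"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "CSPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sign_fix_columns(B: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the first non-zero entry is positive."""
    B = B.copy()
    for j in range(B.shape[1]):
        col = B[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            B[:, j] = -col
    return B


def fit_csp(class1, class2, orientation: str = "paper") -> CSPModel:
    """Fit the CSP projection from two classes of EvoMatrices.

    Parameters
    ----------
    class1, class2 : lists of EvoMatrix (or bare 20 x 20 arrays)
        The positive (cis) and negative (trans) training descriptors; all
        must share the same kind.
    orientation : ``"paper"`` or ``"standard"``
        ``"paper"`` stores W = (B' P)' and takes column variances of
        Z = W E; ``"standard"`` stores W = B' P and takes row variances.
        The two differ only in which axis of Z is read out.
    """
    if not class1 or not class2:
        raise ValueError("both classes must be non-empty")
    if orientation not in ("paper", "standard"):
        raise ValueError(f"unknown orientation {orientation!r}")
    kinds = {m.kind for m in class1 + class2 if isinstance(m, EvoMatrix)}
    if len(kinds) > 1:
        raise ValueError(f"mixed descriptor kinds in CSP fit: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "raw"

    R1 = np.mean([normalized_covariance(m) for m in class1], axis=0)
    R2 = np.mean([normalized_covariance(m) for m in class2], axis=0)
    Rc = R1 + R2

    lc, Uc = np.linalg.eigh(Rc)
    if not np.all(np.isfinite(lc)) or lc.max() <= 0:
        raise DegenerateInputError("composite covariance is zero or non-finite")
    floor = EIGENVALUE_FLOOR * lc.max()
    n_deficient = int(np.sum(lc < floor))
    if n_deficient:
        # keep going with a floored inverse; a severely rank-deficient
        # composite is still reported in the raised diagnostics downstream
        cond = lc.max() / max(lc.min(), np.finfo(float).tiny)
        if lc.min() <= 0:
            raise DegenerateInputError(
                f"composite covariance rank-deficient: {n_deficient} eigenvalues "
                f"below floor, condition number ~{cond:.3e}"
            )
        lc = np.maximum(lc, floor)

    P = np.diag(lc ** -0.5) @ Uc.T          # whitening: P Rc P' = I
    S1 = P @ R1 @ P.T
    S1 = 0.5 * (S1 + S1.T)
    l1, B = np.linalg.eigh(S1)
    order = np.argsort(l1)[::-1]            # descending class-1 eigenvalues
    l1 = l1[order]
    B = _sign_fix_columns(B[:, order])

    WT = B.T @ P                            # rows project; W = (B' P)'
    W = WT.T if orientation == "paper" else WT
    return CSPModel(
        kind=kind,
        W=W,
        eigvals_class1=np.clip(l1, 0.0, 1.0),
        fitted_on=(len(class1), len(class2)),
        orientation=orientation,
    )


def csp_features(model: CSPModel, m) -> np.ndarray:
    """Normalised log-variance features of the projected descriptor.

    Returns the 20-vector f_j = log(var(Z_j) / sum_i var(Z_i)) where Z_j is
    the j-th column (paper orientation) or row (standard orientation) of
    Z = W E.  Population variance (divide by 20) is used throughout; the
    estimator choice cancels in the ratio.
    """
    E = _as_matrix(m)
    if isinstance(m, EvoMatrix) and model.kind not in ("raw", m.kind):
        raise ValueError(
            f"model fitted on {model.kind} applied to {m.kind} descriptor"
        )
    Z = model.W @ E
    axis = 0 if model.orientation == "paper" else 1
    var = Z.var(axis=axis)                  # population variance
    total = var.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateInputError(
            "projected descriptor has zero total variance; features undefined"
        )
    ratio = np.maximum(var / total, VARIANCE_RATIO_FLOOR)
    return np.log(ratio)


def csp_feature_names(kind: str) -> list[str]:
    return [f"CSP-{kind}_f{j + 1}" for j in range(20)]
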