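"""PSI-BLAST ASCII PSSM parsing and the three 20x20 evolutionary descriptors.

A position-specific scoring matrix (PSSM) is an L x 20 profile of log-odds
substitution scores produced by iterative homology search; entry E[i, j] is
the score for amino acid j at position i of the query.  Three fixed-size
descriptors condense a profile into a 20 x 20 matrix:

PSSM-DC
    Rows grouped by the query residue: entry (a, b) sums E[i, b] over all
    positions i whose query residue is a, divided by L.
Bi-gram
    B[m, n] = sum_{i=1..L-1} E[i, m] * E[i+1, n] — products of scores at
    consecutive positions.
ED (evolutionary difference)
    e[m, n] = mean over interior positions i of (E[i-1, m] - E[i+1, n])^2 —
    squared score differences two positions apart.

All in-memory matrices use alphabetical amino-acid column order; the parser
converts from PSI-BLAST's native column order on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._shared import (
    AA_ALPHABETICAL,
    AA_PSIBLAST,
    DIPEPTIDES,
    PSIBLAST_TO_ALPHA,
    InvalidLengthError,
    ParseError,
)

__all__ = [
    "PSSMProfile",
    "EvoMatrix",
    "read_ascii_pssm",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "format_ascii_pssm",
    "pssm_dc",
    "bigram_pssm",
    "ed_pssm",
    "flatten_evo_matrix",
    "evo_feature_names",
]

#: descriptor kinds
KIND_PSSM_DC = "PSSM-DC"
KIND_BIGRAM = "BIGRAM"
KIND_ED = "ED"


@dataclass(frozen=True)
class PSSMProfile:
    """An L x 20 profile of per-position substitution scores.

    ``scores[i, j]`` is the score of amino acid j (alphabetical order) at
    position i; ``residue_at`` is the query sequence read from the file.
    """

    id: str
    scores: np.ndarray = field(repr=False)
    residue_at: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got {s.shape}")
        if s.shape[0] < 3:
            raise InvalidLengthError(
                f"{self.id}: profile has {s.shape[0]} positions, need >= 3"
            )
        if len(self.residue_at) != s.shape[0]:
            raise ValueError(
                f"{self.id}: residue string length {len(self.residue_at)} "
                f"!= profile length {s.shape[0]}"
            )
        if not np.all(np.isfinite(s)):
            raise ValueError(f"{self.id}: non-finite scores")
        object.__setattr__(self, "scores", s)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class EvoMatrix:
    """A 20 x 20 matrix descriptor of one protein."""

    kind: str
    values: np.ndarray = field(repr=False)
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError(f"EvoMatrix must be 20 x 20, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.id}: non-finite descriptor entries")
        if self.kind == KIND_ED and np.any(v < 0):
            raise ValueError(f"{self.id}: ED descriptor must be non-negative")
        object.__setattr__(self, "values", v)


# --------------------------------------------------------------------------
# ASCII PSSM I/O (PSI-BLAST -out_ascii_pssm layout)
# --------------------------------------------------------------------------

def parse_ascii_pssm(text: str, id: str = "") -> PSSMProfile:
    """Parse the text of a PSI-BLAST ASCII PSSM file.

    Only the first block of 20 columns (log-odds scores) is kept; columns
    are re-ordered from PSI-BLAST order to alphabetical order.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(text.splitlines(), start=1):
        tok = line.split()
        if len(tok) < 2 or not tok[0].lstrip("-").isdigit():
            continue
        pos = int(tok[0])
        if pos != expected_pos:
            # trailing statistics lines can start with digits; stop at the
            # first break in the position numbering after the matrix block
            if rows:
                break
            continue
        if len(tok[1]) != 1 or not tok[1].isalpha():
            raise ParseError(f"{id or '<pssm>'}: line {lineno}: bad residue {tok[1]!r}")
        if len(tok) < 22:
            raise ParseError(
                f"{id or '<pssm>'}: line {lineno}: truncated row "
                f"({len(tok) - 2} score columns, need 20)"
            )
        try:
            scores = [float(t) for t in tok[2:22]]
        except ValueError as exc:
            raise ParseError(
                f"{id or '<pssm>'}: line {lineno}: non-numeric score cell ({exc})"
            ) from None
        rows.append(scores)
        residues.append(tok[1].upper())
        expected_pos += 1
    if len(rows) < 3:
        raise ParseError(
            f"{id or '<pssm>'}: found {len(rows)} matrix rows, need >= 3"
        )
    raw = np.asarray(rows, dtype=float)
    alpha = raw[:, PSIBLAST_TO_ALPHA]
    return PSSMProfile(id=id, scores=alpha, residue_at="".join(residues))


def read_ascii_pssm(path) -> PSSMProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file."""
    p = Path(path)
    return parse_ascii_pssm(p.read_text(), id=p.stem)


def format_ascii_pssm(profile: PSSMProfile) -> str:
    """Render a profile in the PSI-BLAST ASCII layout (used for fixtures).

    Scores are written in PSI-BLAST column order with a zero
    weighted-percentage block and plausible trailing statistics, so the
    output round-trips through :func:`parse_ascii_pssm`.
    """
    alpha_to_psiblast = [AA_ALPHABETICAL.index(aa) for aa in AA_PSIBLAST]
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(AA_PSIBLAST) + "   " + "   ".join(AA_PSIBLAST),
    ]
    for i in range(profile.length):
        row = profile.scores[i, alpha_to_psiblast]
        cells = " ".join(f"{v:4.0f}" if float(v).is_integer() else f"{v:6.2f}" for v in row)
        pct = " ".join("   0" for _ in range(20))
        lines.append(f"{i + 1:5d} {profile.residue_at[i]}  {cells}  {pct}  0.00 0.00")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1337     0.3172",
        "",
    ]
    return "\n".join(lines)


def write_ascii_pssm(profile: PSSMProfile, path) -> None:
    Path(path).write_text(format_ascii_pssm(profile))


# --------------------------------------------------------------------------
# Descriptors
# --------------------------------------------------------------------------

def _scaled(profile: PSSMProfile, scale: str) -> np.ndarray:
    if scale == "raw":
        return profile.scores
    if scale == "sigmoid":
        return 1.0 / (1.0 + np.exp(-profile.scores))
    raise ValueError(f"unknown pssm scale {scale!r} (use 'raw' or 'sigmoid')")


def pssm_dc(profile: PSSMProfile, scale: str = "raw") -> EvoMatrix:
    """Dipeptide-composition-style condensation of a PSSM.

    Entry (a, b) is the sum of scores in column b over all positions whose
    query residue is a, divided by the sequence length L.  Positions whose
    query residue is non-standard contribute to no row but still count in L.
    """
    E = _scaled(profile, scale)
    L = profile.length
    out = np.zeros((20, 20))
    for i, r in enumerate(profile.residue_at):
        a = AA_ALPHABETICAL.find(r)
        if a >= 0:
            out[a] += E[i]
    return EvoMatrix(kind=KIND_PSSM_DC, values=out / L, id=profile.id)


def bigram_pssm(profile: PSSMProfile, scale: str = "raw") -> EvoMatrix:
    """B[m, n] = sum over consecutive position pairs of E[i, m] * E[i+1, n]."""
    E = _scaled(profile, scale)
    if profile.length < 2:
        raise InvalidLengthError(f"{profile.id}: bigram needs L >= 2")
    B = E[:-1].T @ E[1:]
    return EvoMatrix(kind=KIND_BIGRAM, values=B, id=profile.id)


def ed_pssm(profile: PSSMProfile, scale: str = "raw") -> EvoMatrix:
    """Evolutionary-difference descriptor.

    e[m, n] = (1 / (L - 2)) * sum over interior positions i (1-based
    2..L-1) of (E[i-1, m] - E[i+1, n])^2 — the mean squared difference
    between scores two positions apart.  Expanded into three Gram-style
    terms for speed; equals the direct double loop exactly.
    """
    E = _scaled(profile, scale)
    L = profile.length
    if L < 3:
        raise InvalidLengthError(f"{profile.id}: ED descriptor needs L >= 3")
    A = E[: L - 2]       # E[i-1] for interior i
    C = E[2:L]           # E[i+1] for interior i
    sq_a = (A ** 2).sum(axis=0)
    sq_c = (C ** 2).sum(axis=0)
    cross = A.T @ C
    e = sq_a[:, None] + sq_c[None, :] - 2.0 * cross
    e = np.maximum(e, 0.0) / (L - 2)
    return EvoMatrix(kind=KIND_ED, values=e, id=profile.id)


def flatten_evo_matrix(m: EvoMatrix) -> np.ndarray:
    """Row-major 400-vector view of a 20 x 20 descriptor."""
    return m.values.reshape(400).copy()


def evo_feature_names(kind: str) -> list[str]:
    return [f"{kind}_{dp}" for dp in DIPEPTIDES]
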