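"""Synthetic two-class datasets for exercising every pipeline stage offline.

The generator emulates the shape of a real cis/trans Golgi benchmark —
two unequal classes of protein sequences (default 87 positives vs 217
negatives) with one PSI-BLAST-style profile per sequence — while making
the class difference a single dial:

Sequences
    Each class draws residues from its own first-order Markov chain over
    the 20 standard amino acids.  The two chains share a common base
    transition matrix whose log-probabilities are nudged in opposite
    directions by a fixed template matrix scaled by the separation ``s``;
    at ``s = 0`` the classes are statistically identical.
Profiles
    Each class draws its L x 20 score rows as Gaussians with a
    class-specific 20 x 20 column covariance.  The two covariances are a
    common eigen-spectrum carried by bases rotated apart by ``s`` (plus a
    spectrum swap that grows with ``s``), so the classes differ in
    covariance structure — exactly the signal a CSP projection detects —
    with iid noise of scale sigma on top.  Scores are quantised to
    integers in [-10, 10], matching PSI-BLAST ASCII conventions, and each
    profile is passed through the ASCII writer and parser so the format
    round-trip is exercised on every generated dataset.

All randomness flows from ``SynthSpec.seed``; the covariance and Markov
templates come from a fixed internal seed so that ``s`` means the same
thing for every dataset seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from ._shared import AA_ALPHABETICAL
from .pssm_features import PSSMProfile, format_ascii_pssm, parse_ascii_pssm, write_ascii_pssm
from .seq_features import ProteinSequence, write_fasta

__all__ = ["SynthSpec", "generate_sequences", "generate_pssms", "emit_fixture_dir"]

#: fixed seed for the class-difference templates (documented, not tunable)
_TEMPLATE_SEED = 424_242
#: integer quantisation range of ASCII PSSM scores
_SCORE_RANGE = 10
#: pre-quantisation scale applied to the Gaussian scores
_SCORE_SCALE = 2.5


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the real benchmark's shape: 87 positive (cis) vs 217
    negative (trans) proteins.  ``separation`` >= 0 scales the class
    difference (0 = identical classes); ``noise`` is the iid score noise
    scale sigma.
    """

    n_pos: int = 87
    n_neg: int = 217
    length_range: tuple[int, int] = (60, 120)
    separation: float = 1.0
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each class needs at least 2 members")
        lmin, lmax = self.length_range
        if lmin < 3 or lmax < lmin:
            raise ValueError(f"bad length range {self.length_range}")
        if self.separation < 0 or self.noise < 0:
            raise ValueError("separation and noise must be >= 0")


def _markov_chains(s: float) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional transition matrices, identical at s = 0.

    The class difference mixes a per-residue usage bias (which shifts the
    stationary distribution and therefore shows up at every gap distance)
    with a transition-structure perturbation (local order only).
    """
    trng = np.random.default_rng(_TEMPLATE_SEED)
    base = trng.dirichlet(np.full(20, 5.0), size=20)       # rows sum to 1
    direction = trng.normal(size=(20, 20))
    bias = trng.normal(size=20)
    logits = np.log(base)
    delta = 0.7 * bias[None, :] + 0.3 * direction

    def soften(sign: float) -> np.ndarray:
        z = logits + sign * 0.5 * s * delta
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    return soften(1.0), soften(-1.0)


def _covariances(s: float) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional 20 x 20 column covariances, identical at s = 0.

    A common spectrum is carried by bases rotated apart by s, and the
    spectrum itself is partially reversed for the second class as s grows,
    so both the orientation and the per-axis energies diverge.
    """
    trng = np.random.default_rng(_TEMPLATE_SEED + 1)
    spectrum = np.geomspace(6.0, 0.3, 20)
    A = trng.normal(size=(20, 20))
    Q0, _ = np.linalg.qr(A)
    K = trng.normal(size=(20, 20))
    K = (K - K.T) / np.sqrt(2)                              # skew-symmetric

    w = s / (4.0 + s)                                       # in [0, 1)
    spec1 = spectrum
    spec2 = (1 - w) * spectrum + w * spectrum[::-1]
    Q1 = Q0 @ expm(0.1 * s * K)
    Q2 = Q0 @ expm(-0.1 * s * K)
    cov1 = Q1 @ np.diag(spec1) @ Q1.T
    cov2 = Q2 @ np.diag(spec2) @ Q2.T
    return cov1, cov2


def _sample_sequence(rng, T_cum: np.ndarray, length: int) -> str:
    state = int(rng.integers(20))
    out = [state]
    u = rng.random(length - 1)
    for i in range(length - 1):
        state = int(np.searchsorted(T_cum[state], u[i]))
        out.append(state)
    return "".join(AA_ALPHABETICAL[i] for i in out)


def generate_sequences(
    spec: SynthSpec,
) -> tuple[list[ProteinSequence], np.ndarray]:
    """Two-class sequences from class-conditional Markov chains.

    Returns ``(sequences, labels)`` with label 1 for the positive class.
    Positives come first; order within class is generation order.
    """
    rng = np.random.default_rng(spec.seed)
    T_pos, T_neg = _markov_chains(spec.separation)
    lmin, lmax = spec.length_range
    seqs: list[ProteinSequence] = []
    labels: list[int] = []
    for cls, n, T in ((1, spec.n_pos, T_pos), (0, spec.n_neg, T_neg)):
        tag = "cis" if cls == 1 else "trans"
        cum = np.cumsum(T, axis=1)
        cum[:, -1] = 1.0            # guard against rounding in searchsorted
        for i in range(n):
            L = int(rng.integers(lmin, lmax + 1))
            seqs.append(
                ProteinSequence(id=f"{tag}{i:04d}", residues=_sample_sequence(rng, cum, L))
            )
            labels.append(cls)
    return seqs, np.asarray(labels, int)


def generate_pssms(
    spec: SynthSpec, sequences: list[ProteinSequence] | None = None
) -> tuple[list[PSSMProfile], np.ndarray]:
    """Two-class integer-quantised profiles with class-specific covariance.

    If ``sequences`` is given (matching the requested class sizes, positives
    first) the profiles take their lengths and query residues from them;
    otherwise fresh sequences are generated first.  Every profile is
    rendered to ASCII PSSM text and re-parsed before being returned.
    """
    if sequences is None:
        sequences, labels = generate_sequences(spec)
    else:
        labels = np.asarray(
            [1] * spec.n_pos + [0] * spec.n_neg, int
        )
        if len(sequences) != len(labels):
            raise ValueError("sequence list does not match spec class sizes")
    rng = np.random.default_rng(spec.seed + 1)
    cov1, cov2 = _covariances(spec.separation)
    roots = {
        1: np.linalg.cholesky(cov1 + 1e-9 * np.eye(20)),
        0: np.linalg.cholesky(cov2 + 1e-9 * np.eye(20)),
    }
    profiles: list[PSSMProfile] = []
    for seq, cls in zip(sequences, labels):
        L = seq.length
        scores = rng.normal(size=(L, 20)) @ roots[cls].T
        scores += spec.noise * rng.normal(size=(L, 20))
        q = np.clip(np.rint(_SCORE_SCALE * scores), -_SCORE_RANGE, _SCORE_RANGE)
        prof = PSSMProfile(id=seq.id, scores=q, residue_at=seq.residues)
        profiles.append(parse_ascii_pssm(format_ascii_pssm(prof), id=prof.id))
    return profiles, labels


def emit_fixture_dir(spec: SynthSpec, outdir) -> Path:
    """Write FASTA + per-protein ASCII PSSMs + labels.csv into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqs, labels = generate_sequences(spec)
    profiles, _ = generate_pssms(spec, sequences=seqs)
    write_fasta(seqs, out / "sequences.fasta")
    pssm_dir = out / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for prof in profiles:
        write_ascii_pssm(prof, pssm_dir / f"{prof.id}.pssm")
    with open(out / "labels.csv", "w") as fh:
        fh.write("id,label\n")
        for seq, y in zip(seqs, labels):
            fh.write(f"{seq.id},{int(y)}\n")
    return out
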