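"""Sequence-composition descriptors: amino-acid frequencies and g-gap dipeptides.

The g-gap dipeptide composition of a protein of length ``L`` counts, for
every ordered pair of standard residues ``(a, b)``, the positions ``i`` such
that residue ``i`` is ``a`` and residue ``i + g + 1`` is ``b`` (``g``
intervening residues), and normalises by the number of available positions
``L - g - 1``.  The result is a 400-vector of frequencies indexed by the
dipeptides in alphabetical, first-residue-major order (AA, AC, ..., YY).

Dipeptides touching a non-standard residue (B, J, O, U, X, Z) are not
counted, but the denominator stays ``L - g - 1`` so that frequencies remain
comparable across proteins; for fully standard sequences the 400 entries
sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._shared import (
    AA_ALPHABETICAL,
    AA_INDEX,
    DIPEPTIDES,
    InvalidLengthError,
    ParseError,
)

__all__ = [
    "ProteinSequence",
    "GapDipeptideVector",
    "AAFrequencyProfile",
    "read_fasta",
    "write_fasta",
    "gap_dipeptide_composition",
    "class_aa_frequencies",
    "aa_frequency_comparison",
    "gap_dc_feature_names",
]


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the one-letter amino-acid alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record with empty id")
        if not self.residues:
            raise ParseError(f"protein record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def nonstandard_positions(self) -> tuple[int, ...]:
        """0-based positions holding non-standard letters (B,J,O,U,X,Z...)."""
        return tuple(
            i for i, r in enumerate(self.residues) if r not in AA_INDEX
        )


@dataclass(frozen=True)
class GapDipeptideVector:
    """400 g-gap dipeptide frequencies, alphabetical first-residue-major order."""

    g: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (400,):
            raise ValueError(f"expected 400 frequencies, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def names(self) -> list[str]:
        return [f"g{self.g}DC_{dp}" for dp in DIPEPTIDES]


@dataclass(frozen=True)
class AAFrequencyProfile:
    """20 amino-acid frequencies (per protein, or averaged over a class)."""

    frequencies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.frequencies, dtype=float)
        if v.shape != (20,):
            raise ValueError(f"expected 20 frequencies, got shape {v.shape}")
        object.__setattr__(self, "frequencies", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AA_ALPHABETICAL, self.frequencies.tolist()))


def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence` (order kept).

    Residues are upper-cased.  An empty file yields an empty list; a record
    with an empty id or empty sequence raises :class:`ParseError` naming it.
    """
    seqs: list[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record #{len(seqs) + 1} has no id")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: FASTA record {rec.id!r} has an empty sequence")
        seqs.append(ProteinSequence(id=rec.id, residues=str(rec.seq)))
    return seqs


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def gap_dipeptide_composition(seq: ProteinSequence, g: int) -> GapDipeptideVector:
    """Compute the g-gap dipeptide composition F^g of a protein.

    Parameters
    ----------
    seq : ProteinSequence
    g : int
        Number of intervening residues between the two members of each
        dipeptide; ``g = 0`` gives the adjoining dipeptide composition.

    Returns
    -------
    GapDipeptideVector
        f_i = n_i / (L - g - 1) for each of the 400 ordered pairs.
    """
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    L = seq.length
    if L < g + 2:
        raise InvalidLengthError(
            f"{seq.id}: length {L} < g + 2 = {g + 2}; cannot form {g}-gap dipeptides"
        )
    first = np.fromiter(
        (AA_INDEX.get(r, -1) for r in seq.residues[: L - g - 1]), dtype=np.int64
    )
    second = np.fromiter(
        (AA_INDEX.get(r, -1) for r in seq.residues[g + 1 :]), dtype=np.int64
    )
    ok = (first >= 0) & (second >= 0)
    counts = np.bincount(first[ok] * 20 + second[ok], minlength=400).astype(float)
    return GapDipeptideVector(g=g, values=counts / (L - g - 1))


def _per_protein_frequencies(seq: ProteinSequence) -> np.ndarray:
    idx = np.fromiter(
        (AA_INDEX.get(r, -1) for r in seq.residues), dtype=np.int64
    )
    idx = idx[idx >= 0]
    if idx.size == 0:
        raise ValueError(f"{seq.id}: no standard residues to count")
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / counts.sum()


def class_aa_frequencies(seqs: list[ProteinSequence]) -> AAFrequencyProfile:
    """Average per-protein amino-acid frequencies over a set of proteins.

    Each protein contributes its own frequency vector (over standard
    residues only), and the class profile is the unweighted mean of those
    vectors, so short and long proteins count equally.
    """
    if not seqs:
        raise ValueError("class_aa_frequencies requires a non-empty list")
    freqs = np.stack([_per_protein_frequencies(s) for s in seqs])
    return AAFrequencyProfile(frequencies=freqs.mean(axis=0))


def aa_frequency_comparison(
    seqs: list[ProteinSequence], labels
) -> dict[int, AAFrequencyProfile]:
    """Per-class average amino-acid frequency profiles (positive vs negative)."""
    labels = np.asarray(labels)
    if len(labels) != len(seqs):
        raise ValueError("labels length must match number of sequences")
    out: dict[int, AAFrequencyProfile] = {}
    for cls in np.unique(labels):
        members = [s for s, y in zip(seqs, labels) if y == cls]
        out[int(cls)] = class_aa_frequencies(members)
    return out


def gap_dc_feature_names(g: int) -> list[str]:
    return [f"g{g}DC_{dp}" for dp in DIPEPTIDES]
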