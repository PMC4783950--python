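"""Shared constants and exception types.

Amino-acid orderings
--------------------
Two single-letter orderings matter throughout the package:

* ``AA_ALPHABETICAL`` — the 20 standard amino acids in alphabetical order
  (A C D E F G H I K L M N P Q R S T V W Y).  All in-memory matrices and
  feature vectors use this order.
* ``AA_PSIBLAST`` — the column order PSI-BLAST uses in its ASCII PSSM
  output (A R N D C Q E G H I L K M F P S T W Y V).  Only the PSSM parser
  and writer touch this order.
"""

from __future__ import annotations

AA_ALPHABETICAL: str = "ACDEFGHIKLMNPQRSTVWY"
AA_PSIBLAST: str = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard one-letter codes that may occur in real records.
NONSTANDARD_AA: frozenset[str] = frozenset("BJOUXZ")

#: index of each standard amino acid in the alphabetical order
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABETICAL)}

#: the 400 ordered dipeptides, first residue major (AA, AC, ..., YY)
DIPEPTIDES: list[str] = [a + b for a in AA_ALPHABETICAL for b in AA_ALPHABETICAL]

#: permutation p such that alphabetical column j equals PSI-BLAST column p[j]
PSIBLAST_TO_ALPHA: list[int] = [AA_PSIBLAST.index(aa) for aa in AA_ALPHABETICAL]


class GolgiCSPError(Exception):
    """Base class for package errors."""


class ParseError(GolgiCSPError):
    """A FASTA or ASCII-PSSM file could not be parsed."""


class InvalidLengthError(GolgiCSPError):
    """Sequence or profile too short for the requested descriptor."""


class DegenerateInputError(GolgiCSPError):
    """Numerically degenerate input (zero matrix, constant projection, ...)."""
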