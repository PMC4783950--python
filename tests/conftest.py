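import numpy as np
import pytest

from golgicsp.imbalance import LabeledFeatureTable
from golgicsp.pssm_features import PSSMProfile
from golgicsp.seq_features import ProteinSequence

from golgicsp._shared import AA_ALPHABETICAL


def random_sequence(rng, length: int, alphabet: str = AA_ALPHABETICAL) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def random_profile(rng, length: int, id: str = "p", integer: bool = False) -> PSSMProfile:
    scores = rng.normal(scale=3.0, size=(length, 20))
    if integer:
        scores = np.clip(np.rint(scores), -10, 10)
    return PSSMProfile(
        id=id, scores=scores, residue_at=random_sequence(rng, length)
    )


def random_table(rng, n: int, d: int, *, informative: int = 0, flip: float = 0.0):
    """Binary-labelled Gaussian table; first `informative` columns shift by class."""
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, d))
    if informative:
        X[:, :informative] += 2.0 * y[:, None]
    if flip:
        swap = rng.random(n) < flip
        y[swap] = 1 - y[swap]
    return LabeledFeatureTable(
        X=X, y=y, feature_names=tuple(f"f{i}" for i in range(d))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protein():
    return ProteinSequence(id="p1", residues="ACDEFGHIKLMNPQRSTVWY")
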