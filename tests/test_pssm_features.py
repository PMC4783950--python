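"""ASCII PSSM parsing and the three 20x20 evolutionary descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golgicsp import (
    InvalidLengthError,
    ParseError,
    PSSMProfile,
    bigram_pssm,
    ed_pssm,
    flatten_evo_matrix,
    parse_ascii_pssm,
    pssm_dc,
    read_ascii_pssm,
    write_ascii_pssm,
)
from golgicsp._shared import AA_ALPHABETICAL, AA_PSIBLAST
from golgicsp.pssm_features import format_ascii_pssm

from conftest import random_profile


def _ascii_fixture(rows: list[tuple[str, list[int]]]) -> str:
    """Minimal PSI-BLAST-style ASCII text with given (residue, 20 scores) rows."""
    head = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(AA_PSIBLAST) + "   " + "   ".join(AA_PSIBLAST),
    ]
    body = [
        f"{i + 1:5d} {res}  "
        + " ".join(f"{v:3d}" for v in scores)
        + "  "
        + " ".join("0" for _ in range(20))
        + "  0.30 0.09"
        for i, (res, scores) in enumerate(rows)
    ]
    tail = ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3172"]
    return "\n".join(head + body + tail)


class TestAsciiParsing:
    def test_zero_matrix_fixture(self):
        text = _ascii_fixture([("A", [0] * 20), ("C", [0] * 20), ("D", [0] * 20)])
        prof = parse_ascii_pssm(text, id="z")
        assert prof.scores.shape == (3, 20)
        assert np.all(prof.scores == 0)
        assert prof.residue_at == "ACD"

    def test_column_reordering_permutation(self):
        # scores 1..20 laid out in PSI-BLAST column order A R N D C Q E ...
        row = list(range(1, 21))
        text = _ascii_fixture([("A", row)] * 3)
        prof = parse_ascii_pssm(text, id="perm")
        a = AA_ALPHABETICAL.index("A")
        c = AA_ALPHABETICAL.index("C")
        assert prof.scores[0, a] == 1          # A is 1st in PSI-BLAST order
        assert prof.scores[0, c] == 5          # C is 5th in PSI-BLAST order
        # full permutation oracle from the two published orders
        for j, aa in enumerate(AA_ALPHABETICAL):
            assert prof.scores[0, j] == AA_PSIBLAST.index(aa) + 1

    def test_writer_reader_round_trip_is_identity(self, rng, tmp_path):
        for i in range(10):
            prof = random_profile(rng, int(rng.integers(3, 40)), id=f"p{i}", integer=True)
            path = tmp_path / f"p{i}.pssm"
            write_ascii_pssm(prof, path)
            back = read_ascii_pssm(path)
            np.testing.assert_array_equal(back.scores, prof.scores)
            assert back.residue_at == prof.residue_at

    def test_truncated_row_reports_line_number(self):
        text = _ascii_fixture([("A", [0] * 20)] * 3)
        lines = text.splitlines()
        lines[4] = "    2 C   1 2 3"           # only 3 score columns
        with pytest.raises(ParseError, match="line 5"):
            parse_ascii_pssm("\n".join(lines), id="t")

    def test_too_few_rows_rejected(self):
        text = _ascii_fixture([("A", [0] * 20), ("C", [0] * 20)])
        with pytest.raises(ParseError, match="need >= 3"):
            parse_ascii_pssm(text, id="short")


class TestPssmDC:
    def test_zero_profile_gives_zero_matrix(self):
        prof = PSSMProfile(id="z", scores=np.zeros((4, 20)), residue_at="ACDA")
        assert np.all(pssm_dc(prof).values == 0)

    def test_grouping_by_query_residue_hand_example(self):
        # residues "AC" + padding row of zeros (profiles need L >= 3):
        # row 1 (query A) is a unit vector at D, row 2 (query C) unit at A
        E = np.zeros((3, 20))
        E[0, AA_ALPHABETICAL.index("D")] = 1.0
        E[1, AA_ALPHABETICAL.index("A")] = 1.0
        prof = PSSMProfile(id="h", scores=E, residue_at="ACX")
        m = pssm_dc(prof).values
        a, c, d = (AA_ALPHABETICAL.index(x) for x in "ACD")
        assert m[a, d] == pytest.approx(1 / 3)     # divided by L = 3
        assert m[c, a] == pytest.approx(1 / 3)
        assert np.count_nonzero(m) == 2

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            prof = random_profile(rng, int(rng.integers(3, 25)))
            got = pssm_dc(prof).values
            expected = np.zeros((20, 20))
            for i, r in enumerate(prof.residue_at):
                if r in AA_ALPHABETICAL:
                    expected[AA_ALPHABETICAL.index(r)] += prof.scores[i]
            np.testing.assert_allclose(got, expected / prof.length, atol=1e-12)

    def test_flattened_length_400(self, rng):
        assert flatten_evo_matrix(pssm_dc(random_profile(rng, 10))).shape == (400,)

    def test_linear_in_scores(self, rng):
        prof = random_profile(rng, 12)
        scaled = PSSMProfile(id="s", scores=3.0 * prof.scores, residue_at=prof.residue_at)
        np.testing.assert_allclose(
            pssm_dc(scaled).values, 3.0 * pssm_dc(prof).values, rtol=1e-12
        )


class TestBigram:
    def test_zero_profile(self):
        prof = PSSMProfile(id="z", scores=np.zeros((5, 20)), residue_at="AAAAA")
        assert np.all(bigram_pssm(prof).values == 0)

    def test_three_rows_sum_of_outer_products(self, rng):
        prof = random_profile(rng, 3)
        expected = np.outer(prof.scores[0], prof.scores[1]) + np.outer(
            prof.scores[1], prof.scores[2]
        )
        np.testing.assert_allclose(bigram_pssm(prof).values, expected, rtol=1e-12)

    def test_matches_triple_loop(self, rng):
        prof = random_profile(rng, 5, integer=True)
        got = bigram_pssm(prof).values
        L = prof.length
        expected = np.zeros((20, 20))
        for m in range(20):
            for n in range(20):
                expected[m, n] = sum(
                    prof.scores[i, m] * prof.scores[i + 1, n] for i in range(L - 1)
                )
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_quadratic_in_scores(self, rng):
        prof = random_profile(rng, 8)
        scaled = PSSMProfile(id="s", scores=2.0 * prof.scores, residue_at=prof.residue_at)
        np.testing.assert_allclose(
            bigram_pssm(scaled).values, 4.0 * bigram_pssm(prof).values, rtol=1e-12
        )


class TestEdPssm:
    def test_constant_profile_gives_zero(self):
        prof = PSSMProfile(id="c", scores=np.full((6, 20), 2.5), residue_at="AAAAAA")
        np.testing.assert_allclose(ed_pssm(prof).values, 0.0, atol=1e-12)

    def test_minimal_length_collapses_to_single_term(self, rng):
        prof = random_profile(rng, 3)
        expected = (prof.scores[0][:, None] - prof.scores[2][None, :]) ** 2
        np.testing.assert_allclose(ed_pssm(prof).values, expected, rtol=1e-10)

    def test_matches_brute_force(self, rng):
        prof = random_profile(rng, 6)
        got = ed_pssm(prof).values
        L = prof.length
        expected = np.zeros((20, 20))
        for m in range(20):
            for n in range(20):
                expected[m, n] = sum(
                    (prof.scores[i - 1, m] - prof.scores[i + 1, n]) ** 2
                    for i in range(1, L - 1)
                ) / (L - 2)
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    @given(seed=st.integers(0, 10_000), length=st.integers(3, 30))
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_everywhere(self, seed, length):
        prof = random_profile(np.random.default_rng(seed), length)
        assert np.all(ed_pssm(prof).values >= 0)

    def test_descriptors_are_deterministic(self, rng):
        prof = random_profile(rng, 15)
        for fn in (pssm_dc, bigram_pssm, ed_pssm):
            a = fn(prof).values
            b = fn(prof).values
            np.testing.assert_array_equal(a, b)


def test_format_parse_round_trip_on_noninteger_scores(rng):
    prof = random_profile(rng, 7)
    back = parse_ascii_pssm(format_ascii_pssm(prof), id=prof.id)
    np.testing.assert_allclose(back.scores, prof.scores, atol=0.005)
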