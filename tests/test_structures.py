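"""Structure model: dot-bracket/CT parsing, pseudoknot predicates, pair matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnavote.simulate import random_structure
from rnavote.structures import (
    RnaSequence,
    SecondaryStructure,
    StructureError,
    is_compatible,
    is_pseudoknot_free,
    parse_ct,
    parse_dotbracket,
    read_ct_file,
    read_dotbracket_file,
    render_ct,
    render_dotbracket,
    to_pair_matrix,
    write_dotbracket_file,
)

from conftest import crossing_oracle, random_valid_structure


@pytest.mark.parametrize(
    "text, expected",
    [
        ("(())", {(1, 4), (2, 3)}),
        ("....", set()),
        ("(.(.).)", {(1, 7), (3, 5)}),
        (".", set()),
    ],
)
def test_parse_dotbracket_stack_matching(text, expected):
    struct = parse_dotbracket(text, len(text))
    assert struct.pairs == frozenset(expected)


@pytest.mark.parametrize(
    "text, fragment",
    [
        ("(()", "unclosed"),
        ("())", "unmatched"),
        ("(x)", "illegal character"),
        ("([)]", "illegal character"),  # extended bracket families rejected
    ],
)
def test_parse_dotbracket_errors_name_position(text, fragment):
    with pytest.raises(StructureError, match=fragment):
        parse_dotbracket(text)


def test_parse_dotbracket_length_mismatch():
    with pytest.raises(StructureError, match="length"):
        parse_dotbracket("(())", 5)


def test_render_dotbracket_examples():
    assert render_dotbracket(SecondaryStructure(4, frozenset({(1, 4), (2, 3)}))) == "(())"
    assert render_dotbracket(SecondaryStructure(3, frozenset())) == "..."
    with pytest.raises(StructureError):
        render_dotbracket(SecondaryStructure(4, frozenset({(1, 3), (2, 4)})))


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(8, 60), density=st.floats(0.0, 0.9))
def test_dotbracket_round_trip_identity(seed, n, density):
    """parse(render(S)) == S for random pseudoknot-free structures."""
    _, struct = random_structure(n, density, seed=seed)
    assert parse_dotbracket(render_dotbracket(struct), n) == struct


def test_structure_invariants_enforced_at_construction():
    with pytest.raises(StructureError):
        SecondaryStructure(5, frozenset({(2, 2)}))
    with pytest.raises(StructureError):
        SecondaryStructure(5, frozenset({(0, 3)}))
    with pytest.raises(StructureError):
        SecondaryStructure(5, frozenset({(1, 6)}))
    with pytest.raises(StructureError, match="reused"):
        SecondaryStructure(6, frozenset({(1, 4), (4, 6)}))


def test_pseudoknot_detection_matches_exhaustive_oracle(rng):
    """Stack-sweep pseudoknot check agrees with the O(m^2) crossing scan."""
    assert is_pseudoknot_free(SecondaryStructure(6, frozenset({(1, 6), (2, 5)})))
    assert not is_pseudoknot_free(SecondaryStructure(4, frozenset({(1, 3), (2, 4)})))
    assert is_pseudoknot_free(SecondaryStructure(4, frozenset()))
    for _ in range(300):
        n = int(rng.integers(4, 25))
        struct = random_valid_structure(rng, n, int(rng.integers(0, n // 2 + 1)))
        assert is_pseudoknot_free(struct) == crossing_oracle(struct)


@pytest.mark.parametrize(
    "candidate, selected_pairs, n, expected",
    [
        ((2, 5), {(1, 6)}, 6, True),   # nested, disjoint
        ((2, 7), {(2, 5)}, 8, False),  # base 2 reused
        ((3, 8), {(1, 5)}, 8, False),  # 1 < 3 < 5 < 8 crossing
        ((1, 2), set(), 4, True),
    ],
)
def test_pair_compatibility(candidate, selected_pairs, n, expected):
    assert is_compatible(candidate, SecondaryStructure(n, frozenset(selected_pairs))) is expected


def test_pair_matrix_is_symmetric_binary_zero_diagonal(rng):
    mat = to_pair_matrix(SecondaryStructure(4, frozenset({(1, 4)})))
    assert mat[0, 3] == 1.0 and mat[3, 0] == 1.0 and mat.sum() == 2.0
    assert np.array_equal(to_pair_matrix(SecondaryStructure(5, frozenset())), np.zeros((5, 5)))
    for _ in range(50):
        struct = random_valid_structure(rng, 15, int(rng.integers(0, 7)))
        mat = to_pair_matrix(struct)
        assert np.array_equal(mat, mat.T)
        assert set(np.unique(mat)) <= {0.0, 1.0}
        assert np.all(np.diag(mat) == 0)
        assert mat.sum() == 2 * len(struct.pairs)


def test_sequence_normalization_and_validation():
    seq = RnaSequence("x", "acgtT")
    assert seq.residues == "ACGUU"
    assert RnaSequence("y", "ACGQ").residues == "ACGN"
    with pytest.raises(StructureError):
        RnaSequence("", "ACGU")
    with pytest.raises(StructureError):
        RnaSequence("z", "")


CT_OK = """4 tiny
1 G 0 2 4 1
2 C 1 3 3 2
3 G 2 4 2 3
4 C 3 0 1 4
"""

CT_UNPAIRED = """3 loop
1 A 0 2 0 1
2 C 1 3 0 2
3 G 2 0 0 3
"""

CT_ASYM = """4 bad
1 G 0 2 4 1
2 C 1 3 0 2
3 G 2 4 0 3
4 C 3 0 0 4
"""


def test_parse_ct_reads_pairs_once_with_i_lt_j():
    seq, struct = parse_ct(CT_OK)
    assert seq.residues == "GCGC"
    assert struct.pairs == frozenset({(1, 4), (2, 3)})


def test_parse_ct_all_unpaired():
    _, struct = parse_ct(CT_UNPAIRED)
    assert struct.pairs == frozenset()


def test_parse_ct_rejects_asymmetric_pairing():
    with pytest.raises(StructureError, match="asymmetric"):
        parse_ct(CT_ASYM)


def test_parse_ct_rejects_malformed_rows():
    with pytest.raises(StructureError):
        parse_ct("2 short\n1 A 0 2 0 1\n")
    with pytest.raises(StructureError, match="malformed"):
        parse_ct("1 x\n1 A 0\n")


def test_ct_round_trip(rng):
    for _ in range(20):
        _, struct = random_structure(int(rng.integers(8, 40)), 0.5, rng=rng)
        seq = RnaSequence("rt", "A" * struct.n)
        seq2, struct2 = parse_ct(render_ct(seq, struct))
        assert struct2 == struct and seq2.residues == seq.residues


def test_file_round_trips(tmp_path, rng):
    records = []
    for i in range(5):
        seq, struct = random_structure(30, 0.5, rng=rng)
        records.append((RnaSequence(f"s{i}", seq.residues), struct))
    path = tmp_path / "multi.dbn"
    write_dotbracket_file(path, records, header_comment="provenance line")
    back = read_dotbracket_file(path)
    assert [(s.identifier, st_) for s, st_ in back] == [
        (s.identifier, st_) for s, st_ in records
    ]
    ct_path = tmp_path / "multi.ct"
    ct_path.write_text("".join(render_ct(s, st_) for s, st_ in records))
    assert [st_ for _, st_ in read_ct_file(ct_path)] == [st_ for _, st_ in records]
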