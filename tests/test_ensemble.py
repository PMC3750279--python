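"""Consensus voting and structure inference, checked against exhaustive oracles."""

import numpy as np
import pytest

from rnavote.ensemble import (
    BasePairMatrix,
    EnsembleError,
    EnsembleParams,
    PredictionSet,
    WeightVector,
    brute_force_mea,
    combine_unweighted,
    combine_weighted,
    dp_mea_inference,
    greedy_inference,
    load_params,
    predict,
    rank_pairs,
    save_params,
    structure_score,
)
from rnavote.structures import RnaSequence, SecondaryStructure, is_pseudoknot_free

from conftest import random_pair_matrix


def S(n, *pairs):
    return SecondaryStructure(n, frozenset(pairs))


def make_set(n, per_predictor):
    seq = RnaSequence("t", "A" * n)
    return PredictionSet(sequence=seq, per_predictor=per_predictor)


# ---------------------------------------------------------------------------
# vote combination
# ---------------------------------------------------------------------------

def test_unweighted_vote_is_normalized_tally():
    preds = make_set(8, {"a": S(8, (1, 6)), "b": S(8, (1, 6), (2, 5)), "c": S(8)})
    matrix = combine_unweighted(preds)
    assert matrix.scores[(1, 6)] == pytest.approx(2 / 3)
    assert matrix.scores[(2, 5)] == pytest.approx(1 / 3)


def test_identical_predictions_give_binary_matrix():
    s = S(8, (1, 8), (3, 6))
    matrix = combine_unweighted(make_set(8, {"a": s, "b": s, "c": s}))
    assert set(matrix.scores) == set(s.pairs)
    assert all(v == pytest.approx(1.0) for v in matrix.scores.values())


def test_weighted_vote_arithmetic():
    preds = make_set(8, {"a": S(8, (1, 6)), "b": S(8, (2, 5))})
    matrix = combine_weighted(preds, WeightVector({"a": 0.7, "b": 0.3}))
    assert matrix.scores[(1, 6)] == pytest.approx(0.7)
    assert matrix.scores[(2, 5)] == pytest.approx(0.3)
    # degenerate weights pick out one predictor exactly
    m1 = combine_weighted(preds, WeightVector({"a": 1.0, "b": 0.0}))
    assert set(m1.scores) == {(1, 6)}


def test_uniform_weights_bitwise_equal_unweighted(rng):
    """Eq-style consistency: explicit 1/k weights reproduce the plain tally."""
    for _ in range(100):
        n = int(rng.integers(8, 20))
        k = int(rng.integers(1, 6))
        per = {}
        for l in range(k):
            pairs = set()
            for _ in range(int(rng.integers(0, 5))):
                i = int(rng.integers(1, n))
                j = int(rng.integers(i + 1, n + 1))
                if all(i not in p and j not in p for p in pairs):
                    pairs.add((i, j))
            per[f"p{l}"] = S(n, *pairs)
        preds = make_set(n, per)
        mu = combine_unweighted(preds)
        mw = combine_weighted(preds, WeightVector.uniform(per))
        assert mu.scores == mw.scores  # bit-identical
        assert all(0.0 < v <= 1.0 for v in mu.scores.values())


def test_weight_vector_validation():
    with pytest.raises(EnsembleError):
        WeightVector({"a": 0.7, "b": 0.2})  # sums to 0.9
    with pytest.raises(EnsembleError):
        WeightVector({})
    w = WeightVector.from_raw({"a": 40.0, "b": 60.0})  # percentage scale
    assert w["b"] == pytest.approx(0.6)


def test_combine_rejects_mismatched_rosters():
    preds = make_set(8, {"a": S(8, (1, 6))})
    with pytest.raises(EnsembleError, match="mismatch"):
        combine_weighted(preds, WeightVector({"a": 0.5, "b": 0.5}))


def test_prediction_set_rejects_length_mismatch():
    with pytest.raises(EnsembleError, match="n="):
        make_set(8, {"a": S(9, (1, 6))})


# ---------------------------------------------------------------------------
# ranking and inference
# ---------------------------------------------------------------------------

def test_rank_pairs_order_and_tie_break():
    ranked = rank_pairs(BasePairMatrix(n=8, scores={(2, 5): 0.8, (1, 6): 0.9}))
    assert [p for p, _ in ranked] == [(1, 6), (2, 5)]
    tied = rank_pairs(BasePairMatrix(n=8, scores={(2, 6): 0.5, (1, 4): 0.5}))
    assert [p for p, _ in tied] == [(1, 4), (2, 6)]
    assert rank_pairs(BasePairMatrix(n=5, scores={})) == []


def test_greedy_hand_trace():
    # (2,5) is rejected because base 2 is taken by the higher-ranked (2,7)
    matrix = BasePairMatrix(
        n=8, scores={(1, 8): 0.9, (2, 7): 0.8, (2, 5): 0.7, (3, 6): 0.6}
    )
    assert greedy_inference(matrix, 0.5).pairs == frozenset({(1, 8), (2, 7), (3, 6)})


def test_greedy_rejects_crossing_pair():
    matrix = BasePairMatrix(n=8, scores={(1, 5): 0.9, (3, 8): 0.8})
    assert greedy_inference(matrix, 0.5).pairs == frozenset({(1, 5)})


def test_greedy_threshold_excludes_all():
    matrix = BasePairMatrix(n=8, scores={(1, 5): 0.9, (3, 8): 0.8})
    assert greedy_inference(matrix, 1.0).pairs == frozenset()


def test_dp_beats_greedy_on_conflict():
    matrix = BasePairMatrix(n=8, scores={(2, 6): 0.6, (1, 3): 0.5, (4, 7): 0.5})
    dp = dp_mea_inference(matrix, 0.4)
    assert dp.pairs == frozenset({(1, 3), (4, 7)})
    assert structure_score(matrix, dp) == pytest.approx(1.0)
    greedy = greedy_inference(matrix, 0.4)
    assert structure_score(matrix, greedy) == pytest.approx(0.6)


def test_dp_empty_above_max_score():
    matrix = BasePairMatrix(n=8, scores={(1, 5): 0.9})
    assert dp_mea_inference(matrix, 0.95).pairs == frozenset()


def test_dp_equals_greedy_on_nested_candidates():
    matrix = BasePairMatrix(n=10, scores={(1, 10): 0.9, (2, 9): 0.8, (3, 8): 0.7})
    theta = 0.5
    assert dp_mea_inference(matrix, theta).pairs == greedy_inference(matrix, theta).pairs


def test_brute_force_guard_and_trivia():
    big = BasePairMatrix(n=35, scores={(i, i + 10): 0.5 for i in range(1, 22)})
    with pytest.raises(EnsembleError, match="guard"):
        brute_force_mea(big, 0.0)
    assert brute_force_mea(BasePairMatrix(n=5, scores={}), 0.5).pairs == frozenset()
    single = brute_force_mea(BasePairMatrix(n=4, scores={(1, 4): 0.2}), 0.1)
    assert single.pairs == frozenset({(1, 4)})


def test_dp_matches_brute_force_oracle(rng):
    """DP total score equals exhaustive enumeration on random instances."""
    for _ in range(250):
        matrix = random_pair_matrix(rng)
        theta = float(rng.uniform(0.0, 0.8))
        dp = dp_mea_inference(matrix, theta)
        oracle = brute_force_mea(matrix, theta)
        assert structure_score(matrix, dp) == pytest.approx(
            structure_score(matrix, oracle), abs=1e-9
        )
        assert is_pseudoknot_free(dp)


def test_greedy_contract_properties(rng):
    """Greedy output: valid, thresholded, never above DP, theta-monotone."""
    for _ in range(250):
        matrix = random_pair_matrix(rng)
        t1, t2 = sorted(rng.uniform(0.0, 1.0, size=2))
        g1, g2 = greedy_inference(matrix, t1), greedy_inference(matrix, t2)
        assert is_pseudoknot_free(g1) and is_pseudoknot_free(g2)
        assert all(matrix.scores[p] >= t1 for p in g1.pairs)
        assert g2.pairs <= g1.pairs  # larger theta selects a subset
        dp = dp_mea_inference(matrix, t1)
        assert structure_score(matrix, g1) <= structure_score(matrix, dp) + 1e-9


# ---------------------------------------------------------------------------
# end-to-end predict and parameter files
# ---------------------------------------------------------------------------

def test_predict_single_predictor_pass_through():
    s = S(8, (1, 8), (3, 6))
    preds = make_set(8, {"only": s})
    params = EnsembleParams(weights=WeightVector({"only": 1.0}), theta=0.5)
    assert predict(preds, params, "greedy") == s
    assert predict(preds, params, "dp") == s


def test_predict_unanimous_predictions_returned():
    s = S(8, (1, 8), (3, 6))
    preds = make_set(8, {"a": s, "b": s, "c": s})
    params = EnsembleParams(weights=WeightVector({"a": 0.5, "b": 0.3, "c": 0.2}), theta=0.5)
    assert predict(preds, params, "greedy") == s


def test_predict_missing_predictor_strict_vs_permissive():
    s = S(8, (1, 8))
    preds = make_set(8, {"a": s})
    params = EnsembleParams(weights=WeightVector({"a": 0.6, "b": 0.4}), theta=0.5)
    with pytest.raises(EnsembleError):
        predict(preds, params)
    assert predict(preds, params, allow_missing=True) == s


def test_params_file_round_trip_and_percent_scale(tmp_path):
    path = tmp_path / "params.yaml"
    params = EnsembleParams(weights=WeightVector({"a": 0.25, "b": 0.75}), theta=0.4)
    save_params(path, params, "dp")
    loaded, method = load_params(path)
    assert method == "dp"
    assert loaded.weights.weights == pytest.approx(params.weights.weights)
    assert loaded.theta == pytest.approx(0.4)

    # percentage-scale file: weights summing to 100, theta on the same scale
    path2 = tmp_path / "percent.yaml"
    path2.write_text("weights:\n  a: 40.8\n  b: 59.2\ntheta: 42.7\n")
    loaded2, method2 = load_params(path2)
    assert method2 == "greedy"
    assert loaded2.weights["a"] == pytest.approx(0.408)
    assert loaded2.theta == pytest.approx(0.427)


def test_matrix_entry_validation():
    with pytest.raises(EnsembleError):
        BasePairMatrix(n=5, scores={(1, 6): 0.5})
    with pytest.raises(EnsembleError):
        BasePairMatrix(n=5, scores={(1, 4): 1.5})
    with pytest.raises(EnsembleError):
        BasePairMatrix(n=5, scores={(1, 4): 0.0})
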