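"""Consensus base-pair voting and pseudoknot-free structure inference.

Given predictions S(A_1, s), ..., S(A_k, s) for one sequence from k black-box
predictors, each structure is viewed as a binary pair matrix BP(S) and the
ensemble forms the weighted normalised sum

    P(w)_ij = sum_l  w_l * BP(S(A_l, s))_ij,      sum_l w_l = 1,

whose entries lie in [0, 1] and act as consensus pairing probabilities (the
unweighted vote is the special case w_l = 1/k).  A structure is then extracted
either greedily — scan candidate pairs in decreasing score order while the
score is >= the pairing threshold theta, accepting a pair iff it neither
reuses a base nor introduces a pseudoknot — or exactly, by a Nussinov-style
O(n^3) dynamic program that maximises the summed score of selected pairs over
candidates with score >= theta (maximum expected accuracy inference).

theta controls the sensitivity/PPV trade-off: high theta keeps only pairs most
predictors agree on (few false positives), low theta admits minority pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import yaml

from .structures import (
    RnaSequence,
    SecondaryStructure,
    crosses,
)

logger = logging.getLogger(__name__)

InferenceMethod = Literal["greedy", "dp"]

_WEIGHT_TOL = 1e-9


class EnsembleError(ValueError):
    """Raised for inconsistent ensembles or parameter files."""


@dataclass(frozen=True)
class PredictionSet:
    """Predictions for one sequence from each predictor in the ensemble."""

    sequence: RnaSequence
    per_predictor: Mapping[str, SecondaryStructure]

    def __post_init__(self) -> None:
        if not self.per_predictor:
            raise EnsembleError(f"no predictions for sequence {self.sequence.identifier!r}")
        object.__setattr__(self, "per_predictor", dict(self.per_predictor))
        n = self.sequence.n
        for label, struct in self.per_predictor.items():
            if struct.n != n:
                raise EnsembleError(
                    f"prediction {label!r} for {self.sequence.identifier!r} has "
                    f"n={struct.n}, sequence has n={n}"
                )

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(sorted(self.per_predictor))


@dataclass(frozen=True)
class BasePairMatrix:
    """Sparse symmetric matrix of per-pair consensus scores in (0, 1].

    Stored as a mapping from (i, j) with i < j to its score; zero entries are
    omitted and the diagonal is empty.
    """

    n: int
    scores: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], float] = {}
        for (i, j), s in self.scores.items():
            if not (1 <= i < j <= self.n):
                raise EnsembleError(f"matrix entry ({i},{j}) out of range for n={self.n}")
            if not (0.0 < s <= 1.0 + _WEIGHT_TOL):
                raise EnsembleError(f"score {s} for pair ({i},{j}) outside (0, 1]")
            clean[(i, j)] = min(float(s), 1.0)
        object.__setattr__(self, "scores", clean)

    def to_dense(self) -> np.ndarray:
        mat = np.zeros((self.n, self.n))
        for (i, j), s in self.scores.items():
            mat[i - 1, j - 1] = s
            mat[j - 1, i - 1] = s
        return mat


@dataclass(frozen=True)
class WeightVector:
    """Per-predictor weights on the probability simplex (sum to 1)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = {str(k): float(v) for k, v in self.weights.items()}
        if not w:
            raise EnsembleError("empty weight vector")
        for label, value in w.items():
            if not (0.0 <= value <= 1.0 + _WEIGHT_TOL):
                raise EnsembleError(f"weight {value} for {label!r} outside [0, 1]")
        total = sum(w.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise EnsembleError(f"weights sum to {total}, expected 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_raw(cls, raw: Mapping[str, float]) -> "WeightVector":
        """Normalize arbitrary non-negative weights (e.g. percentages) to sum 1."""
        total = sum(raw.values())
        if total <= 0:
            raise EnsembleError("raw weights must have a positive sum")
        return cls({k: v / total for k, v in raw.items()})

    @classmethod
    def uniform(cls, labels: Iterable[str]) -> "WeightVector":
        labels = list(labels)
        return cls({label: 1.0 / len(labels) for label in labels})

    def __getitem__(self, label: str) -> float:
        return self.weights[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.weights))


@dataclass(frozen=True)
class EnsembleParams:
    """Everything the combiner needs: weights plus the pairing threshold."""

    weights: WeightVector
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise EnsembleError(f"theta {self.theta} outside [0, 1]")


# ---------------------------------------------------------------------------
# Vote combination
# ---------------------------------------------------------------------------

def combine_weighted(predictions: PredictionSet, weights: WeightVector) -> BasePairMatrix:
    """Weighted normalised sum of the predictors' binary pair matrices."""
    pred_labels = set(predictions.per_predictor)
    weight_labels = set(weights.weights)
    if pred_labels != weight_labels:
        raise EnsembleError(
            f"weight/prediction mismatch: weights for {sorted(weight_labels)}, "
            f"predictions from {sorted(pred_labels)}"
        )
    scores: dict[tuple[int, int], float] = {}
    for label in sorted(pred_labels):
        w = weights[label]
        if w == 0.0:
            continue
        for pair in predictions.per_predictor[label].pairs:
            scores[pair] = scores.get(pair, 0.0) + w
    return BasePairMatrix(n=predictions.sequence.n, scores=scores)


def combine_unweighted(predictions: PredictionSet) -> BasePairMatrix:
    """Plain vote tally: entry (i,j) = (# predictors proposing the pair) / k."""
    return combine_weighted(predictions, WeightVector.uniform(predictions.per_predictor))


# ---------------------------------------------------------------------------
# Structure inference
# ---------------------------------------------------------------------------

def rank_pairs(matrix: BasePairMatrix) -> list[tuple[tuple[int, int], float]]:
    """Candidate pairs sorted by decreasing score; ties broken by (i, j)."""
    return sorted(matrix.scores.items(), key=lambda item: (-item[1], item[0]))


def greedy_inference(matrix: BasePairMatrix, theta: float) -> SecondaryStructure:
    """Greedy MEA estimate: accept ranked pairs with score >= theta when compatible."""
    _check_theta(theta)
    occupied: set[int] = set()
    selected: list[tuple[int, int]] = []
    for (i, j), score in rank_pairs(matrix):
        if score < theta:
            break
        if i in occupied or j in occupied:
            continue
        if any(crosses((i, j), prev) for prev in selected):
            continue
        selected.append((i, j))
        occupied.update((i, j))
    return SecondaryStructure(n=matrix.n, pairs=frozenset(selected))


def dp_mea_inference(matrix: BasePairMatrix, theta: float) -> SecondaryStructure:
    """Exact MEA inference by Nussinov-style dynamic programming.

    Maximises the summed score of selected pairs over candidates with score
    >= theta, subject to nestedness and one pair per base.  O(n^3) time,
    O(n^2) space.  Traceback is deterministic: leaving i unpaired is preferred
    on ties, then the smallest pairing partner.
    """
    _check_theta(theta)
    n = matrix.n
    # S[i, l] = score of candidate pair (i, l) if admitted, else 0 mask entry
    S = np.zeros((n + 2, n + 2))
    admitted = np.zeros((n + 2, n + 2), dtype=bool)
    for (i, j), s in matrix.scores.items():
        if s >= theta:
            S[i, j] = s
            admitted[i, j] = True
    M = np.zeros((n + 2, n + 2))
    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = M[i + 1, j]
            mask = admitted[i, i + 1 : j + 1]
            if mask.any():
                # grouping matches the scalar recomputation in traceback
                vals = (S[i, i + 1 : j + 1] + M[i + 1, i:j]) + M[i + 2 : j + 2, j]
                vals = np.where(mask, vals, -np.inf)
                best = max(best, float(vals.max()))
            M[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(1, n)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        target = M[i, j]
        for l in range(i + 1, j + 1):
            if admitted[i, l] and (S[i, l] + M[i + 1, l - 1]) + M[l + 1, j] == target:
                pairs.append((i, l))
                stack.append((i + 1, l - 1))
                stack.append((l + 1, j))
                break
        else:  # pragma: no cover - defends against float drift
            raise RuntimeError(f"DP traceback failed on interval ({i},{j})")
    return SecondaryStructure(n=n, pairs=frozenset(pairs))


def structure_score(matrix: BasePairMatrix, structure: SecondaryStructure) -> float:
    """Summed consensus score of a structure's pairs under the matrix."""
    return sum(matrix.scores.get(pair, 0.0) for pair in structure.pairs)


def brute_force_mea(
    matrix: BasePairMatrix, theta: float, max_candidates: int = 20
) -> SecondaryStructure:
    """Exhaustive MEA oracle for testing.

    Enumerates every pseudoknot-free, one-pair-per-base subset of the
    candidate pairs (score >= theta) by depth-first search and returns one of
    maximum total score (first found in lexicographic DFS order on ties).
    Guarded to small candidate sets.
    """
    _check_theta(theta)
    candidates = sorted(
        (pair for pair, s in matrix.scores.items() if s >= theta)
    )
    if len(candidates) > max_candidates:
        raise EnsembleError(
            f"{len(candidates)} candidate pairs exceed the brute-force guard "
            f"({max_candidates})"
        )
    best_score = -1.0
    best_pairs: tuple[tuple[int, int], ...] = ()

    def recurse(start: int, chosen: list[tuple[int, int]], score: float) -> None:
        nonlocal best_score, best_pairs
        if score > best_score:
            best_score = score
            best_pairs = tuple(chosen)
        for idx in range(start, len(candidates)):
            cand = candidates[idx]
            i, j = cand
            ok = all(
                i != a and i != b and j != a and j != b and not crosses(cand, (a, b))
                for a, b in chosen
            )
            if ok:
                chosen.append(cand)
                recurse(idx + 1, chosen, score + matrix.scores[cand])
                chosen.pop()

    recurse(0, [], 0.0)
    return SecondaryStructure(n=matrix.n, pairs=frozenset(best_pairs))


def predict(
    predictions: PredictionSet,
    params: EnsembleParams,
    method: InferenceMethod = "greedy",
    allow_missing: bool = False,
) -> SecondaryStructure:
    """Full consensus pipeline for one sequence: combine, then infer.

    With ``allow_missing`` the weights of predictors absent from this
    sequence's prediction set are renormalized over those present (logged);
    by default a missing prediction is a hard error, since silent
    renormalization changes the estimator.
    """
    weights = params.weights
    present = set(predictions.per_predictor)
    weighted = set(weights.weights)
    if present != weighted:
        if not allow_missing or not (present < weighted):
            raise EnsembleError(
                f"sequence {predictions.sequence.identifier!r}: predictions from "
                f"{sorted(present)} but weights for {sorted(weighted)}"
            )
        logger.warning(
            "sequence %r: renormalizing weights over present predictors %s",
            predictions.sequence.identifier,
            sorted(present),
        )
        weights = WeightVector.from_raw({l: weights[l] for l in present})
    matrix = combine_weighted(predictions, weights)
    infer = greedy_inference if method == "greedy" else dp_mea_inference
    return infer(matrix, params.theta)


def _check_theta(theta: float) -> None:
    if not (0.0 <= theta <= 1.0):
        raise EnsembleError(f"theta {theta} outside [0, 1]")


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

def load_params(path: str | Path) -> tuple[EnsembleParams, InferenceMethod]:
    """Read an ensemble parameter file (YAML).

    Weights are divided by their sum on load, so files on a percentage scale
    work unchanged; a theta above 1 is taken to be on the same percentage
    scale and divided by 100.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "weights" not in data:
        raise EnsembleError(f"parameter file {path} lacks a 'weights' mapping")
    weights = WeightVector.from_raw({str(k): float(v) for k, v in data["weights"].items()})
    theta = float(data.get("theta", 0.5))
    if theta > 1.0:
        theta /= 100.0
    method = str(data.get("method", "greedy"))
    if method not in ("greedy", "dp"):
        raise EnsembleError(f"unknown inference method {method!r}")
    return EnsembleParams(weights=weights, theta=theta), method  # type: ignore[return-value]


def save_params(
    path: str | Path, params: EnsembleParams, method: InferenceMethod = "greedy"
) -> None:
    data = {
        "weights": {k: float(v) for k, v in sorted(params.weights.weights.items())},
        "theta": float(params.theta),
        "method": method,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
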