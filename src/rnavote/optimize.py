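"""Training the consensus: weight/threshold optimization, ablation, sweeps.

The free parameters of the consensus predictor are the k predictor weights
(constrained to the probability simplex) and the pairing threshold theta.
They are fitted by maximising the mean F-measure over a training set of
(prediction-set, reference) records with a gradient-free stochastic search:
scipy's differential evolution over the box [0,1]^(k+1), with the raw weight
coordinates clipped to be non-negative and normalised to sum 1 (uniform if
all are zero).  The uniform-weight, theta = 0.5 baseline is always evaluated
alongside the search result and the better of the two is returned, so the
optimizer can never regress below the plain unweighted vote.

The ablation procedure identifies, at each step, the reduced ensemble (after
re-optimization warm-started at the current parameters) that performs worst
on the training set and removes its missing member — i.e. the component whose
loss hurts most goes first and the weakest component survives longest —
recording train and test accuracy at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .ensemble import (
    BasePairMatrix,
    EnsembleError,
    EnsembleParams,
    InferenceMethod,
    PredictionSet,
    WeightVector,
    dp_mea_inference,
    greedy_inference,
    predict,
)
from .metrics import evaluate_set, f_measure, ppv, sensitivity
from .structures import SecondaryStructure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSet:
    """Paired (prediction-set, reference) records sharing one predictor roster."""

    records: tuple[tuple[PredictionSet, SecondaryStructure], ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValueError("training set must be non-empty")
        roster = records[0][0].predictors
        for preds, ref in records:
            if preds.sequence.n != ref.n:
                raise ValueError(
                    f"record {preds.sequence.identifier!r}: prediction n={preds.sequence.n} "
                    f"vs reference n={ref.n}"
                )
            if preds.predictors != roster:
                raise ValueError(
                    f"record {preds.sequence.identifier!r} has predictor roster "
                    f"{preds.predictors}, expected {roster}"
                )
        object.__setattr__(self, "records", records)

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.records[0][0].predictors

    @property
    def references(self) -> tuple[SecondaryStructure, ...]:
        return tuple(ref for _, ref in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def restrict(self, labels: Sequence[str]) -> "TrainingSet":
        """Project every record onto a predictor subset."""
        keep = set(labels)
        missing = keep - set(self.predictors)
        if missing:
            raise ValueError(f"unknown predictors {sorted(missing)}")
        return TrainingSet(
            records=tuple(
                (
                    PredictionSet(
                        sequence=preds.sequence,
                        per_predictor={
                            l: s for l, s in preds.per_predictor.items() if l in keep
                        },
                    ),
                    ref,
                )
                for preds, ref in self.records
            )
        )


@dataclass(frozen=True)
class OptimizationConfig:
    max_iterations: int = 100
    population_size: int = 15
    seed: int = 0
    inference_method: InferenceMethod = "greedy"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class AblationStep:
    removed: str
    params: EnsembleParams
    train_f: float
    test_f: float


@dataclass(frozen=True)
class AblationTrace:
    initial_params: EnsembleParams
    initial_train_f: float
    initial_test_f: float
    steps: tuple[AblationStep, ...]

    @property
    def removal_order(self) -> tuple[str, ...]:
        return tuple(step.removed for step in self.steps)


def objective(
    params: EnsembleParams,
    training: TrainingSet,
    method: InferenceMethod = "greedy",
) -> float:
    """Mean F-measure of the consensus prediction over the training records."""
    predictions = [predict(preds, params, method) for preds, _ in training.records]
    return evaluate_set(predictions, list(training.references)).mean_f


class _CachedObjective:
    """Fast objective evaluator.

    Pre-computes, per record, the union of proposed pairs together with a
    0/1 membership matrix over predictors, so each evaluation is one matrix
    product plus inference instead of re-walking every predicted structure.
    """

    def __init__(self, training: TrainingSet, method: InferenceMethod) -> None:
        self.method = method
        self.labels = training.predictors
        self.references = list(training.references)
        self.records: list[tuple[int, list[tuple[int, int]], np.ndarray]] = []
        k = len(self.labels)
        for preds, _ in training.records:
            union = sorted({p for s in preds.per_predictor.values() for p in s.pairs})
            mask = np.zeros((len(union), k))
            for col, label in enumerate(self.labels):
                pair_set = preds.per_predictor[label].pairs
                for row, pair in enumerate(union):
                    if pair in pair_set:
                        mask[row, col] = 1.0
            self.records.append((preds.sequence.n, union, mask))

    def mean_f(self, w: np.ndarray, theta: float) -> float:
        infer = greedy_inference if self.method == "greedy" else dp_mea_inference
        total = 0.0
        for (n, union, mask), ref in zip(self.records, self.references):
            scores = mask @ w
            matrix = BasePairMatrix(
                n=n,
                scores={
                    pair: min(float(s), 1.0)
                    for pair, s in zip(union, scores)
                    if s > 0.0
                },
            )
            pred = infer(matrix, theta)
            total += f_measure(sensitivity(pred, ref), ppv(pred, ref))
        return total / len(self.references)


def _map_raw(x: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Map raw search coordinates to (simplex weights, clipped theta)."""
    w = np.clip(x[:k], 0.0, None)
    s = w.sum()
    w = np.full(k, 1.0 / k) if s == 0.0 else w / s
    theta = float(np.clip(x[k], 0.0, 1.0))
    return w, theta


def optimize(training: TrainingSet, config: OptimizationConfig) -> EnsembleParams:
    """Fit weights and theta by seeded, iteration-bounded differential evolution.

    Returns parameters whose training objective is >= the uniform-weight,
    theta = 0.5 baseline (the baseline is injected into the candidate pool).
    """
    labels = training.predictors
    k = len(labels)
    evaluator = _CachedObjective(training, config.inference_method)

    def neg_obj(x: np.ndarray) -> float:
        w, theta = _map_raw(x, k)
        return -evaluator.mean_f(w, theta)

    if k == 1:
        bounds = [(0.0, 1.0)]  # only theta is searched

        def neg_obj(x: np.ndarray) -> float:  # noqa: F811
            return -evaluator.mean_f(np.ones(1), float(x[0]))

    else:
        bounds = [(0.0, 1.0)] * (k + 1)

    result = differential_evolution(
        neg_obj,
        bounds,
        maxiter=config.max_iterations,
        popsize=config.population_size,
        seed=config.seed,
        polish=False,
        init="latinhypercube",
        tol=1e-8,
    )
    if k == 1:
        w_best, theta_best = np.ones(1), float(np.clip(result.x[0], 0.0, 1.0))
    else:
        w_best, theta_best = _map_raw(result.x, k)
    search_f = evaluator.mean_f(w_best, theta_best)

    w_base = np.full(k, 1.0 / k)
    baseline_f = evaluator.mean_f(w_base, 0.5)
    if baseline_f >= search_f:
        w_best, theta_best, search_f = w_base, 0.5, baseline_f
    logger.info("optimize: best mean F %.4f (baseline %.4f)", search_f, baseline_f)
    return EnsembleParams(
        weights=WeightVector.from_raw(dict(zip(labels, w_best))), theta=theta_best
    )


def _reoptimize(
    training: TrainingSet,
    config: OptimizationConfig,
    warm: EnsembleParams | None,
    seed: int,
) -> tuple[EnsembleParams, float]:
    """Optimize a (sub-)ensemble, also considering a warm-start candidate."""
    cfg = replace(config, seed=seed)
    params = optimize(training, cfg)
    evaluator = _CachedObjective(training, config.inference_method)
    labels = training.predictors
    best_f = evaluator.mean_f(
        np.array([params.weights[l] for l in labels]), params.theta
    )
    if warm is not None:
        raw = {l: warm.weights[l] for l in labels if warm.weights.weights.get(l, 0.0) > 0}
        if raw:
            warm_params = EnsembleParams(
                weights=WeightVector.from_raw(
                    {l: raw.get(l, 0.0) + 1e-12 for l in labels}
                ),
                theta=warm.theta,
            )
            warm_f = evaluator.mean_f(
                np.array([warm_params.weights[l] for l in labels]), warm_params.theta
            )
            if warm_f > best_f:
                params, best_f = warm_params, warm_f
    return params, best_f


def _derived_seed(master: int, *parts: int) -> int:
    return int(np.random.SeedSequence([master, *parts]).generate_state(1)[0] % (2**31))


def ablate(
    training: TrainingSet,
    test: TrainingSet,
    config: OptimizationConfig,
    stop_at_two: bool = False,
) -> AblationTrace:
    """Iterative worst-removal ablation with per-step re-optimization.

    At each step, for every remaining predictor l the reduced ensemble
    without l is re-optimized (warm-started at the current parameters) and
    scored on the training set; the l whose reduced ensemble scores lowest is
    removed.  Runs to a single survivor by default (``stop_at_two`` stops
    while two remain).
    """
    if len(training.predictors) < 2:
        raise ValueError("ablation requires at least two predictors")
    current = list(training.predictors)
    params, train_f = _reoptimize(
        training, config, None, _derived_seed(config.seed, 0)
    )
    initial = AblationTrace(
        initial_params=params,
        initial_train_f=train_f,
        initial_test_f=objective(params, test.restrict(current), config.inference_method),
        steps=(),
    )
    steps: list[AblationStep] = []
    floor = 2 if stop_at_two else 1
    step_no = 0
    while len(current) > floor:
        step_no += 1
        worst_label: str | None = None
        worst_f = np.inf
        worst_params: EnsembleParams | None = None
        for idx, label in enumerate(sorted(current)):
            remaining = [l for l in current if l != label]
            sub_params, sub_f = _reoptimize(
                training.restrict(remaining),
                config,
                params,
                _derived_seed(config.seed, step_no, idx),
            )
            if sub_f < worst_f:
                worst_label, worst_f, worst_params = label, sub_f, sub_params
        assert worst_label is not None and worst_params is not None
        current = [l for l in current if l != worst_label]
        params = worst_params
        steps.append(
            AblationStep(
                removed=worst_label,
                params=params,
                train_f=worst_f,
                test_f=objective(
                    params, test.restrict(current), config.inference_method
                ),
            )
        )
    return replace(initial, steps=tuple(steps))


def threshold_sweep(
    params: EnsembleParams,
    evaluation: TrainingSet,
    theta_grid: Sequence[float],
) -> pd.DataFrame:
    """Mean sensitivity/PPV/F at each theta (greedy inference).

    Traces the sensitivity-PPV trade-off curve: raising theta keeps only
    high-agreement pairs (fewer false positives, more false negatives).
    """
    grid = list(theta_grid)
    if not grid:
        raise ValueError("theta grid must be non-empty")
    if sorted(grid) != grid:
        raise ValueError("theta grid must be sorted ascending")
    rows = []
    for theta in grid:
        p = EnsembleParams(weights=params.weights, theta=float(theta))
        preds = [predict(ps, p, "greedy") for ps, _ in evaluation.records]
        summary = evaluate_set(preds, list(evaluation.references))
        rows.append(
            {
                "theta": float(theta),
                "mean_sensitivity": summary.mean_sensitivity,
                "mean_ppv": summary.mean_ppv,
                "mean_f": summary.mean_f,
                "mean_pairs": float(np.mean([len(s.pairs) for s in preds])),
            }
        )
    return pd.DataFrame(rows)


def sample_training_subset(full_set: TrainingSet, size: int, seed: int) -> TrainingSet:
    """Uniform subsample without replacement; reproducible under seed."""
    if size < 1 or size > len(full_set):
        raise ValueError(f"subset size {size} outside [1, {len(full_set)}]")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(full_set))[:size]
    return TrainingSet(records=tuple(full_set.records[i] for i in idx))
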