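"""Resampling statistics over per-structure accuracy vectors.

Benchmark comparisons of structure predictors rest on a vector f of
per-structure F-measures (or sensitivities/PPVs).  This module provides the
three tools used to judge such comparisons:

* bootstrap percentile confidence intervals for the mean of f,
* a paired permutation test for the difference in mean accuracy between two
  predictors (per-structure swap with probability 1/2),
* Spearman rank correlation between two predictors' accuracy vectors.

All randomness flows from explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AccuracyVector:
    """Per-structure accuracy values in [0,1], index-aligned to a benchmark set."""

    values: np.ndarray
    label: str = "accuracy"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("accuracy vector must be a non-empty 1-D array")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("accuracy values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    n_resamples: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("CI lower bound exceeds upper bound")


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    alpha: float
    reject: bool


def _as_array(f: AccuracyVector | Sequence[float]) -> np.ndarray:
    if isinstance(f, AccuracyVector):
        return f.values
    return np.asarray(f, dtype=np.float64)


def bootstrap_ci(
    f: AccuracyVector | Sequence[float],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> ConfidenceInterval:
    """Bootstrap percentile CI for the mean of f.

    Draws ``n_resamples`` uniform with-replacement samples of size ``|f|``,
    takes the mean of each, and reports the (1-level)/2 and 1-(1-level)/2
    empirical percentiles of those means (linear interpolation between order
    statistics, so results are bit-reproducible given the seed).
    """
    values = _as_array(f)
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level {level} outside (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [tail, 1.0 - tail])
    return ConfidenceInterval(
        lower=float(lower), upper=float(upper), level=level, n_resamples=n_resamples
    )


def permutation_test(
    fA: AccuracyVector | Sequence[float],
    fB: AccuracyVector | Sequence[float],
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Paired permutation test for equal mean accuracy of predictors A and B.

    The observed statistic is mean(fA) - mean(fB).  Each permutation swaps
    the two values at every index independently with probability 1/2 and
    recomputes the statistic; the one-sided percentile p-value is the
    fraction of permuted statistics at least as large as the observed one.
    Counting is inclusive with the add-one convention, so p >= 1/(B+1) and a
    pair compared with itself yields p = 1.  ``alternative='two-sided'``
    reports 2 * min(p_greater, p_less), capped at 1.  The null is rejected
    iff p < alpha.
    """
    a, b = _as_array(fA), _as_array(fB)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: |fA|={a.size}, |fB|={b.size}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    diffs = a - b
    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    # swapping A_i and B_i flips the sign of the per-index difference
    signs = np.where(rng.random((n_permutations, diffs.size)) < 0.5, -1.0, 1.0)
    permuted = (signs * diffs).mean(axis=1)
    p_greater = (1 + int(np.count_nonzero(permuted >= observed))) / (n_permutations + 1)
    if alternative == "greater":
        p = p_greater
    else:
        p_less = (1 + int(np.count_nonzero(permuted <= observed))) / (n_permutations + 1)
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return PermutationResult(
        observed_diff=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        alpha=alpha,
        reject=bool(p < alpha),
    )


def spearman(
    fA: AccuracyVector | Sequence[float], fB: AccuracyVector | Sequence[float]
) -> float:
    """Spearman rank correlation (Pearson on average ranks) of two vectors."""
    a, b = _as_array(fA), _as_array(fB)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("spearman requires two equal-length vectors of size >= 2")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("spearman undefined for a constant vector (zero rank variance)")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def pairwise_comparison(
    vectors: Sequence[AccuracyVector],
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs permutation p-values and Spearman coefficients.

    Returns two lower-triangular DataFrames (rows/columns labelled by vector
    labels; upper triangle and diagonal are NaN).  The permutation seed for
    each pair is derived deterministically from the master seed and the pair's
    indices, so a repeated run reproduces the matrices exactly.
    """
    if len(vectors) < 2:
        raise ValueError("pairwise comparison requires at least two vectors")
    sizes = {len(v) for v in vectors}
    if len(sizes) != 1:
        raise ValueError(f"vectors have differing lengths: {sorted(sizes)}")
    labels = [v.label for v in vectors]
    if len(set(labels)) != len(labels):
        raise ValueError("vector labels must be unique")
    p_mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    rho_mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for ia in range(len(vectors)):
        for ib in range(ia):
            pair_seed = int(
                np.random.SeedSequence([seed, ia, ib]).generate_state(1)[0] % (2**31)
            )
            res = permutation_test(
                vectors[ia], vectors[ib], n_permutations, alpha, pair_seed
            )
            p_mat.iloc[ia, ib] = res.p_value
            try:
                rho_mat.iloc[ia, ib] = spearman(vectors[ia], vectors[ib])
            except ValueError:
                pass  # constant vector: correlation undefined, cell stays NaN
    return p_mat, rho_mat
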