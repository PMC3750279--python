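"""Base-pair prediction accuracy: sensitivity, PPV and F-measure.

A predicted pair is counted correct only if it is exactly identical to a
reference pair — one-position-shifted ("slipped") pairs earn no credit.
Sensitivity is correct / |reference pairs| and PPV is correct / |predicted
pairs|; when both structures are empty both measures are defined as 1, and
when exactly one is empty the measure whose denominator vanishes is 0.  The
F-measure is the harmonic mean of the two, taken as 0 when both are 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .structures import SecondaryStructure, StructureError


@dataclass(frozen=True)
class AccuracyRecord:
    sensitivity: float
    ppv: float
    f_measure: float


@dataclass(frozen=True)
class SetSummary:
    """Per-structure accuracy records plus their arithmetic means."""

    per_structure: tuple[AccuracyRecord, ...]
    mean_sensitivity: float
    mean_ppv: float
    mean_f: float


def _check_lengths(predicted: SecondaryStructure, reference: SecondaryStructure) -> None:
    if predicted.n != reference.n:
        raise StructureError(
            f"length mismatch: predicted n={predicted.n}, reference n={reference.n}"
        )


def count_correct(predicted: SecondaryStructure, reference: SecondaryStructure) -> int:
    """Number of predicted pairs exactly identical to a reference pair."""
    _check_lengths(predicted, reference)
    return len(predicted.pairs & reference.pairs)


def sensitivity(predicted: SecondaryStructure, reference: SecondaryStructure) -> float:
    _check_lengths(predicted, reference)
    if not reference.pairs:
        return 1.0 if not predicted.pairs else 0.0
    return count_correct(predicted, reference) / len(reference.pairs)


def ppv(predicted: SecondaryStructure, reference: SecondaryStructure) -> float:
    _check_lengths(predicted, reference)
    if not predicted.pairs:
        return 1.0 if not reference.pairs else 0.0
    return count_correct(predicted, reference) / len(predicted.pairs)


def f_measure(sens: float, ppv_val: float) -> float:
    """Harmonic mean of sensitivity and PPV; 0 when both are 0."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= ppv_val <= 1.0):
        raise ValueError("sensitivity and PPV must lie in [0, 1]")
    if sens + ppv_val == 0.0:
        return 0.0
    return 2.0 * sens * ppv_val / (sens + ppv_val)


def score_structure(predicted: SecondaryStructure, reference: SecondaryStructure) -> AccuracyRecord:
    s = sensitivity(predicted, reference)
    p = ppv(predicted, reference)
    return AccuracyRecord(sensitivity=s, ppv=p, f_measure=f_measure(s, p))


def evaluate_set(
    predictions: Sequence[SecondaryStructure],
    references: Sequence[SecondaryStructure],
) -> SetSummary:
    """Score index-aligned prediction/reference collections and average."""
    if len(predictions) != len(references):
        raise ValueError(
            f"misaligned collections: {len(predictions)} predictions, {len(references)} references"
        )
    if not predictions:
        raise ValueError("cannot evaluate an empty collection")
    records = tuple(
        score_structure(pred, ref) for pred, ref in zip(predictions, references)
    )
    m = len(records)
    return SetSummary(
        per_structure=records,
        mean_sensitivity=sum(r.sensitivity for r in records) / m,
        mean_ppv=sum(r.ppv for r in records) / m,
        mean_f=sum(r.f_measure for r in records) / m,
    )


def evaluation_table(
    predictions: Sequence[SecondaryStructure],
    references: Sequence[SecondaryStructure],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabular report: one row per structure plus a terminal mean row."""
    summary = evaluate_set(predictions, references)
    if ids is None:
        ids = [f"seq_{k + 1}" for k in range(len(predictions))]
    rows = []
    for ident, pred, ref, rec in zip(ids, predictions, references, summary.per_structure):
        rows.append(
            {
                "id": ident,
                "n": ref.n,
                "pairs_ref": len(ref.pairs),
                "pairs_pred": len(pred.pairs),
                "correct": count_correct(pred, ref),
                "sensitivity": rec.sensitivity,
                "ppv": rec.ppv,
                "f": rec.f_measure,
            }
        )
    rows.append(
        {
            "id": "MEAN",
            "n": "",
            "pairs_ref": "",
            "pairs_pred": "",
            "correct": "",
            "sensitivity": summary.mean_sensitivity,
            "ppv": summary.mean_ppv,
            "f": summary.mean_f,
        }
    )
    return pd.DataFrame(rows)
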