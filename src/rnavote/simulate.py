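"""Synthetic reference structures and imperfect predictor ensembles.

Real benchmarks pair trusted reference structures with the outputs of several
imperfect, partially correlated predictors.  This module emulates exactly
that: random pseudoknot-free reference structures (nested-interval sampling
with a minimum hairpin gap), per-predictor noisy copies (true pairs dropped
with probability ``drop_rate``; spurious but structurally compatible decoy
pairs added at rate ``decoy_rate``), and an optional ``correlation_share``
that makes a fraction of the noise decisions common to all predictors, so
predictor errors are correlated the way real prediction methods' errors are.

Base identities are drawn uniformly over {A, C, G, U}; they are irrelevant to
every computation here but required by the file formats.  Nothing about the
generator is thermodynamic — it makes no attempt to emulate any specific
prediction method's error profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble import PredictionSet
from .optimize import TrainingSet
from .structures import RnaSequence, SecondaryStructure, crosses

logger = logging.getLogger(__name__)

_MIN_HAIRPIN_GAP = 3  # unpaired bases enclosed by a hairpin-closing pair
_MIN_SPAN = _MIN_HAIRPIN_GAP + 1  # j - i for an admissible pair


@dataclass(frozen=True)
class NoiseModel:
    """Error profile of one synthetic predictor.

    drop_rate: per true pair, probability of omission.
    decoy_rate: expected number of spurious pairs added per structure.
    correlation_share: fraction of drop/decoy decisions shared across
        predictors (0 = independent errors, 1 = identical errors).
    """

    drop_rate: float = 0.3
    decoy_rate: float = 3.0
    correlation_share: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.drop_rate <= 1.0):
            raise ValueError("drop_rate must lie in [0, 1]")
        if self.decoy_rate < 0.0:
            raise ValueError("decoy_rate must be non-negative")
        if not (0.0 <= self.correlation_share <= 1.0):
            raise ValueError("correlation_share must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureConfig:
    n_sequences: int = 50
    length_range: tuple[int, int] = (40, 80)
    pairing_density: float = 0.5
    k_predictors: int = 5
    noise: NoiseModel | tuple[NoiseModel, ...] = NoiseModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.k_predictors < 1:
            raise ValueError("n_sequences and k_predictors must be positive")
        lo, hi = self.length_range
        if lo < 8 or hi < lo:
            raise ValueError("length_range lower bound must be >= 8 and <= upper")
        if not (0.0 <= self.pairing_density <= 1.0):
            raise ValueError("pairing_density must lie in [0, 1]")

    def noise_models(self) -> tuple[NoiseModel, ...]:
        if isinstance(self.noise, NoiseModel):
            return (self.noise,) * self.k_predictors
        if len(self.noise) != self.k_predictors:
            raise ValueError(
                f"{len(self.noise)} noise models for {self.k_predictors} predictors"
            )
        return tuple(self.noise)


def _compatible_candidates(
    n: int, taken: set[int], pairs: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for i in range(1, n - _MIN_SPAN + 1):
        if i in taken:
            continue
        for j in range(i + _MIN_SPAN, n + 1):
            if j in taken:
                continue
            cand = (i, j)
            if not any(crosses(cand, p) for p in pairs):
                out.append(cand)
    return out


def random_structure(
    length: int,
    pairing_density: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RnaSequence, SecondaryStructure]:
    """Random pseudoknot-free structure over a random sequence.

    Pairs are inserted one at a time, each drawn uniformly from the pairs
    still compatible with the current nested set and spanning at least
    ``_MIN_SPAN`` (so any hairpin-closing pair encloses >= 3 unpaired bases),
    until the fraction of paired bases reaches ``pairing_density`` or no
    candidate remains.  A shortfall against an unreachable density is logged,
    not raised.
    """
    if length < 8:
        raise ValueError("length must be >= 8")
    if rng is None:
        rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list("ACGU"), size=length))
    seq = RnaSequence(identifier=f"synthetic_{rng.integers(1, 10**9)}", residues=residues)
    target_paired = int(round(pairing_density * length))
    pairs: list[tuple[int, int]] = []
    taken: set[int] = set()
    while 2 * len(pairs) < target_paired:
        candidates = _compatible_candidates(length, taken, pairs)
        if not candidates:
            logger.debug(
                "density %.2f unreachable at n=%d: paired %d of %d",
                pairing_density, length, 2 * len(pairs), target_paired,
            )
            break
        i, j = candidates[rng.integers(len(candidates))]
        pairs.append((i, j))
        taken.update((i, j))
    return seq, SecondaryStructure(n=length, pairs=frozenset(pairs))


def perturb_structure(
    reference: SecondaryStructure,
    noise: NoiseModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SecondaryStructure:
    """Noisy copy of a reference: drop true pairs, add compatible decoys."""
    if rng is None:
        rng = np.random.default_rng(seed)
    kept = [p for p in sorted(reference.pairs) if rng.random() >= noise.drop_rate]
    n_decoys = int(rng.poisson(noise.decoy_rate))
    pairs = list(kept)
    taken = {p for pair in pairs for p in pair}
    for _ in range(n_decoys):
        candidates = [
            c
            for c in _compatible_candidates(reference.n, taken, pairs)
            if c not in reference.pairs
        ]
        if not candidates:
            break
        i, j = candidates[rng.integers(len(candidates))]
        pairs.append((i, j))
        taken.update((i, j))
    return SecondaryStructure(n=reference.n, pairs=frozenset(pairs))


def _correlated_predictions(
    reference: SecondaryStructure,
    noises: Sequence[NoiseModel],
    rng: np.random.Generator,
) -> list[SecondaryStructure]:
    """Per-predictor noisy structures with partially shared noise decisions."""
    ref_pairs = sorted(reference.pairs)
    # one shared uniform draw per true pair, reused by adopting predictors
    shared_keep_u = rng.random(len(ref_pairs))
    mean_decoy = float(np.mean([nm.decoy_rate for nm in noises]))
    n_shared_proposals = int(rng.poisson(mean_decoy))
    shared_proposals: list[tuple[int, int]] = []
    taken_probe: set[int] = set()
    probe_pairs: list[tuple[int, int]] = []
    for _ in range(n_shared_proposals):
        candidates = [
            c
            for c in _compatible_candidates(reference.n, taken_probe, probe_pairs)
            if c not in reference.pairs
        ]
        if not candidates:
            break
        cand = candidates[rng.integers(len(candidates))]
        shared_proposals.append(cand)
        probe_pairs.append(cand)
        taken_probe.update(cand)

    structures = []
    for nm in noises:
        kept: list[tuple[int, int]] = []
        for u_shared, pair in zip(shared_keep_u, ref_pairs):
            u = u_shared if rng.random() < nm.correlation_share else rng.random()
            if u >= nm.drop_rate:
                kept.append(pair)
        pairs = list(kept)
        taken = {p for pair in pairs for p in pair}

        def try_add(cand: tuple[int, int]) -> None:
            i, j = cand
            if i in taken or j in taken:
                return
            if any(crosses(cand, p) for p in pairs):
                return
            pairs.append(cand)
            taken.update(cand)

        for cand in shared_proposals:
            if rng.random() < nm.correlation_share:
                try_add(cand)
        n_own = int(rng.poisson(nm.decoy_rate * (1.0 - nm.correlation_share)))
        for _ in range(n_own):
            candidates = [
                c
                for c in _compatible_candidates(reference.n, taken, pairs)
                if c not in reference.pairs
            ]
            if not candidates:
                break
            try_add(candidates[rng.integers(len(candidates))])
        structures.append(SecondaryStructure(n=reference.n, pairs=frozenset(pairs)))
    return structures


def generate_ensemble_dataset(config: FixtureConfig) -> TrainingSet:
    """A full synthetic benchmark: references plus k noisy predictor outputs.

    Every sequence gets its own sub-generator spawned from the master seed,
    so the dataset is reproducible record by record.
    """
    noises = config.noise_models()
    master = np.random.SeedSequence(config.seed)
    records = []
    for idx, child in enumerate(master.spawn(config.n_sequences)):
        rng = np.random.default_rng(child)
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq, reference = random_structure(length, config.pairing_density, rng=rng)
        seq = RnaSequence(identifier=f"seq_{idx + 1:04d}", residues=seq.residues)
        predicted = _correlated_predictions(reference, noises, rng)
        preds = PredictionSet(
            sequence=seq,
            per_predictor={
                f"pred_{p + 1:02d}": struct for p, struct in enumerate(predicted)
            },
        )
        records.append((preds, reference))
    return TrainingSet(records=tuple(records))
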