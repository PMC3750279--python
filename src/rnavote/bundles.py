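"""Prediction-bundle layout: one structure file per predictor, keyed by id.

A bundle is a directory holding

* ``references.dbn`` — reference structures (optional for pure prediction),
* one ``<label>.dbn`` or ``<label>.ct`` per predictor, whose stem names the
  predictor.

Records are keyed by sequence id; ids must match across all files.  In strict
mode (the default) any id missing from any predictor file is an error listing
the offenders.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .ensemble import EnsembleError, PredictionSet
from .optimize import TrainingSet
from .structures import (
    RnaSequence,
    SecondaryStructure,
    read_ct_file,
    read_dotbracket_file,
    write_dotbracket_file,
)

REFERENCE_STEM = "references"


def _read_structure_file(path: Path) -> dict[str, tuple[RnaSequence, SecondaryStructure]]:
    if path.suffix == ".ct":
        records = read_ct_file(path)
    else:
        records = read_dotbracket_file(path)
    out: dict[str, tuple[RnaSequence, SecondaryStructure]] = {}
    for seq, struct in records:
        if seq.identifier in out:
            raise EnsembleError(f"duplicate id {seq.identifier!r} in {path}")
        out[seq.identifier] = (seq, struct)
    return out


def load_bundle(
    directory: str | Path, require_references: bool = True
) -> tuple[list[tuple[str, PredictionSet]], dict[str, SecondaryStructure] | None]:
    """Read a bundle directory into per-id prediction sets (id-sorted)."""
    directory = Path(directory)
    pred_files = sorted(
        p
        for p in list(directory.glob("*.dbn")) + list(directory.glob("*.ct"))
        if p.stem != REFERENCE_STEM
    )
    if not pred_files:
        raise EnsembleError(f"no predictor files (*.dbn/*.ct) in {directory}")
    per_predictor = {p.stem: _read_structure_file(p) for p in pred_files}

    id_sets = {label: set(recs) for label, recs in per_predictor.items()}
    all_ids = sorted(set.union(*id_sets.values()))
    offenders = {
        label: sorted(set(all_ids) - ids) for label, ids in id_sets.items() if set(all_ids) - ids
    }
    if offenders:
        detail = "; ".join(f"{label} missing {missing}" for label, missing in offenders.items())
        raise EnsembleError(f"id mismatch across predictor files: {detail}")

    references: dict[str, SecondaryStructure] | None = None
    ref_path = next(
        (directory / f"{REFERENCE_STEM}{ext}" for ext in (".dbn", ".ct")
         if (directory / f"{REFERENCE_STEM}{ext}").exists()),
        None,
    )
    if ref_path is not None:
        references = {ident: struct for ident, (_, struct) in _read_structure_file(ref_path).items()}
        missing_refs = sorted(set(all_ids) - set(references))
        if missing_refs:
            raise EnsembleError(f"references missing for ids {missing_refs}")
    elif require_references:
        raise EnsembleError(f"no {REFERENCE_STEM}.dbn/.ct in {directory}")

    sets: list[tuple[str, PredictionSet]] = []
    for ident in all_ids:
        seqs = {label: per_predictor[label][ident][0] for label in per_predictor}
        sequence = next(iter(seqs.values()))
        sets.append(
            (
                ident,
                PredictionSet(
                    sequence=sequence,
                    per_predictor={
                        label: per_predictor[label][ident][1] for label in per_predictor
                    },
                ),
            )
        )
    return sets, references


def bundle_to_training_set(directory: str | Path) -> TrainingSet:
    sets, references = load_bundle(directory, require_references=True)
    assert references is not None
    return TrainingSet(
        records=tuple((preds, references[ident]) for ident, preds in sets)
    )


def write_bundle(
    directory: str | Path,
    dataset: TrainingSet,
    header_comment: str | None = None,
) -> None:
    """Write a training set as a bundle directory of dot-bracket files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = dataset.predictors
    per_label: Mapping[str, list[tuple[RnaSequence, SecondaryStructure]]] = {
        label: [] for label in labels
    }
    refs: list[tuple[RnaSequence, SecondaryStructure]] = []
    for preds, ref in dataset.records:
        refs.append((preds.sequence, ref))
        for label in labels:
            per_label[label].append((preds.sequence, preds.per_predictor[label]))
    write_dotbracket_file(directory / f"{REFERENCE_STEM}.dbn", refs, header_comment)
    for label in labels:
        write_dotbracket_file(directory / f"{label}.dbn", per_label[label], header_comment)
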