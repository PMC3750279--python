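"""Core representations of RNA sequences and secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` with ``1 <= i < j <= n``
over a sequence of length ``n``, each position pairing at most once.  All
coordinates at module interfaces are 1-based and inclusive, following the CT
file convention.  Structures *stored* here may be pseudoknotted (the binary
pair-matrix view permits it), but everything inferred downstream is
pseudoknot-free and representable in single-family dot-bracket notation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

_RESIDUE_ALPHABET = set("ACGUN")


class StructureError(ValueError):
    """Raised for malformed structures or structure files."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with a short identifier.

    Residues are normalized on construction: ``T`` becomes ``U`` and any
    character outside ``{A, C, G, U, N}`` becomes ``N`` (with a warning), so
    heterogeneous predictor output is ingested tolerantly.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise StructureError("sequence identifier must be non-empty")
        if not self.residues:
            raise StructureError(f"sequence {self.identifier!r} has no residues")
        normalized = self.residues.upper().replace("T", "U")
        if not set(normalized) <= _RESIDUE_ALPHABET:
            bad = sorted(set(normalized) - _RESIDUE_ALPHABET)
            logger.warning(
                "sequence %r: unknown residues %s mapped to N", self.identifier, bad
            )
            normalized = "".join(c if c in _RESIDUE_ALPHABET else "N" for c in normalized)
        object.__setattr__(self, "residues", normalized)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over a sequence of length ``n``.

    Pairs are stored as ``(i, j)`` tuples with ``i < j``, 1-based.  Each
    position occurs in at most one pair (enforced at construction).
    """

    n: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise StructureError("structure length must be positive")
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        seen: set[int] = set()
        for i, j in pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(
                    f"pair ({i},{j}) violates 1 <= i < j <= n (n={self.n})"
                )
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair ({i},{j})")
            seen.add(i)
            seen.add(j)
        object.__setattr__(self, "pairs", pairs)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def __len__(self) -> int:
        return len(self.pairs)


def parse_dotbracket(structure_text: str, sequence_length: int | None = None) -> SecondaryStructure:
    """Parse single-family Vienna dot-bracket notation by stack matching.

    Only ``(``, ``)`` and ``.`` are accepted; extended bracket families are
    rejected because every in-scope structure is pseudoknot-free.  Errors name
    the offending 1-based position.
    """
    if sequence_length is None:
        sequence_length = len(structure_text)
    if len(structure_text) != sequence_length:
        raise StructureError(
            f"structure length {len(structure_text)} != sequence length {sequence_length}"
        )
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, char in enumerate(structure_text, start=1):
        if char == "(":
            stack.append(pos)
        elif char == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif char != ".":
            raise StructureError(f"illegal character {char!r} at position {pos}")
    if stack:
        raise StructureError(f"unclosed '(' at position {stack[-1]}")
    return SecondaryStructure(n=sequence_length, pairs=frozenset(pairs))


def render_dotbracket(structure: SecondaryStructure) -> str:
    """Render a pseudoknot-free structure as a dot-bracket string.

    Inverse of :func:`parse_dotbracket`; a pseudoknotted structure is not
    representable with one bracket family and raises ``StructureError``.
    """
    if not is_pseudoknot_free(structure):
        raise StructureError("pseudoknotted structure cannot be rendered in dot-bracket")
    chars = ["."] * structure.n
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def is_pseudoknot_free(structure: SecondaryStructure) -> bool:
    """True iff no two pairs cross, i.e. no (i,j), (k,l) with i < k < j < l.

    Uses a linear stack sweep: pairs are properly nestable exactly when,
    scanning positions left to right, every closing position matches the most
    recently opened pair.
    """
    opens: dict[int, int] = {}
    closes: dict[int, int] = {}
    for i, j in structure.pairs:
        opens[i] = j
        closes[j] = i
    stack: list[int] = []
    for pos in range(1, structure.n + 1):
        if pos in closes:
            if not stack or stack[-1] != pos:
                return False
            stack.pop()
        if pos in opens:
            stack.append(opens[pos])
    return True


def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True iff base pairs a and b cross (form a pseudoknot)."""
    (i, j), (k, l) = sorted((a, b))
    return i < k < j < l


def is_compatible(candidate: tuple[int, int], selected: SecondaryStructure) -> bool:
    """Can ``candidate`` join ``selected`` without reusing a base or crossing?"""
    i, j = candidate
    occupied = selected.paired_positions
    if i in occupied or j in occupied:
        return False
    return not any(crosses(candidate, pair) for pair in selected.pairs)


def to_pair_matrix(structure: SecondaryStructure) -> np.ndarray:
    """Binary symmetric n x n pair matrix: entry (i-1, j-1) = 1 for each pair."""
    mat = np.zeros((structure.n, structure.n), dtype=np.float64)
    for i, j in structure.pairs:
        mat[i - 1, j - 1] = 1.0
        mat[j - 1, i - 1] = 1.0
    return mat


# ---------------------------------------------------------------------------
# File formats: dot-bracket (Vienna) records, CT connectivity tables, FASTA.
# ---------------------------------------------------------------------------

def parse_ct(ct_text: str) -> tuple[RnaSequence, SecondaryStructure]:
    """Parse a single CT (connectivity table) record.

    Layout: a header line starting with the sequence length (the remainder is
    taken as the identifier), then one line per base with six columns::

        index  base  index-1  index+1  partner  natural-index

    ``partner`` 0 means unpaired.  Pairing must be symmetric: if row i names
    j, row j must name i.
    """
    lines = [ln for ln in ct_text.strip().splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT record")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureError(f"CT header does not start with a length: {lines[0]!r}") from exc
    identifier = " ".join(header[1:]) or "ct_record"
    if len(lines) - 1 != n:
        raise StructureError(f"CT declares {n} bases but has {len(lines) - 1} rows")
    residues: list[str] = []
    partner: dict[int, int] = {}
    for row_no, line in enumerate(lines[1:], start=1):
        cols = line.split()
        if len(cols) < 6:
            raise StructureError(f"malformed CT row {row_no}: {line!r}")
        try:
            idx, base, pair_to = int(cols[0]), cols[1], int(cols[4])
        except ValueError as exc:
            raise StructureError(f"malformed CT row {row_no}: {line!r}") from exc
        if idx != row_no:
            raise StructureError(f"CT row {row_no} carries index {idx}")
        if pair_to < 0 or pair_to > n:
            raise StructureError(f"CT row {row_no}: partner {pair_to} out of range")
        residues.append(base)
        partner[idx] = pair_to
    pairs: set[tuple[int, int]] = set()
    for i, j in partner.items():
        if j == 0:
            continue
        if partner.get(j) != i:
            raise StructureError(f"asymmetric pairing: row {i} says {j}, row {j} says {partner.get(j)}")
        if i < j:
            pairs.add((i, j))
    seq = RnaSequence(identifier=identifier, residues="".join(residues))
    return seq, SecondaryStructure(n=n, pairs=frozenset(pairs))


def render_ct(sequence: RnaSequence, structure: SecondaryStructure) -> str:
    """Render one CT record (inverse of :func:`parse_ct`)."""
    if sequence.n != structure.n:
        raise StructureError("sequence/structure length mismatch")
    partner = {i: 0 for i in range(1, structure.n + 1)}
    for i, j in structure.pairs:
        partner[i] = j
        partner[j] = i
    lines = [f"{structure.n} {sequence.identifier}"]
    for i, base in enumerate(sequence.residues, start=1):
        lines.append(f"{i} {base} {i - 1} {i + 1 if i < structure.n else 0} {partner[i]} {i}")
    return "\n".join(lines) + "\n"


def read_ct_file(path: str | Path) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Read a CT file holding one or more concatenated records."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    records: list[tuple[RnaSequence, SecondaryStructure]] = []
    pos = 0
    while pos < len(lines):
        try:
            n = int(lines[pos].split()[0])
        except (IndexError, ValueError) as exc:
            raise StructureError(f"bad CT header near line {pos + 1}: {lines[pos]!r}") from exc
        block = lines[pos : pos + n + 1]
        records.append(parse_ct("\n".join(block)))
        pos += n + 1
    return records


def read_dotbracket_file(path: str | Path) -> list[tuple[RnaSequence, SecondaryStructure]]:
    """Read a multi-record Vienna file: '>' id line, sequence line, structure line."""
    records: list[tuple[RnaSequence, SecondaryStructure]] = []
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith((";", "#"))
    ]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise StructureError(f"truncated record {lines[i]!r} in {path}")
        ident = lines[i][1:].strip()
        seq = RnaSequence(identifier=ident, residues=lines[i + 1])
        struct = parse_dotbracket(lines[i + 2], seq.n)
        records.append((seq, struct))
        i += 3
    return records


def write_dotbracket_file(
    path: str | Path,
    records: Iterable[tuple[RnaSequence, SecondaryStructure]],
    header_comment: str | None = None,
) -> None:
    out: list[str] = []
    if header_comment:
        out.extend(f"; {line}" for line in header_comment.splitlines())
    for seq, struct in records:
        out.append(f">{seq.identifier}")
        out.append(seq.residues)
        out.append(render_dotbracket(struct))
    Path(path).write_text("\n".join(out) + "\n")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read bare sequences from FASTA (via Biopython)."""
    from Bio import SeqIO

    return [
        RnaSequence(identifier=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
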