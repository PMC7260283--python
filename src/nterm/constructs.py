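"""Sequence constructs: tag insertion, point mutations and FASTA I/O.

The LeuT study inserts a 17-residue lanthanide binding tag (LBT,
``YWDTNNDGWYEGDELLA``) into extracellular loop 4 between A335 and G336,
and derives single-cysteine labeling sites (K4C, H7C, A9C) and
salt-bridge-breaking mutants (R5A, R30A) on that background.  This module
provides the bookkeeping for such constructs: flank-checked insertions,
wild-type-checked point mutations, and annotations that remember where
edits were made.

Numbering is 1-based on the construct's own sequence.  An insertion
shifts downstream numbering; annotations record ranges in the current
(post-edit) coordinates, with labels carrying the original wild-type
identifiers (e.g. ``LBT@335``, ``K4C``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: the 17-residue lanthanide binding tag used as the Tb3+ donor site
LBT_SEQUENCE = "YWDTNNDGWYEGDELLA"

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ConstructSequence:
    """An annotated amino-acid sequence, indexed from 1.

    Parameters
    ----------
    name:
        Record identifier (FASTA header word).
    residues:
        One-letter amino-acid codes, upper case.
    annotations:
        ``(start, end, label)`` triples in current 1-based coordinates,
        inclusive on both ends.
    """

    name: str
    residues: str
    annotations: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard amino-acid letters: {sorted(bad)}")
        for start, end, label in self.annotations:
            if not (1 <= start <= end <= len(self.residues)):
                raise ValueError(
                    f"annotation {label!r} range ({start}, {end}) outside "
                    f"[1, {len(self.residues)}]"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> str:
        """Return the one-letter code at 1-based ``index``."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"index {index} outside [1, {len(self.residues)}]")
        return self.residues[index - 1]


def insert_tag(
    seq: ConstructSequence,
    tag: str,
    after_index: int,
    expected_left: str,
    expected_right: str,
) -> ConstructSequence:
    """Insert ``tag`` after position ``after_index``, checking both flanks.

    The flank check guards against off-by-one construct errors: the
    residue at ``after_index`` must be ``expected_left`` and the residue
    at ``after_index + 1`` must be ``expected_right`` (for the LBT
    insertion these are A335 and G336).  An empty tag returns the input
    unchanged.
    """
    if not 1 <= after_index < len(seq):
        raise IndexError(
            f"insertion point {after_index} outside [1, {len(seq) - 1}]"
        )
    left = seq.residue(after_index)
    right = seq.residue(after_index + 1)
    if left != expected_left:
        raise ValueError(
            f"left flank mismatch at {after_index}: expected "
            f"{expected_left!r}, found {left!r}"
        )
    if right != expected_right:
        raise ValueError(
            f"right flank mismatch at {after_index + 1}: expected "
            f"{expected_right!r}, found {right!r}"
        )
    tag = tag.upper()
    if not tag:
        return seq
    residues = seq.residues[:after_index] + tag + seq.residues[after_index:]
    annotation = (after_index + 1, after_index + len(tag), f"insertion@{after_index}")
    return ConstructSequence(
        name=seq.name,
        residues=residues,
        annotations=seq.annotations + (annotation,),
    )


def delete_range(seq: ConstructSequence, start: int, end: int) -> ConstructSequence:
    """Delete residues ``start``..``end`` (1-based, inclusive).

    Inverse of :func:`insert_tag` when applied to the annotated range.
    Annotations covering the deleted range are dropped; others are kept
    only if they do not overlap it (their coordinates are shifted).
    """
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(f"range ({start}, {end}) outside [1, {len(seq)}]")
    residues = seq.residues[: start - 1] + seq.residues[end:]
    width = end - start + 1
    kept = []
    for a_start, a_end, label in seq.annotations:
        if a_end < start:
            kept.append((a_start, a_end, label))
        elif a_start > end:
            kept.append((a_start - width, a_end - width, label))
        # overlapping annotations are removed together with the range
    return ConstructSequence(seq.name, residues, tuple(kept))


def apply_mutation(seq: ConstructSequence, spec: str) -> ConstructSequence:
    """Apply a point mutation given as ``"<wt><index><new>"`` (e.g. K4C).

    The wild-type letter is checked against the sequence before the
    substitution is made, so stale mutation specs fail loudly.
    """
    match = _MUTATION_RE.match(spec.strip().upper())
    if match is None:
        raise ValueError(f"malformed mutation spec: {spec!r}")
    wt, index, new = match.group(1), int(match.group(2)), match.group(3)
    if wt not in AMINO_ACIDS or new not in AMINO_ACIDS:
        raise ValueError(f"non-standard amino acid in mutation spec {spec!r}")
    found = seq.residue(index)
    if found != wt:
        raise ValueError(
            f"wild-type mismatch for {spec}: position {index} is {found!r}, "
            f"expected {wt!r}"
        )
    residues = seq.residues[: index - 1] + new + seq.residues[index:]
    annotation = (index, index, spec.strip().upper())
    return replace(seq, residues=residues, annotations=seq.annotations + (annotation,))


def read_fasta(path) -> list[ConstructSequence]:
    """Read single- or multi-record FASTA; case is normalized to upper."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [
        ConstructSequence(name=rec.id, residues=str(rec.seq).upper())
        for rec in records
    ]


def write_fasta(sequences, path) -> None:
    """Write constructs to FASTA (annotations go into the description)."""
    records = []
    for seq in sequences:
        desc = " ".join(
            f"{label}:{start}-{end}" for start, end, label in seq.annotations
        )
        records.append(SeqRecord(Seq(seq.residues), id=seq.name, description=desc))
    SeqIO.write(records, str(path), "fasta")
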