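"""Sequence model for two interacting RNAs.

Two RNA strands R' (length n) and R'' (length m) are folded jointly by
concatenating them into a single working sequence R = R' N R'' of length
l = n + m + 1, where the separator character ``N`` at position n + 1 can
never base-pair.  All public coordinates are 1-based and inclusive, in
the 5'->3' direction of each strand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

SEPARATOR = "N"
_ALPHABET = frozenset("ACGU")


class SequenceError(ValueError):
    """Raised for malformed or unsupported RNA sequence input."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated single-stranded RNA sequence over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside [1, {len(self.residues)}]")
        return self.residues[pos - 1]


class Owner(enum.Enum):
    """Which strand a position of the concatenated sequence belongs to."""

    FIRST = "first"
    SEPARATOR = "separator"
    SECOND = "second"


@dataclass(frozen=True)
class JointSequence:
    """The concatenation R = R' N R'' with l = n + m + 1."""

    first: RnaSequence
    second: RnaSequence
    residues: str
    separator_pos: int

    @property
    def n(self) -> int:
        return len(self.first)

    @property
    def m(self) -> int:
        return len(self.second)

    @property
    def length(self) -> int:
        return len(self.residues)

    def base(self, pos: int) -> str:
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside [1, {self.length}]")
        return self.residues[pos - 1]

    def owner(self, pos: int) -> Owner:
        return position_owner(self, pos)

    def to_local(self, pos: int) -> tuple[Owner, int]:
        """Map a joint position to (owner, 1-based local coordinate).

        The separator maps to local coordinate 0.
        """
        who = position_owner(self, pos)
        if who is Owner.FIRST:
            return who, pos
        if who is Owner.SEPARATOR:
            return who, 0
        return who, pos - self.n - 1


def normalize_sequence(raw: str, id: str = "rna") -> RnaSequence:
    """Validate and normalize raw sequence text into an :class:`RnaSequence`.

    Whitespace is stripped, lowercase is uppercased and T (DNA deposits)
    is read as U.  Any other character is rejected with its position.
    """
    cleaned = "".join(raw.split())
    if not cleaned:
        raise SequenceError(f"sequence {id!r} is empty")
    out = []
    for i, ch in enumerate(cleaned, start=1):
        up = ch.upper()
        if up == "T":
            up = "U"
        if up not in _ALPHABET:
            raise SequenceError(
                f"sequence {id!r}: invalid character {ch!r} at position {i}"
            )
        out.append(up)
    return RnaSequence(id=id, residues="".join(out))


def concatenate(first: RnaSequence, second: RnaSequence) -> JointSequence:
    """Join two strands into R = R' N R''."""
    residues = first.residues + SEPARATOR + second.residues
    return JointSequence(
        first=first,
        second=second,
        residues=residues,
        separator_pos=len(first) + 1,
    )


def position_owner(js: JointSequence, pos: int) -> Owner:
    """Partition [1, l] into FIRST (<= n), SEPARATOR (n+1) and SECOND (>= n+2)."""
    if not 1 <= pos <= js.length:
        raise IndexError(f"position {pos} outside [1, {js.length}]")
    if pos < js.separator_pos:
        return Owner.FIRST
    if pos == js.separator_pos:
        return Owner.SEPARATOR
    return Owner.SECOND


def split(js: JointSequence) -> tuple[RnaSequence, RnaSequence]:
    """Inverse of :func:`concatenate`."""
    n = js.separator_pos - 1
    return (
        RnaSequence(id=js.first.id, residues=js.residues[:n]),
        RnaSequence(id=js.second.id, residues=js.residues[n + 1 :]),
    )


def read_fasta_pair(
    path: str | Path, second_path: str | Path | None = None
) -> tuple[RnaSequence, RnaSequence]:
    """Read the two interacting RNAs from FASTA.

    Accepts either one file containing exactly two records, or two files
    with one record each.  Multi-line records and CRLF line endings are
    handled by the underlying parser; T is accepted as U.
    """
    if second_path is None:
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 2:
            raise SequenceError(
                f"{path}: expected exactly 2 FASTA records, found {len(records)}"
            )
    else:
        records = []
        for p in (path, second_path):
            recs = list(SeqIO.parse(str(p), "fasta"))
            if len(recs) != 1:
                raise SequenceError(
                    f"{p}: expected exactly 1 FASTA record, found {len(recs)}"
                )
            records.append(recs[0])
    return (
        normalize_sequence(str(records[0].seq), id=records[0].id),
        normalize_sequence(str(records[1].seq), id=records[1].id),
    )
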