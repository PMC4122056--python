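"""Genotypes over the sub-diagonal set and their structural phenotypes.

An individual of the genetic algorithm is a bit-tuple over D^R: bit k
activates candidate helix d_k.  The phenotype is built by walking the
helices in the fixed D^R order and keeping, for each active helix, the
pairs that neither reuse a base already claimed by an earlier helix nor
cross an accepted pair of the same class (first-come-wins).  Pairs left
without a stacked neighbor are then pruned to fixpoint, so no lonely
pair survives.  Hybrid pairs may freely cross intramolecular pairs —
that is exactly a kissing-hairpin interaction — but each intramolecular
set stays nested and the hybrid set stays antiparallel-consistent, so
every phenotype is energy-evaluable and renderable.

The joint structure is written as two dot-bracket lines: ``(`` / ``)``
for stems inside a strand, ``[`` on R' matching ``]`` on R'' for hybrid
pairs (the i-th ``[`` 5'->3' on R' pairs the i-th ``]`` counted from the
3' end of R'', the antiparallel convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .dotmatrix import Category, Pair, SubDiagonal, SubDiagonalSet
from .sequences import JointSequence, Owner

__all__ = [
    "Genotype",
    "Individual",
    "JointStructure",
    "StructureError",
    "construct_individual",
    "remove_lonely",
    "render_joint_dotbracket",
    "parse_joint_dotbracket",
    "read_joint_structure",
    "write_joint_structure",
]


class StructureError(ValueError):
    """Raised for structures that violate the joint-structure contract."""


@dataclass(frozen=True)
class Genotype:
    """Bit-tuple aligned to a :class:`SubDiagonalSet`."""

    bits: tuple[int, ...]
    active_cap: int | None = None

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("genotype bits must be 0/1")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def num_active(self) -> int:
        return sum(self.bits)


def crosses(p: Pair, q: Pair) -> bool:
    """True iff the arcs (a, b) and (c, d) cross (interleave)."""
    a, b = p
    c, d = q
    return (a < c < b < d) or (c < a < d < b)


def _is_nested(pairs: frozenset[Pair]) -> bool:
    ordered = sorted(pairs)
    for i, p in enumerate(ordered):
        for q in ordered[i + 1 :]:
            if q[0] > p[1]:
                break
            if crosses(p, q):
                return False
    return True


@dataclass(frozen=True)
class JointStructure:
    """Final pair sets, in local 1-based coordinates of each strand.

    ``hybrid`` holds pairs (p, q) with p on R' and q on R''.
    """

    intra_first: frozenset[Pair] = frozenset()
    intra_second: frozenset[Pair] = frozenset()
    hybrid: frozenset[Pair] = frozenset()

    @staticmethod
    def make(
        intra_first=(), intra_second=(), hybrid=()
    ) -> "JointStructure":
        return JointStructure(
            frozenset(tuple(p) for p in intra_first),
            frozenset(tuple(p) for p in intra_second),
            frozenset(tuple(p) for p in hybrid),
        )

    @property
    def num_pairs(self) -> int:
        return len(self.intra_first) + len(self.intra_second) + len(self.hybrid)

    def validate(self) -> None:
        """Assert base-disjointness, nestedness and hybrid consistency."""
        for name, pairs in (
            ("intra_first", self.intra_first),
            ("intra_second", self.intra_second),
        ):
            for a, b in pairs:
                if a >= b:
                    raise StructureError(f"{name}: pair ({a}, {b}) not ordered")
            if not _is_nested(pairs):
                raise StructureError(f"{name}: crossing pairs")
        used_first: set[int] = set()
        used_second: set[int] = set()
        for a, b in self.intra_first:
            for x in (a, b):
                if x in used_first:
                    raise StructureError(f"R' base {x} paired twice")
                used_first.add(x)
        for a, b in self.intra_second:
            for x in (a, b):
                if x in used_second:
                    raise StructureError(f"R'' base {x} paired twice")
                used_second.add(x)
        for p, q in self.hybrid:
            if p in used_first:
                raise StructureError(f"R' base {p} paired twice")
            if q in used_second:
                raise StructureError(f"R'' base {q} paired twice")
            used_first.add(p)
            used_second.add(q)
        ordered = sorted(self.hybrid)
        for (p1, q1), (p2, q2) in zip(ordered, ordered[1:]):
            if not q1 > q2:
                raise StructureError(
                    f"hybrid pairs ({p1},{q1}) and ({p2},{q2}) cross"
                )


@dataclass
class Individual:
    """A genotype together with its resolved phenotype and cached fitness."""

    genotype: Genotype
    components: tuple[frozenset[Pair], ...]  # C_k sets, joint coordinates
    component_indices: tuple[int, ...]  # D^R index of each nonempty C_k
    structure: JointStructure
    fitness: float | None = None

    @property
    def all_pairs(self) -> frozenset[Pair]:
        out: set[Pair] = set()
        for c in self.components:
            out |= c
        return frozenset(out)


def remove_lonely(pairs: set[Pair] | frozenset[Pair]) -> frozenset[Pair]:
    """Delete pairs without a stacked neighbor, repeating to fixpoint.

    A pair (a, b) is lonely when neither (a+1, b-1) nor (a-1, b+1) is in
    the set; removing one pair can isolate another, hence the loop.
    """
    current = set(pairs)
    while True:
        lonely = {
            (a, b)
            for a, b in current
            if (a + 1, b - 1) not in current and (a - 1, b + 1) not in current
        }
        if not lonely:
            return frozenset(current)
        current -= lonely


def _to_joint_structure(
    components: list[tuple[Category, frozenset[Pair]]], js: JointSequence
) -> JointStructure:
    intra_first: set[Pair] = set()
    intra_second: set[Pair] = set()
    hybrid: set[Pair] = set()
    n = js.n
    for category, pairs in components:
        for a, b in pairs:
            if category is Category.INTRA_FIRST:
                intra_first.add((a, b))
            elif category is Category.INTRA_SECOND:
                intra_second.add((a - n - 1, b - n - 1))
            else:
                hybrid.add((a, b - n - 1))
    return JointStructure(
        frozenset(intra_first), frozenset(intra_second), frozenset(hybrid)
    )


def construct_individual(
    bits: Genotype, diagonals: SubDiagonalSet, js: JointSequence
) -> Individual:
    """Resolve a genotype into a conflict-free phenotype (first-come-wins).

    Helices are visited in the deterministic D^R order; for each active
    helix the surviving pair set C_k is its pairs minus base-sharing
    conflicts with anything already accepted, minus same-class crossing
    conflicts, then pruned of lonely pairs.  Empty C_k are dropped.
    """
    if len(bits) != len(diagonals):
        raise ValueError(
            f"genotype length {len(bits)} != |D^R| = {len(diagonals)}"
        )
    used_bases: set[int] = set()
    accepted_by_class: dict[Category, list[Pair]] = {c: [] for c in Category}
    components: list[tuple[Category, frozenset[Pair]]] = []
    component_indices: list[int] = []

    for k, (bit, diag) in enumerate(zip(bits.bits, diagonals)):
        if not bit:
            continue
        same_class = accepted_by_class[diag.category]
        survivors = [
            (a, b)
            for a, b in diag.pairs
            if a not in used_bases
            and b not in used_bases
            and not any(crosses((a, b), q) for q in same_class)
        ]
        kept = remove_lonely(set(survivors))
        if not kept:
            continue
        for a, b in kept:
            used_bases.add(a)
            used_bases.add(b)
        same_class.extend(kept)
        components.append((diag.category, kept))
        component_indices.append(k)

    structure = _to_joint_structure(components, js)
    structure.validate()
    return Individual(
        genotype=bits,
        components=tuple(pairs for _, pairs in components),
        component_indices=tuple(component_indices),
        structure=structure,
    )


# --- joint dot-bracket rendering / parsing ---------------------------------


def render_joint_dotbracket(
    s: JointStructure, js: JointSequence
) -> tuple[str, str]:
    """Render a structure as the two-line joint dot-bracket notation."""
    s.validate()
    n, m = js.n, js.m
    line1 = ["."] * n
    line2 = ["."] * m

    def put(line: list[str], pos: int, ch: str, length: int, label: str) -> None:
        if not 1 <= pos <= length:
            raise StructureError(f"{label} position {pos} outside [1, {length}]")
        if line[pos - 1] != ".":
            raise StructureError(f"{label} position {pos} doubly occupied")
        line[pos - 1] = ch

    for a, b in s.intra_first:
        put(line1, a, "(", n, "R'")
        put(line1, b, ")", n, "R'")
    for a, b in s.intra_second:
        put(line2, a, "(", m, "R''")
        put(line2, b, ")", m, "R''")
    for p, q in s.hybrid:
        put(line1, p, "[", n, "R'")
        put(line2, q, "]", m, "R''")
    return "".join(line1), "".join(line2)


def _match_parens(line: str, which: str) -> set[Pair]:
    pairs: set[Pair] = set()
    stack: list[int] = []
    for i, ch in enumerate(line, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"{which}: unbalanced ')' at position {i}"
                )
            pairs.add((stack.pop(), i))
    if stack:
        raise StructureError(
            f"{which}: unbalanced '(' at position {stack[-1]}"
        )
    return pairs


def parse_joint_dotbracket(line1: str, line2: str) -> JointStructure:
    """Parse the two-line notation back into a :class:`JointStructure`."""
    for which, line, alphabet in (
        ("R' line", line1, "().["),
        ("R'' line", line2, "().]"),
    ):
        for i, ch in enumerate(line, start=1):
            if ch not in alphabet:
                raise StructureError(
                    f"{which}: invalid character {ch!r} at position {i}"
                )
    intra_first = _match_parens(line1, "R' line")
    intra_second = _match_parens(line2, "R'' line")
    opens = [i for i, ch in enumerate(line1, start=1) if ch == "["]
    closes = [i for i, ch in enumerate(line2, start=1) if ch == "]"]
    if len(opens) != len(closes):
        raise StructureError(
            f"hybrid brackets unbalanced: {len(opens)} '[' vs {len(closes)} ']'"
        )
    # i-th '[' on R' pairs the i-th ']' from the 3' end of R''.
    hybrid = {(p, q) for p, q in zip(opens, reversed(closes))}
    structure = JointStructure(
        frozenset(intra_first), frozenset(intra_second), frozenset(hybrid)
    )
    structure.validate()
    return structure


def write_joint_structure(
    path: str | Path, s: JointStructure, js: JointSequence
) -> None:
    """Write sequence + structure as a four-line joint dot-bracket file."""
    line1, line2 = render_joint_dotbracket(s, js)
    Path(path).write_text(
        f"{js.first.residues}\n{line1}\n{js.second.residues}\n{line2}\n"
    )


def read_joint_structure(path: str | Path) -> JointStructure:
    """Read a joint dot-bracket file (two bracket lines, or four lines
    with each bracket line preceded by its sequence)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith((">", "#"))]
    if len(lines) == 2:
        return parse_joint_dotbracket(lines[0], lines[1])
    if len(lines) == 4:
        return parse_joint_dotbracket(lines[1], lines[3])
    raise StructureError(
        f"{path}: expected 2 or 4 content lines, found {len(lines)}"
    )
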