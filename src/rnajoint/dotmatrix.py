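"""Complementarity dot matrix and candidate stem / hybrid enumeration.

The working sequence R is plotted against its reverse: cell (i, j) is 1
iff residues r_i and r_{l-j+1} can pair (Watson-Crick A-U / C-G or the
G-U wobble).  Every maximal anti-diagonal run of 1s — a *sub-diagonal* —
is a candidate helix: a stem inside one strand or a hybrid region
between the two strands.  The set of sub-diagonals D^R is the search
space the genetic algorithm optimizes over.

Because wobble pairs are markedly weaker than Watson-Crick pairs, a
percentage filter strips G-U pairs from candidate helices in which they
are over-represented (default threshold 14%, a statistic of curated
interacting sRNA-mRNA pairs), re-segmenting the survivors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .sequences import JointSequence, Owner

Pair = tuple[int, int]

COMPLEMENTARY: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)
WOBBLE: frozenset[tuple[str, str]] = frozenset([("G", "U"), ("U", "G")])


class Category(enum.Enum):
    """Homogeneous kind of a sub-diagonal; order fixes enumeration order."""

    INTRA_FIRST = 0
    INTRA_SECOND = 1
    HYBRID = 2


@dataclass(frozen=True)
class DotMatrix:
    """Binary matrix M[i, j] = 1 iff (r_i, r_{l-j+1}) is a valid pair."""

    size: int
    cells: np.ndarray  # bool, shape (l, l); 0-based internally

    def cell(self, i: int, j: int) -> int:
        """Value at 1-based matrix coordinates (i, j)."""
        if not (1 <= i <= self.size and 1 <= j <= self.size):
            raise IndexError(f"cell ({i}, {j}) outside [1, {self.size}]^2")
        return int(self.cells[i - 1, j - 1])

    def pair_value(self, a: int, b: int) -> int:
        """Value for the base pair (a, b), i.e. cell (a, l - b + 1)."""
        return self.cell(a, self.size - b + 1)


@dataclass(frozen=True)
class SubDiagonal:
    """A maximal run of t+1 consecutive candidate pairs (a+s, b-s)."""

    pairs: tuple[Pair, ...]
    category: Category
    gu_flags: tuple[bool, ...]
    size: int  # l of the joint sequence, for coordinate bookkeeping

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.gu_flags):
            raise ValueError("pairs and gu_flags length mismatch")

    @property
    def row_start(self) -> int:
        return self.pairs[0][0]

    @property
    def col_start(self) -> int:
        return self.size - self.pairs[0][1] + 1

    @property
    def extent(self) -> int:
        """The run parameter t: number of pairs minus one."""
        return len(self.pairs) - 1

    @property
    def num_pairs(self) -> int:
        return len(self.pairs)

    @property
    def gu_fraction(self) -> float:
        return sum(self.gu_flags) / len(self.pairs)

    def sort_key(self) -> tuple[int, int, int]:
        a0, b0 = self.pairs[0]
        return (self.category.value, a0, -b0)


@dataclass(frozen=True)
class SubDiagonalSet:
    """All sub-diagonals of a joint sequence in a fixed deterministic order.

    Ordering: category (stems of R', stems of R'', hybrids), then first
    pair's smaller index ascending, then larger index descending.
    """

    diagonals: tuple[SubDiagonal, ...]
    ordering_key: str = "category, first-pair a ascending, b descending"

    def __len__(self) -> int:
        return len(self.diagonals)

    def __iter__(self):
        return iter(self.diagonals)

    def __getitem__(self, k: int) -> SubDiagonal:
        return self.diagonals[k]

    def to_tsv(self) -> str:
        """Debug dump: one line per sub-diagonal."""
        lines = ["category\ta_start\tb_start\tnum_pairs\tgu_fraction\tpairs"]
        for d in self.diagonals:
            pair_txt = ";".join(f"{a}-{b}" for a, b in d.pairs)
            lines.append(
                f"{d.category.name}\t{d.pairs[0][0]}\t{d.pairs[0][1]}"
                f"\t{d.num_pairs}\t{d.gu_fraction:.4f}\t{pair_txt}"
            )
        return "\n".join(lines) + "\n"


def _pair_bases(js: JointSequence, a: int, b: int) -> tuple[str, str]:
    return js.base(a), js.base(b)


def is_complementary(js: JointSequence, a: int, b: int) -> bool:
    return _pair_bases(js, a, b) in COMPLEMENTARY


def is_wobble(js: JointSequence, a: int, b: int) -> bool:
    return _pair_bases(js, a, b) in WOBBLE


def build_matrix(js: JointSequence) -> DotMatrix:
    """Build the l x l complementarity matrix of R against reverse R."""
    l = js.length
    order = "ACGUN"
    codes = np.fromiter(
        (order.index(c) for c in js.residues), dtype=np.int8, count=l
    )
    table = np.zeros((5, 5), dtype=bool)
    for x, y in COMPLEMENTARY:
        table[order.index(x), order.index(y)] = True
    cells = table[codes[:, None], codes[::-1][None, :]]
    return DotMatrix(size=l, cells=cells)


def pair_category(js: JointSequence, a: int, b: int) -> Category:
    """Category of pair (a, b); both ends must avoid the separator."""
    oa, ob = js.owner(a), js.owner(b)
    if oa is Owner.FIRST and ob is Owner.FIRST:
        return Category.INTRA_FIRST
    if oa is Owner.SECOND and ob is Owner.SECOND:
        return Category.INTRA_SECOND
    if oa is Owner.FIRST and ob is Owner.SECOND:
        return Category.HYBRID
    raise ValueError(f"pair ({a}, {b}) touches the separator")


def _pair_predicate(
    js: JointSequence, min_hairpin_loop: int
) -> Callable[[int, int], bool]:
    """Validity of a canonical candidate pair (a < b), with exclusions.

    Excluded: self/inverted pairs (a >= b), pairs touching the
    separator, non-complementary bases, and intramolecular pairs that
    would enclose fewer than ``min_hairpin_loop`` unpaired bases.
    """
    sep = js.separator_pos
    l = js.length

    def valid(a: int, b: int) -> bool:
        if not (1 <= a < b <= l):
            return False
        if a == sep or b == sep:
            return False
        if not is_complementary(js, a, b):
            return False
        same_side = (b < sep) or (a > sep)
        if same_side and (b - a - 1) < min_hairpin_loop:
            return False
        return True

    return valid


def extract_subdiagonals(
    matrix: DotMatrix,
    js: JointSequence,
    min_pairs: int = 2,
    min_hairpin_loop: int = 3,
) -> SubDiagonalSet:
    """Enumerate all maximal candidate helices of the joint sequence.

    Scans every anti-diagonal a + b = const of the pair space and
    collects maximal runs of valid consecutive pairs (a+s, b-s) of
    length >= ``min_pairs``.  Only canonical pairs a < b are considered,
    so each biological pair appears exactly once (the matrix itself is
    mirror-symmetric).
    """
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    if min_hairpin_loop < 0:
        raise ValueError("min_hairpin_loop must be >= 0")
    l = js.length
    valid = _pair_predicate(js, min_hairpin_loop)

    found: list[SubDiagonal] = []
    for total in range(3, 2 * l):  # a + b, with a < b
        run: list[Pair] = []
        a_lo = max(1, total - l)
        a_hi = (total - 1) // 2  # largest a with a < b
        for a in range(a_lo, a_hi + 1):
            b = total - a
            if matrix.pair_value(a, b) and valid(a, b):
                run.append((a, b))
            else:
                if len(run) >= min_pairs:
                    found.append(_make_subdiagonal(js, run))
                run = []
        if len(run) >= min_pairs:
            found.append(_make_subdiagonal(js, run))

    found.sort(key=SubDiagonal.sort_key)
    return SubDiagonalSet(diagonals=tuple(found))


def _make_subdiagonal(js: JointSequence, run: list[Pair]) -> SubDiagonal:
    return SubDiagonal(
        pairs=tuple(run),
        category=pair_category(js, *run[0]),
        gu_flags=tuple(is_wobble(js, a, b) for a, b in run),
        size=js.length,
    )


def filter_gu(
    diagonals: SubDiagonalSet,
    gu_threshold: float = 0.14,
    min_pairs: int = 2,
) -> SubDiagonalSet:
    """Strip wobble pairs from candidate helices over-rich in them.

    A sub-diagonal whose G-U fraction strictly exceeds ``gu_threshold``
    has its G-U pairs removed; the remaining pairs are re-segmented into
    maximal consecutive runs and runs shorter than ``min_pairs`` are
    dropped.  Sub-diagonals at or below the threshold pass unchanged.
    """
    if not 0.0 <= gu_threshold <= 1.0:
        raise ValueError("gu_threshold must be in [0, 1]")
    out: list[SubDiagonal] = []
    for d in diagonals:
        if d.gu_fraction <= gu_threshold:
            out.append(d)
            continue
        run_pairs: list[Pair] = []
        run_flags: list[bool] = []
        segments: list[tuple[list[Pair], list[bool]]] = []
        for pair, gu in zip(d.pairs, d.gu_flags):
            if gu:
                if run_pairs:
                    segments.append((run_pairs, run_flags))
                run_pairs, run_flags = [], []
            else:
                run_pairs.append(pair)
                run_flags.append(gu)
        if run_pairs:
            segments.append((run_pairs, run_flags))
        for pairs, flags in segments:
            if len(pairs) >= min_pairs:
                out.append(
                    SubDiagonal(
                        pairs=tuple(pairs),
                        category=d.category,
                        gu_flags=tuple(flags),
                        size=d.size,
                    )
                )
    out.sort(key=SubDiagonal.sort_key)
    return SubDiagonalSet(diagonals=tuple(out))
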