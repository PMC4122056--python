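"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rnajoint.dotmatrix import COMPLEMENTARY
from rnajoint.sequences import JointSequence, RnaSequence, concatenate, normalize_sequence

# The worked example pair used throughout the docs: a 14-mer pair whose
# joint structure has one stem per strand and two kissing hybrid regions.
EXAMPLE_FIRST = "CGGUUUGAGGUCCG"
EXAMPLE_SECOND = "ACUACCGAAAAGUU"


@pytest.fixture
def example_pair() -> tuple[RnaSequence, RnaSequence]:
    return (
        normalize_sequence(EXAMPLE_FIRST, "R1"),
        normalize_sequence(EXAMPLE_SECOND, "R2"),
    )


@pytest.fixture
def example_joint(example_pair) -> JointSequence:
    return concatenate(*example_pair)


def random_rna(rng: np.random.Generator, length: int, name: str = "rna") -> RnaSequence:
    residues = "".join("ACGU"[int(i)] for i in rng.integers(0, 4, size=length))
    return RnaSequence(id=name, residues=residues)


def random_joint(rng: np.random.Generator, max_len: int = 15) -> JointSequence:
    n = int(rng.integers(1, max_len + 1))
    m = int(rng.integers(1, max_len + 1))
    return concatenate(random_rna(rng, n, "a"), random_rna(rng, m, "b"))


def oracle_subdiagonals(
    js: JointSequence, min_pairs: int = 2, min_hairpin_loop: int = 3
) -> set[tuple[tuple[int, int], ...]]:
    """Brute-force enumeration of maximal candidate runs.

    Tests every (a, b, length) triple directly against the pairing
    predicate and the exclusion rules, independent of the dot-matrix
    scan; a triple is kept iff all its pairs are valid and it cannot be
    extended on either side.
    """
    sep = js.separator_pos
    l = js.length

    def ok(a: int, b: int) -> bool:
        if not (1 <= a < b <= l):
            return False
        if a == sep or b == sep:
            return False
        if (js.base(a), js.base(b)) not in COMPLEMENTARY:
            return False
        if (b < sep or a > sep) and (b - a - 1) < min_hairpin_loop:
            return False
        return True

    runs: set[tuple[tuple[int, int], ...]] = set()
    for a in range(1, l + 1):
        for b in range(a + 1, l + 1):
            for num in range(min_pairs, l + 1):
                pairs = tuple((a + s, b - s) for s in range(num))
                if not all(ok(x, y) for x, y in pairs):
                    continue
                if ok(a - 1, b + 1) or ok(a + num, b - num):
                    continue  # extensible, not maximal
                runs.add(pairs)
    return runs
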