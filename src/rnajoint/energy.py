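"""Free-energy evaluation of joint structures.

The fitness of an individual is MFE(S) + MFE(H): the energy of the two
intramolecular secondary structures plus the energy of the hybrid
(intermolecular) pairs, each evaluated separately and summed.  Energy
evaluation is pluggable: any object satisfying :class:`EnergyModel` can
be used.  The built-in :class:`SimpleNearestNeighborModel` is a
simplified Turner-style nearest-neighbor scheme with a small embedded
constant table, chosen so that every example energy can be recomputed by
hand; an adapter to an external structure-evaluation program (ViennaRNA
``RNAeval``) is provided as an alternative backend.

All energies are in kcal/mol; lower is more stable.
"""

from __future__ import annotations

import math
import re
import subprocess
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .dotmatrix import Pair, WOBBLE
from .genotype import Individual, JointStructure, crosses
from .sequences import JointSequence, RnaSequence


class EnergyContractError(ValueError):
    """Input violates the energy-model contract (e.g. crossing pairs)."""


class AdapterError(RuntimeError):
    """The external evaluator failed or produced unparseable output."""


@runtime_checkable
class EnergyModel(Protocol):
    """Contract every energy backend must satisfy.

    Empty structures evaluate to exactly 0.0 and every structure that
    satisfies the phenotype invariants gets a finite energy.
    """

    name: str

    def evaluate_intra(self, seq: RnaSequence, pairs: frozenset[Pair]) -> float: ...

    def evaluate_hybrid(
        self,
        first: RnaSequence,
        second: RnaSequence,
        hybrid: frozenset[Pair],
    ) -> float: ...


def _flip(pt: str) -> str:
    return pt[1] + pt[0]


def _build_stack_table() -> dict[tuple[str, str], float]:
    # Canonical entries; the strand-flip mirror stack(p, q) ==
    # stack(flip(q), flip(p)) is filled in programmatically so a helix
    # scores the same read from either strand.
    canonical: dict[tuple[str, str], float] = {
        ("AU", "AU"): -0.9,
        ("AU", "UA"): -1.1,
        ("UA", "AU"): -1.3,
        ("AU", "CG"): -2.2,
        ("AU", "GC"): -2.1,
        ("UA", "CG"): -2.4,
        ("UA", "GC"): -2.1,
        ("CG", "CG"): -3.3,
        ("CG", "GC"): -2.4,
        ("GC", "CG"): -3.4,
        ("AU", "GU"): -0.6,
        ("AU", "UG"): -1.4,
        ("UA", "GU"): -1.0,
        ("UA", "UG"): -1.3,
        ("CG", "GU"): -1.4,
        ("CG", "UG"): -2.1,
        ("GC", "GU"): -1.5,
        ("GC", "UG"): -2.5,
        ("GU", "GU"): -0.5,
        ("GU", "UG"): 0.5,
        ("UG", "GU"): -0.2,
    }
    table = dict(canonical)
    for (p, q), e in canonical.items():
        mirror = (_flip(q), _flip(p))
        if mirror in table and table[mirror] != e:
            raise AssertionError(f"inconsistent stack mirror {mirror}")
        table[mirror] = e
    if len(table) != 36:
        raise AssertionError(f"stack table has {len(table)} entries, not 36")
    return table


@dataclass(frozen=True)
class SimpleNearestNeighborModel:
    """Simplified nearest-neighbor model with embedded constants.

    - ``stack_table``: energy of each ordered adjacent-pair stack,
      read outer pair -> inner pair along increasing 5' coordinate.
    - hairpin penalty ``hairpin_a + hairpin_b * ln(size)`` (size >= 3);
    - bulge/internal penalty ``internal_a + internal_b * ln(size)``;
    - multiloop ``multiloop_init + multiloop_branch * branches``;
    - ``duplex_init`` once per maximal hybrid region;
    - ``gu_end`` per helix/region terminus closed by a wobble pair.
    """

    name: str = "simple-nn"
    hairpin_a: float = 3.5
    hairpin_b: float = 1.1
    internal_a: float = 1.7
    internal_b: float = 1.1
    multiloop_init: float = 3.4
    multiloop_branch: float = 0.4
    duplex_init: float = 4.1
    gu_end: float = 0.5

    @property
    def stack_table(self) -> dict[tuple[str, str], float]:
        return _STACK_TABLE

    # -- shared pieces ------------------------------------------------

    def hairpin_penalty(self, size: int) -> float:
        if size < 3:
            raise EnergyContractError(f"hairpin loop of size {size} < 3")
        return self.hairpin_a + self.hairpin_b * math.log(size)

    def loop_penalty(self, size: int) -> float:
        """Bulge / internal-loop penalty for ``size`` unpaired bases."""
        if size < 1:
            raise EnergyContractError(f"loop size {size} < 1")
        return self.internal_a + self.internal_b * math.log(size)

    def stack(self, outer: str, inner: str) -> float:
        try:
            return _STACK_TABLE[(outer, inner)]
        except KeyError:
            raise EnergyContractError(
                f"non-complementary stack {outer}/{inner}"
            ) from None

    # -- intramolecular -----------------------------------------------

    def evaluate_intra(
        self, seq: RnaSequence, pairs: frozenset[Pair]
    ) -> float:
        if not pairs:
            return 0.0
        ordered = sorted(pairs)
        pairset = set(ordered)
        seen: set[int] = set()
        for a, b in ordered:
            if a >= b or a in seen or b in seen:
                raise EnergyContractError(f"pair ({a}, {b}) reuses a base")
            seen.update((a, b))
        for i, p in enumerate(ordered):
            for q in ordered[i + 1 :]:
                if q[0] > p[1]:
                    break
                if crosses(p, q):
                    raise EnergyContractError(f"crossing pairs {p} and {q}")

        def pt(a: int, b: int) -> str:
            return seq.base(a) + seq.base(b)

        # Build the nesting tree (parent = innermost enclosing pair).
        children: dict[Pair, list[Pair]] = {p: [] for p in ordered}
        stack: list[Pair] = []
        for p in ordered:
            while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
                stack.pop()
            if stack:
                children[stack[-1]].append(p)
            stack.append(p)

        energy = 0.0
        for a, b in ordered:
            if (a + 1, b - 1) in pairset:
                energy += self.stack(pt(a, b), pt(a + 1, b - 1))
            else:
                kids = children[(a, b)]
                if not kids:
                    energy += self.hairpin_penalty(b - a - 1)
                elif len(kids) == 1:
                    (c, d) = kids[0]
                    energy += self.loop_penalty((c - a - 1) + (b - d - 1))
                else:
                    energy += (
                        self.multiloop_init
                        + self.multiloop_branch * (len(kids) + 1)
                    )
            if pt(a, b) in ("GU", "UG"):
                if (a - 1, b + 1) not in pairset:
                    energy += self.gu_end
                if (a + 1, b - 1) not in pairset:
                    energy += self.gu_end
        return energy

    # -- intermolecular -----------------------------------------------

    def evaluate_hybrid(
        self,
        first: RnaSequence,
        second: RnaSequence,
        hybrid: frozenset[Pair],
    ) -> float:
        if not hybrid:
            return 0.0
        ordered = sorted(hybrid)
        for (p1, q1), (p2, q2) in zip(ordered, ordered[1:]):
            if p1 == p2 or q1 <= q2:
                raise EnergyContractError(
                    f"hybrid pairs ({p1},{q1}) and ({p2},{q2}) conflict"
                )

        def pt(p: int, q: int) -> str:
            return first.base(p) + second.base(q)

        # Maximal regions of consecutive pairs (p+1, q-1).
        regions: list[list[Pair]] = [[ordered[0]]]
        for pair in ordered[1:]:
            prev = regions[-1][-1]
            if pair == (prev[0] + 1, prev[1] - 1):
                regions[-1].append(pair)
            else:
                regions.append([pair])

        energy = 0.0
        for region in regions:
            energy += self.duplex_init
            for (p1, q1), (p2, q2) in zip(region, region[1:]):
                energy += self.stack(pt(p1, q1), pt(p2, q2))
            for p, q in (region[0], region[-1]):
                if pt(p, q) in ("GU", "UG"):
                    energy += self.gu_end
        for left, right in zip(regions, regions[1:]):
            gap = (right[0][0] - left[-1][0] - 1) + (left[-1][1] - right[0][1] - 1)
            energy += self.loop_penalty(gap)
        return energy


_STACK_TABLE = _build_stack_table()

DEFAULT_MODEL = SimpleNearestNeighborModel()


def fitness(
    model: EnergyModel, individual: Individual, js: JointSequence
) -> float:
    """Fitness(P) = MFE(S) + MFE(H); cached on the individual."""
    s = individual.structure
    value = (
        model.evaluate_intra(js.first, s.intra_first)
        + model.evaluate_intra(js.second, s.intra_second)
        + model.evaluate_hybrid(js.first, js.second, s.hybrid)
    )
    individual.fitness = value
    return value


# --- external evaluator adapter -------------------------------------------

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


class ExternalEvaluatorModel:
    """Energy backend that shells out to a dot-bracket evaluator.

    The command (default ``RNAeval``) must read ``sequence\\nstructure``
    on stdin and print the structure followed by its energy in
    parentheses; intermolecular calls use the two-strand ``&`` dialect.
    """

    def __init__(self, command: str = "RNAeval") -> None:
        self.command = command
        self.name = f"external:{command}"

    def _call(self, seq: str, db: str) -> float:
        try:
            proc = subprocess.run(
                self.command.split(),
                input=f"{seq}\n{db}\n",
                capture_output=True,
                text=True,
                timeout=60,
            )
        except FileNotFoundError as exc:
            raise AdapterError(
                f"external evaluator {self.command!r} not found; "
                "use the built-in nearest-neighbor model instead"
            ) from exc
        if proc.returncode != 0:
            raise AdapterError(
                f"{self.command} exited with {proc.returncode}: {proc.stderr}"
            )
        for line in reversed(proc.stdout.splitlines()):
            match = _ENERGY_RE.search(line.strip())
            if match:
                return float(match.group(1))
        raise AdapterError(
            f"could not parse energy from {self.command} output:\n{proc.stdout}"
        )

    def evaluate_intra(
        self, seq: RnaSequence, pairs: frozenset[Pair]
    ) -> float:
        if not pairs:
            return 0.0
        db = ["."] * len(seq)
        for a, b in sorted(pairs):
            db[a - 1] = "("
            db[b - 1] = ")"
        return self._call(seq.residues, "".join(db))

    def evaluate_hybrid(
        self,
        first: RnaSequence,
        second: RnaSequence,
        hybrid: frozenset[Pair],
    ) -> float:
        if not hybrid:
            return 0.0
        db1 = ["."] * len(first)
        db2 = ["."] * len(second)
        for p, q in sorted(hybrid):
            db1[p - 1] = "("
            db2[q - 1] = ")"
        return self._call(
            f"{first.residues}&{second.residues}",
            "".join(db1) + "&" + "".join(db2),
        )


def external_evaluator_adapter(
    structure: JointStructure,
    js: JointSequence,
    command: str = "RNAeval",
) -> float:
    """Evaluate MFE(S) + MFE(H) of a structure with an external program."""
    model = ExternalEvaluatorModel(command)
    return (
        model.evaluate_intra(js.first, structure.intra_first)
        + model.evaluate_intra(js.second, structure.intra_second)
        + model.evaluate_hybrid(js.first, js.second, structure.hybrid)
    )


def get_model(selector: str = "builtin") -> EnergyModel:
    """Resolve an energy-model selector string to a backend."""
    if selector == "builtin":
        return SimpleNearestNeighborModel()
    if selector.startswith("external"):
        _, _, cmd = selector.partition(":")
        return ExternalEvaluatorModel(cmd or "RNAeval")
    raise ValueError(f"unknown energy model {selector!r}")
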