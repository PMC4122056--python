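"""Synthetic interacting-RNA pairs with a planted ground-truth structure.

The generator emulates the kind of data the predictor targets: each
strand carries one or more hairpin stems, and the loop of the first
hairpin of each strand holds a planted hybrid site — loop-loop pairing,
i.e. a kissing-hairpin interaction.  Planted stems and the hybrid are
perfectly Watson-Crick complementary; everything else is background.
With the LOW_COMPLEMENT background, non-planted positions are all A
and planted element sequences are drawn from {G, C}: no U occurs
anywhere, so background bases cannot pair at all and the only
complementarity in the pair is among the strong G:C planted elements
(plus short accidental G:C runs between them).  The RANDOM background
draws everything uniformly over A/C/G/U instead, adding realistic
spurious complementarity and weaker planted helices.

Every fixture is deterministic in its seed and ships with the truth as
a :class:`~rnajoint.genotype.JointStructure`, so predictions can be
scored without any external data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype import JointStructure, render_joint_dotbracket
from .sequences import RnaSequence, concatenate

_WC_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class FixtureError(ValueError):
    """An infeasible fixture layout was requested."""


class Background(enum.Enum):
    LOW_COMPLEMENT = "low-complement"
    RANDOM = "random"


_BACKGROUND_ALPHABET = {
    Background.LOW_COMPLEMENT: "A",
    Background.RANDOM: "ACGU",
}
_ELEMENT_ALPHABET = {
    Background.LOW_COMPLEMENT: "GC",
    Background.RANDOM: "ACGU",
}


@dataclass(frozen=True)
class PlantedFixture:
    first: RnaSequence
    second: RnaSequence
    truth: JointStructure
    seed: int
    design: dict

    def to_fasta(self) -> str:
        return (
            f">{self.first.id}\n{self.first.residues}\n"
            f">{self.second.id}\n{self.second.residues}\n"
        )


def _revcomp(seq: str) -> str:
    return "".join(_WC_COMPLEMENT[c] for c in reversed(seq))


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> list[str]:
    return [alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=length)]


def _spread_slack(
    rng: np.random.Generator, slack: int, bins: int
) -> list[int]:
    """Randomly distribute ``slack`` extra bases over ``bins`` gaps."""
    out = [0] * bins
    for _ in range(slack):
        out[int(rng.integers(0, bins))] += 1
    return out


def _plan_strand(
    rng: np.random.Generator,
    length: int,
    stem_lens: list[int],
    first_loop_len: int,
    min_hairpin_loop: int,
    label: str,
) -> list[tuple[int, int, int, int]]:
    """Place hairpins on one strand; returns (arm_start, loop_start,
    loop_len, stem_len) per hairpin, 1-based."""
    loop_lens = []
    for i, s in enumerate(stem_lens):
        loop_lens.append(first_loop_len if i == 0 else max(min_hairpin_loop, 3))
    block_sizes = [2 * s + lp for s, lp in zip(stem_lens, loop_lens)]
    # one background base between consecutive blocks
    min_total = sum(block_sizes) + max(0, len(block_sizes) - 1)
    if min_total > length:
        raise FixtureError(
            f"{label}: need {min_total} bases for the planted elements "
            f"but only {length} available"
        )
    extras = _spread_slack(rng, length - min_total, len(block_sizes) + 1)
    placements = []
    cursor = 1 + extras[0]
    for i, (s, lp) in enumerate(zip(stem_lens, loop_lens)):
        placements.append((cursor, cursor + s, lp, s))
        cursor += 2 * s + lp
        if i < len(stem_lens) - 1:
            cursor += 1 + extras[i + 1]
    return placements


def generate_fixture(
    seed: int,
    n: int = 30,
    m: int = 30,
    num_stems_each: int = 1,
    stem_len: tuple[int, int] = (4, 4),
    hybrid_len: tuple[int, int] = (8, 8),
    background: Background = Background.LOW_COMPLEMENT,
    min_hairpin_loop: int = 3,
) -> PlantedFixture:
    """Generate a deterministic planted interacting pair.

    ``stem_len`` and ``hybrid_len`` are inclusive ranges sampled per
    element / per fixture.  With ``num_stems_each == 0`` the hybrid
    site sits in an otherwise unstructured strand.
    """
    if stem_len[0] < 2 and num_stems_each > 0:
        raise FixtureError("stem_len must be >= 2 so stems survive lonely-pair removal")
    if hybrid_len[0] < 2:
        raise FixtureError("hybrid_len must be >= 2 so the hybrid survives lonely-pair removal")
    rng = np.random.default_rng(seed)
    alphabet = _BACKGROUND_ALPHABET[background]
    element_alphabet = _ELEMENT_ALPHABET[background]

    hlen = int(rng.integers(hybrid_len[0], hybrid_len[1] + 1))
    first_loop = hlen + 2  # one background margin on each side of the site

    strands: list[str] = []
    intra_sets: list[set[tuple[int, int]]] = []
    hybrid_sites: list[int] = []  # start of the hybrid site on each strand
    for length, label in ((n, "first strand"), (m, "second strand")):
        stem_lens = [
            int(rng.integers(stem_len[0], stem_len[1] + 1))
            for _ in range(num_stems_each)
        ]
        chars = _random_seq(rng, alphabet, length)
        pairs: set[tuple[int, int]] = set()
        if num_stems_each > 0:
            placements = _plan_strand(
                rng, length, stem_lens, first_loop, min_hairpin_loop, label
            )
            for arm_start, loop_start, loop_len, s in placements:
                left = _random_seq(rng, element_alphabet, s)
                right = list(_revcomp("".join(left)))
                right_start = loop_start + loop_len
                for i in range(s):
                    chars[arm_start - 1 + i] = left[i]
                    chars[right_start - 1 + i] = right[i]
                    pairs.add((arm_start + i, right_start + s - 1 - i))
            loop_start, loop_len = placements[0][1], placements[0][2]
        else:
            if length < hlen + 2:
                raise FixtureError(
                    f"{label}: length {length} cannot host a hybrid site of {hlen}"
                )
            loop_start, loop_len = 2, length - 2
        site_start = loop_start + (loop_len - hlen) // 2
        hybrid_sites.append(site_start)
        strands.append("".join(chars))
        intra_sets.append(pairs)

    # Thread the hybrid: R' site random, R'' site its reverse complement.
    site1 = _random_seq(rng, element_alphabet, hlen)
    site2 = _revcomp("".join(site1))
    chars1, chars2 = list(strands[0]), list(strands[1])
    p0, q0 = hybrid_sites
    hybrid_pairs: set[tuple[int, int]] = set()
    for i in range(hlen):
        chars1[p0 - 1 + i] = site1[i]
        chars2[q0 - 1 + i] = site2[i]
        hybrid_pairs.add((p0 + i, q0 + hlen - 1 - i))

    first = RnaSequence(id="planted_first", residues="".join(chars1))
    second = RnaSequence(id="planted_second", residues="".join(chars2))
    truth = JointStructure(
        frozenset(intra_sets[0]), frozenset(intra_sets[1]), frozenset(hybrid_pairs)
    )
    truth.validate()
    return PlantedFixture(
        first=first,
        second=second,
        truth=truth,
        seed=seed,
        design={
            "n": n,
            "m": m,
            "num_stems_each": num_stems_each,
            "hybrid_len": hlen,
            "hybrid_site_first": p0,
            "hybrid_site_second": q0,
            "background": background.value,
        },
    )


def write_fixture(fixture: PlantedFixture, directory: str | Path) -> dict[str, Path]:
    """Write FASTA + truth joint dot-bracket; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "pair.fasta"
    fasta.write_text(fixture.to_fasta())
    js = concatenate(fixture.first, fixture.second)
    line1, line2 = render_joint_dotbracket(fixture.truth, js)
    truth = directory / "truth.dbn"
    truth.write_text(
        f"{fixture.first.residues}\n{line1}\n{fixture.second.residues}\n{line2}\n"
    )
    return {"fasta": fasta, "truth": truth}
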