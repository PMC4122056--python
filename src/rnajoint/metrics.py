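"""Base-pair-level accuracy metrics for joint structures.

Predictions are scored against a reference structure by counting
correctly predicted (TP), falsely predicted (FP) and missed (FN) base
pairs, either over the whole joint structure (intramolecular pairs of
both strands plus hybrid pairs, each tagged by kind) or over the hybrid
binding-site pairs only.  From the counts:

    Sn  = 100 * TP / (TP + FN)          sensitivity
    PPV = 100 * TP / (TP + FP)          positive predictive value
    F   = 2 * Sn * PPV / (Sn + PPV)     harmonic mean
    MCC = sqrt(Sn * PPV)                geometric mean

All four are reported on the 0-100 percentage scale.  Degenerate
denominators (no predicted or no reference pairs) yield 0 with a logged
warning rather than an error, matching how empty predictions are scored
in published benchmark tables.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from .genotype import JointStructure

logger = logging.getLogger(__name__)


class Mode(enum.Enum):
    JOINT = "joint"
    BINDING_SITES_ONLY = "binding-sites"


@dataclass(frozen=True)
class PairSetComparison:
    tp: int
    fp: int
    fn: int
    mode: Mode

    @property
    def num_reference(self) -> int:
        return self.tp + self.fn

    @property
    def num_predicted(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricReport:
    sn: float
    ppv: float
    f: float
    mcc: float


def _tagged(structure: JointStructure, mode: Mode) -> set[tuple]:
    if mode is Mode.BINDING_SITES_ONLY:
        return {("hybrid", p, q) for p, q in structure.hybrid}
    out = {("intra1", a, b) for a, b in structure.intra_first}
    out |= {("intra2", a, b) for a, b in structure.intra_second}
    out |= {("hybrid", p, q) for p, q in structure.hybrid}
    return out


def compare(
    predicted: JointStructure,
    reference: JointStructure,
    mode: Mode = Mode.JOINT,
    n: int | None = None,
    m: int | None = None,
) -> PairSetComparison:
    """Count TP/FP/FN base pairs of a prediction against a reference.

    ``n`` and ``m``, when given, bound the local coordinates of both
    structures; a pair outside them means the structures belong to
    different sequences and is an error.
    """
    if n is not None or m is not None:
        for label, s in (("predicted", predicted), ("reference", reference)):
            for which, pairs, limit in (
                ("R'", s.intra_first, n),
                ("R''", s.intra_second, m),
            ):
                if limit is None:
                    continue
                for a, b in pairs:
                    if b > limit:
                        raise ValueError(
                            f"{label} {which} pair ({a}, {b}) exceeds length {limit}"
                        )
            for p, q in s.hybrid:
                if n is not None and p > n:
                    raise ValueError(f"{label} hybrid position {p} exceeds {n}")
                if m is not None and q > m:
                    raise ValueError(f"{label} hybrid position {q} exceeds {m}")
    pred = _tagged(predicted, mode)
    ref = _tagged(reference, mode)
    return PairSetComparison(
        tp=len(pred & ref),
        fp=len(pred - ref),
        fn=len(ref - pred),
        mode=mode,
    )


def sensitivity(c: PairSetComparison) -> float:
    if c.tp + c.fn == 0:
        logger.warning("no reference pairs: sensitivity defined as 0")
        return 0.0
    return 100.0 * c.tp / (c.tp + c.fn)


def ppv(c: PairSetComparison) -> float:
    if c.tp + c.fp == 0:
        logger.warning("no predicted pairs: PPV defined as 0")
        return 0.0
    return 100.0 * c.tp / (c.tp + c.fp)


def f_measure(sn: float, ppv_value: float) -> float:
    """Harmonic mean of sensitivity and PPV (percent scale)."""
    if sn < 0 or ppv_value < 0:
        raise ValueError("Sn and PPV must be non-negative")
    if sn + ppv_value == 0:
        return 0.0
    return 2.0 * sn * ppv_value / (sn + ppv_value)


def mcc(sn: float, ppv_value: float) -> float:
    """Geometric mean sqrt(Sn * PPV) (percent scale)."""
    if sn < 0 or ppv_value < 0:
        raise ValueError("Sn and PPV must be non-negative")
    return math.sqrt(sn * ppv_value)


def report(c: PairSetComparison) -> MetricReport:
    sn = sensitivity(c)
    p = ppv(c)
    return MetricReport(sn=sn, ppv=p, f=f_measure(sn, p), mcc=mcc(sn, p))


# --- printed-table consistency checking ------------------------------------


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places, as tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def printed_decimals(value: float) -> int:
    """Number of decimal places a printed table value carries."""
    text = repr(value)
    if "." not in text:
        return 0
    frac = text.split(".", 1)[1].rstrip("0")
    return len(frac)


def truncate(value: float, decimals: int) -> float:
    """Truncate (round toward zero) at ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class RowCheck:
    label: str
    sn: float
    ppv: float
    f_recomputed: float
    f_printed: float
    consistent: bool
    # An inconsistent row may still be a faithful *truncated* rendering
    # of the recomputed value: flagged, but only a printing artifact.
    truncation_rendered: bool


@dataclass(frozen=True)
class TableConsistencyReport:
    rows: tuple[RowCheck, ...]
    mean_sn: float
    mean_ppv: float
    mean_f_printed: float

    @property
    def flagged(self) -> tuple[RowCheck, ...]:
        return tuple(r for r in self.rows if not r.consistent)


def table_consistency_report(
    rows: list[tuple[str, float, float, float]],
) -> TableConsistencyReport:
    """Recompute F from each row's Sn/PPV and check it against print.

    Each row is (label, sn, ppv, printed_f).  The recomputed F is
    rounded half-up to the printed value's own precision before
    comparison; mismatching rows are flagged, never silently adjusted.
    Column means of the printed values are recomputed as well.
    """
    checks: list[RowCheck] = []
    for label, sn, p, printed_f in rows:
        f_exact = f_measure(sn, p)
        decimals = printed_decimals(printed_f)
        f_rounded = round_half_up(f_exact, decimals)
        consistent = f_rounded == printed_f
        checks.append(
            RowCheck(
                label=label,
                sn=sn,
                ppv=p,
                f_recomputed=f_rounded,
                f_printed=printed_f,
                consistent=consistent,
                truncation_rendered=(
                    not consistent and truncate(f_exact, decimals) == printed_f
                ),
            )
        )
    count = len(rows) or 1
    return TableConsistencyReport(
        rows=tuple(checks),
        mean_sn=sum(r[1] for r in rows) / count,
        mean_ppv=sum(r[2] for r in rows) / count,
        mean_f_printed=sum(r[3] for r in rows) / count,
    )
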