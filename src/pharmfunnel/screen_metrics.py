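"""Pharmacophore screen validation statistics (Guner-Henry analysis).

Given the four counts of a retrospective active/decoy screen —

* ``D``  total molecules in the validation database,
* ``A``  known actives among them,
* ``Ht`` total hits returned by the screen,
* ``Ha`` actives among the hits,

computes the standard enrichment diagnostics:

* percent yield of actives  ``100 * Ha / Ht``  (precision),
* percent ratio of actives  ``100 * Ha / A``   (recall),
* enrichment factor         ``EF = (Ha/Ht) / (A/D)``,
* false positives/negatives ``Ht - Ha`` and ``A - Ha``,
* Guner-Henry score         ``GH = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha)/(D - A)]``,

where GH = 1 indicates a perfect screen and EF = 1 a random one.
"""

from __future__ import annotations

from dataclasses import dataclass


class UndefinedStatisticError(ZeroDivisionError):
    """A ratio statistic was requested with a zero denominator."""


@dataclass(frozen=True)
class ScreenCounts:
    """Counts of a retrospective screen over a database of known labels."""

    D: int
    A: int
    Ht: int
    Ha: int

    def __post_init__(self) -> None:
        if not (0 <= self.Ha <= min(self.A, self.Ht)):
            raise ValueError("need 0 <= Ha <= min(A, Ht)")
        if self.Ht > self.D or self.A > self.D:
            raise ValueError("Ht and A cannot exceed D")

    @classmethod
    def from_labels(cls, is_active, is_hit) -> "ScreenCounts":
        """Build counts from parallel boolean sequences."""
        is_active = [bool(x) for x in is_active]
        is_hit = [bool(x) for x in is_hit]
        if len(is_active) != len(is_hit):
            raise ValueError("label sequences differ in length")
        return cls(
            D=len(is_active),
            A=sum(is_active),
            Ht=sum(is_hit),
            Ha=sum(a and h for a, h in zip(is_active, is_hit)),
        )


@dataclass(frozen=True)
class ScreenStats:
    yield_pct: float
    ratio_pct: float
    EF: float
    FP: int
    FN: int
    GH: float


def yield_of_actives(c: ScreenCounts) -> float:
    """Percent of hits that are active: 100 * Ha / Ht."""
    if c.Ht < 1:
        raise UndefinedStatisticError("yield undefined for Ht = 0")
    return 100.0 * c.Ha / c.Ht


def ratio_of_actives(c: ScreenCounts) -> float:
    """Percent of actives recovered: 100 * Ha / A."""
    if c.A < 1:
        raise UndefinedStatisticError("ratio undefined for A = 0")
    return 100.0 * c.Ha / c.A


def enrichment_factor(c: ScreenCounts) -> float:
    """(Ha/Ht) / (A/D); 1 means no better than random selection."""
    if c.Ht < 1:
        raise UndefinedStatisticError("EF undefined for Ht = 0")
    if c.A < 1:
        raise UndefinedStatisticError("EF undefined for A = 0")
    return (c.Ha / c.Ht) / (c.A / c.D)


def goodness_of_hit(c: ScreenCounts) -> float:
    """Guner-Henry composite of precision and recall, 1 = perfect."""
    if c.Ht < 1 or c.A < 1:
        raise UndefinedStatisticError("GH undefined for Ht = 0 or A = 0")
    if c.D == c.A:
        raise UndefinedStatisticError("GH undefined when D = A (no decoys)")
    precision_part = c.Ha * (3 * c.A + c.Ht) / (4.0 * c.Ht * c.A)
    decoy_part = 1.0 - (c.Ht - c.Ha) / float(c.D - c.A)
    return precision_part * decoy_part


def summarize(c: ScreenCounts) -> ScreenStats:
    """All validation statistics at full precision."""
    return ScreenStats(
        yield_pct=yield_of_actives(c),
        ratio_pct=ratio_of_actives(c),
        EF=enrichment_factor(c),
        FP=c.Ht - c.Ha,
        FN=c.A - c.Ha,
        GH=goodness_of_hit(c),
    )


def round2(x: float) -> float:
    """Half-to-even rounding at 2 decimals on the decimal value.

    Statistics from integer counts are exact decimals (e.g. GH = 0.495
    for model 3), so rounding is done on a 10-digit decimal rendering
    rather than the raw binary float, giving 0.495 -> 0.50.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    return float(Decimal(f"{x:.10f}").quantize(Decimal("0.01"), ROUND_HALF_EVEN))


_round2 = round2


def format_report(c: ScreenCounts, name: str = "model") -> str:
    """Human-readable validation table for one screen."""
    s = summarize(c)
    lines = [
        f"Pharmacophore validation — {name}",
        f"  Database size (D)        {c.D}",
        f"  Known actives (A)        {c.A}",
        f"  Total hits (Ht)          {c.Ht}",
        f"  Active hits (Ha)         {c.Ha}",
        f"  % yield of actives       {_round2(s.yield_pct)}",
        f"  % ratio of actives       {_round2(s.ratio_pct)}",
        f"  Enrichment factor (EF)   {_round2(s.EF)}",
        f"  False positives          {s.FP}",
        f"  False negatives          {s.FN}",
        f"  Goodness of hit (GH)     {_round2(s.GH)}",
    ]
    return "\n".join(lines)
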