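"""Dose schemes, total-daily-dose arithmetic and regimen redistribution.

Regimens use the German ``morning-noon-evening(-night)`` notation: "1-0-1"
means one dose unit in the morning and one in the evening. Slots are exact
rationals so that half and quarter tablets and all dose comparisons are free
of floating-point artefacts.

:func:`redistribute` is the dose-recomputation step of the switch algorithm:
given a target total daily dose and a candidate product (strength +
divisibility), find the administration scheme that best achieves the target,
preferring simple regimens (fewest administrations, least tablet splitting,
doses early in the day) among equally accurate ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from ._util import as_fraction, fraction_to_float
from .catalogue import DrugProduct
from .config import EngineConfig

__all__ = [
    "Regimen",
    "Prescription",
    "RedistributionResult",
    "parse_scheme",
    "scheme_to_text",
    "total_daily_dose",
    "redistribute",
]

_SLOT_RE = re.compile(r"^\d+(\.\d+)?$|^\d+/\d+$|^\d+ \d+/\d+$")


def _parse_slot(text: str) -> Fraction:
    text = text.strip()
    if not _SLOT_RE.match(text):
        raise ValueError(f"unparseable slot {text!r}")
    if " " in text:  # mixed number, e.g. "1 1/2"
        whole, frac = text.split(" ")
        return Fraction(whole) + Fraction(frac)
    return as_fraction(text)


@dataclass(frozen=True)
class Regimen:
    """Administration scheme: dose units at (morning, noon, evening, night).

    Unparseable free-text schemes are retained verbatim with
    ``free_text_flag`` set — they are never silently dropped, and downstream
    the engine routes them to manual handling.
    """

    slots: tuple[Fraction, Fraction, Fraction, Fraction] = (
        Fraction(0), Fraction(0), Fraction(0), Fraction(0),
    )
    free_text: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "slots", tuple(as_fraction(s) for s in self.slots))
        if len(self.slots) != 4:
            raise ValueError("a regimen has exactly four slots")
        if any(s < 0 for s in self.slots):
            raise ValueError("slots must be non-negative")
        if self.free_text is None and not any(s > 0 for s in self.slots):
            raise ValueError("at least one slot must be > 0 (or flag free text)")

    @property
    def free_text_flag(self) -> bool:
        return self.free_text is not None

    @property
    def total_units(self) -> Fraction:
        return sum(self.slots, Fraction(0))

    @property
    def n_administrations(self) -> int:
        return sum(1 for s in self.slots if s > 0)

    @property
    def requires_splitting(self) -> bool:
        return any(s.denominator != 1 for s in self.slots)

    def fits_divisibility(self, divisibility: int) -> bool:
        """True when every slot is a multiple of 1/divisibility."""
        return all((s * divisibility).denominator == 1 for s in self.slots)


def parse_scheme(text: str) -> Regimen:
    """Parse ``a-b-c`` / ``a-b-c-d`` scheme strings into a :class:`Regimen`.

    Slot values may be integers, decimals ("0.5", decimal point only) or
    fractions ("1/2", "1 1/2"). Anything else — "2 Hub morgens", an empty
    string, a five-slot scheme — comes back flagged as free text.
    """
    parts = [p.strip() for p in text.strip().split("-")]
    if len(parts) not in (3, 4):
        return Regimen(free_text=text)
    try:
        slots = [_parse_slot(p) for p in parts]
    except ValueError:
        return Regimen(free_text=text)
    if len(slots) == 3:
        slots.append(Fraction(0))
    if not any(s > 0 for s in slots):
        return Regimen(free_text=text)
    return Regimen(slots=tuple(slots))


def _format_slot(x: Fraction) -> str:
    if x.denominator == 1:
        return str(x.numerator)
    whole, rem = divmod(x.numerator, x.denominator)
    frac = f"{rem}/{x.denominator}"
    return frac if whole == 0 else f"{whole} {frac}"


def scheme_to_text(regimen: Regimen) -> str:
    """Serialize back to the four-slot dialect with fractions as 1/2, 1/4."""
    if regimen.free_text_flag:
        return regimen.free_text or ""
    return "-".join(_format_slot(s) for s in regimen.slots)


@dataclass(frozen=True)
class Prescription:
    """One line of a patient's medication list: a product plus its regimen.

    ``product`` is None for prescriptions that could not be resolved against
    the catalogue; the original text is kept in ``descriptor``.
    """

    product: DrugProduct | None
    regimen: Regimen
    descriptor: str = ""

    def __post_init__(self):
        if self.product is not None and not self.regimen.free_text_flag:
            if not self.regimen.fits_divisibility(self.product.divisibility):
                raise ValueError(
                    f"scheme {scheme_to_text(self.regimen)} is finer than the "
                    f"divisibility (1/{self.product.divisibility}) of "
                    f"{self.product.product_id}"
                )

    @property
    def resolved(self) -> bool:
        return self.product is not None

    @property
    def complete(self) -> bool:
        return self.resolved and not self.regimen.free_text_flag


def total_daily_dose(p: Prescription, parent: str) -> Fraction:
    """Total daily dose of one active parent: (sum of slots) x normalized
    strength. Result is in mg for mass strengths and IU for IU strengths."""
    if not p.resolved:
        raise ValueError("cannot compute a daily dose for an unresolved prescription")
    if p.regimen.free_text_flag:
        raise ValueError("cannot compute a daily dose for a free-text regimen")
    strength = p.product.strength_of(parent)  # KeyError if parent absent
    return p.regimen.total_units * strength


@dataclass(frozen=True)
class RedistributionResult:
    """A feasible redistributed scheme with its accuracy bookkeeping."""

    regimen: Regimen
    achieved_tdd: Fraction
    deviation: Fraction  # |achieved - target| / target, exact
    split_required: bool

    @property
    def deviation_float(self) -> float:
        return fraction_to_float(self.deviation)


def _slot_values(divisibility: int, max_units: int) -> list[Fraction]:
    step = Fraction(1, divisibility)
    return [k * step for k in range(max_units * divisibility + 1)]


def _distributions(total: Fraction, divisibility: int, max_units: int):
    values = _slot_values(divisibility, max_units)
    # enumerate slot tuples summing to `total`, pruning on the running sum
    for a in values:
        if a > total:
            break
        for b in values:
            if a + b > total:
                break
            for c in values:
                if a + b + c > total:
                    break
                d = total - a - b - c
                if d in values:
                    yield (a, b, c, d)


def _scheme_preference(slots: tuple[Fraction, ...]):
    """Tie-break key: fewest administrations, fewest split (fractional)
    slots, then doses as early in the day as possible."""
    n_admin = sum(1 for s in slots if s > 0)
    n_split = sum(1 for s in slots if s.denominator != 1)
    return (n_admin, n_split, tuple(-s for s in slots))


def redistribute(
    target_tdd: Fraction | float,
    candidate: DrugProduct,
    parent: str,
    cfg: EngineConfig = EngineConfig(),
) -> RedistributionResult | None:
    """Find the best administration scheme of ``candidate`` for a target
    daily dose of ``parent``.

    Minimizes the relative deviation of the achieved total daily dose from
    the target over all schemes whose slots are multiples of
    1/candidate.divisibility with at most ``cfg.max_units_per_slot`` units
    per slot; exact ties are broken by scheme simplicity
    (:func:`_scheme_preference`). Returns None when even the best achievable
    deviation exceeds ``cfg.max_dose_deviation`` — callers demote such
    prescriptions to manual handling instead of emitting a bad dose.
    """
    target = as_fraction(target_tdd)
    if target <= 0:
        raise ValueError("target daily dose must be > 0")
    strength = candidate.strength_of(parent)  # KeyError if parent absent

    step = Fraction(1, candidate.divisibility)
    max_total_units = 4 * cfg.max_units_per_slot
    # phase 1: best achievable totals (few dozen values, exact arithmetic)
    best_dev: Fraction | None = None
    best_totals: list[Fraction] = []
    n_steps = int(max_total_units / step)
    for k in range(1, n_steps + 1):
        total = k * step
        dev = abs(total * strength - target) / target
        if best_dev is None or dev < best_dev:
            best_dev, best_totals = dev, [total]
        elif dev == best_dev:
            best_totals.append(total)
    if best_dev is None or best_dev > cfg.max_dose_deviation:
        return None
    # phase 2: nicest distribution of the winning total(s) over the 4 slots
    best_slots = min(
        (
            slots
            for total in best_totals
            for slots in _distributions(total, candidate.divisibility, cfg.max_units_per_slot)
        ),
        key=_scheme_preference,
    )
    regimen = Regimen(slots=best_slots)
    return RedistributionResult(
        regimen=regimen,
        achieved_tdd=regimen.total_units * strength,
        deviation=best_dev,
        split_required=regimen.requires_splitting,
    )
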