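"""Independent brute-force oracles used to cross-check the library.

Everything here is written directly from the domain definitions (scan all
products, enumerate all schemes) without reusing the library's query or
search code, so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from rxswitch.catalogue import Catalogue, DrugProduct


def rel_dev(a: Fraction, b: Fraction) -> Fraction:
    return abs(a - b) / a


def _presentation_matches(src: DrugProduct, cand: DrugProduct) -> bool:
    return (
        cand.form_group == src.form_group
        and cand.release == src.release
        and cand.route == src.route
    )


def _units_comparable(src: DrugProduct, cand: DrugProduct) -> bool:
    return all(
        src.ingredient(p).unit_class == cand.ingredient(p).unit_class
        for p in src.parents
    )


def scan_equivalents(src: DrugProduct, cat: Catalogue, rel_tol: Fraction) -> set[str]:
    out = set()
    for cand in cat:
        if not cand.on_hdf or cand.product_id == src.product_id:
            continue
        if cand.parents != src.parents or not _presentation_matches(src, cand):
            continue
        if not _units_comparable(src, cand):
            continue
        if all(
            rel_dev(src.strength_of(p), cand.strength_of(p)) <= rel_tol
            for p in src.parents
        ):
            out.add(cand.product_id)
    return out


def scan_alternatives(src: DrugProduct, cat: Catalogue, rel_tol: Fraction) -> set[str]:
    out = set()
    for cand in cat:
        if not cand.on_hdf or cand.product_id == src.product_id:
            continue
        if cand.parents != src.parents or not _presentation_matches(src, cand):
            continue
        if not _units_comparable(src, cand):
            continue
        beyond = any(
            rel_dev(src.strength_of(p), cand.strength_of(p)) > rel_tol
            for p in src.parents
        )
        ratios = {cand.strength_of(p) / src.strength_of(p) for p in src.parents}
        if beyond and len(ratios) == 1:
            out.add(cand.product_id)
    return out


def exhaustive_redistribute(
    target: Fraction,
    strength: Fraction,
    divisibility: int,
    max_dose_deviation: Fraction,
    max_units_per_slot: int = 4,
):
    """Enumerate every admissible four-slot scheme and pick the best by
    (deviation, administrations, fractional slots, earlier-doses)."""
    step = Fraction(1, divisibility)
    values = [k * step for k in range(max_units_per_slot * divisibility + 1)]
    best = None
    best_key = None
    for slots in itertools.product(values, repeat=4):
        total = sum(slots)
        if total == 0:
            continue
        dev = abs(total * strength - target) / target
        key = (
            dev,
            sum(1 for s in slots if s > 0),
            sum(1 for s in slots if s.denominator != 1),
            tuple(-s for s in slots),
        )
        if best_key is None or key < best_key:
            best, best_key = slots, key
    if best is None or best_key[0] > max_dose_deviation:
        return None
    return best, best_key[0]
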