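"""Deterministic synthetic fixtures with constructed ground truth.

Real hospital formularies, commercial drug catalogues and patient medication
lists cannot ship with a library, so this module generates them: a catalogue
of synthetic drug products engineered so that every planned prescription has
exactly one intended resolution path through the switch algorithm (already
on the formulary / equivalent only / alternative only / therapeutic
equivalent only / no match), a knowledge base covering the therapeutic
cases with known equipotent doses, and consultations whose statistical shape
mirrors the published evaluation: drug counts per consultation drawn from a
truncated normal (default mean 7.5, SD 3.9, minimum 1) and a configurable
fraction of prescriptions rendered incomplete (default 12.2%) by blanking
the product or the dosage scheme, as happens on handwritten consultation
faxes.

The accompanying :class:`GroundTruthManifest` records the intended group and
suggestion for every generated prescription — the test oracle against which
the engine's recovery is measured.

Determinism: every artefact is reproducible byte-for-byte from
``(seed, spec)``. Catalogue planning and consultation sampling use separate
child streams of one seeded generator, so generating more consultations
never perturbs the catalogue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalogue import Catalogue, DrugProduct, IngredientStrength
from .engine import Group
from .interchange import (
    DEFAULT_EXCLUDED_PREFIXES,
    ExclusionRules,
    InterchangeClass,
    InterchangeMember,
    KnowledgeBase,
)
from .regimen import Prescription, Regimen, scheme_to_text

__all__ = [
    "GeneratorSpec",
    "PlannedCase",
    "GroundTruthEntry",
    "GroundTruthManifest",
    "generate_catalogue",
    "generate_consultations",
]

_ATC_LETTERS = "ABCDGHJLMNPRS"
_SCHEMES = ((1, 0, 0, 0), (1, 0, 1, 0), (1, 1, 1, 0), (0, 0, 1, 0))
_STRENGTHS = (5, 10, 20, 25, 40, 50, 100)
_FACTORS = (Fraction(1), Fraction(2), Fraction(1, 2))


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-condition parameters for fixture generation.

    The group-mix defaults are the final-version field mix (31.7% already on
    formulary, 40.7% equivalents, 12.2% alternatives, 7.0% therapeutic
    equivalents, 8.4% unswitchable); consultation size and incompleteness
    defaults are the published 7.5 ± 3.9 drugs per consultation and 12.2%
    incomplete prescriptions. ``hdf_fraction`` is the group-1 share of the
    mix; the four ``p_*`` weights are renormalised over the remaining mass,
    so ``hdf_fraction=1.0`` plans every prescription as group 1.
    """

    seed: int = 0
    n_products: int = 100
    hdf_fraction: float = 0.317
    p_equivalent: float = 0.407
    p_alternative: float = 0.122
    p_therapeutic: float = 0.070
    p_unswitchable: float = 0.084
    drugs_per_consultation_mean: float = 7.5
    drugs_per_consultation_sd: float = 3.9
    incomplete_rate: float = 0.122
    n_consultations: int = 202

    def __post_init__(self):
        probs = (
            self.hdf_fraction,
            self.p_equivalent,
            self.p_alternative,
            self.p_therapeutic,
            self.p_unswitchable,
            self.incomplete_rate,
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        rest = self.p_equivalent + self.p_alternative + self.p_therapeutic + self.p_unswitchable
        if rest > 1 + 1e-9:
            raise ValueError("group mix must sum to <= 1")
        if self.drugs_per_consultation_sd < 0:
            raise ValueError("consultation-size SD must be >= 0")
        if self.drugs_per_consultation_sd == 0 and self.drugs_per_consultation_mean < 1:
            raise ValueError("degenerate size distribution needs mean >= 1")
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")

    @property
    def group_weights(self) -> tuple[float, ...]:
        rest = self.p_equivalent + self.p_alternative + self.p_therapeutic + self.p_unswitchable
        if rest == 0:
            scale = 0.0
        else:
            scale = (1.0 - self.hdf_fraction) / rest
        return (
            self.hdf_fraction,
            self.p_equivalent * scale,
            self.p_alternative * scale,
            self.p_therapeutic * scale,
            self.p_unswitchable * scale,
        )


@dataclass(frozen=True)
class PlannedCase:
    """One engineered source product with its intended resolution path."""

    index: int
    group: Group
    source_id: str
    scheme: tuple[int, int, int, int]
    expected_suggestion_ids: tuple[str, ...]
    expected_tdd: Fraction | None  # per suggestion reference parent, mg/day


@dataclass(frozen=True)
class GroundTruthEntry:
    """Manifest row for one generated prescription."""

    consultation: int
    position: int
    source_id: str | None
    expected_group: Group
    expected_suggestion_ids: tuple[str, ...]
    expected_tdd: float | None
    incomplete: bool

    def to_dict(self) -> dict:
        return {
            "consultation": self.consultation,
            "position": self.position,
            "source_id": self.source_id,
            "expected_group": int(self.expected_group),
            "expected_suggestion_ids": list(self.expected_suggestion_ids),
            "expected_tdd": self.expected_tdd,
            "incomplete": self.incomplete,
        }


@dataclass
class GroundTruthManifest:
    """Constructed ground truth for a generated data set."""

    n_products: int
    n_hdf: int
    entries: list[GroundTruthEntry] = field(default_factory=list)

    @property
    def group_counts(self) -> dict[int, int]:
        counts = {g: 0 for g in range(1, 6)}
        for e in self.entries:
            counts[int(e.expected_group)] += 1
        return counts

    @property
    def n_incomplete(self) -> int:
        return sum(1 for e in self.entries if e.incomplete)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_products": self.n_products,
                "n_hdf": self.n_hdf,
                "group_counts": {str(k): v for k, v in self.group_counts.items()},
                "n_incomplete": self.n_incomplete,
                "entries": [e.to_dict() for e in self.entries],
            },
            sort_keys=True,
            indent=1,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _atc_code(rng: np.random.Generator) -> str:
    """A syntactically valid level-4 ATC code outside every excluded prefix."""
    while True:
        code = (
            _ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]
            + f"{rng.integers(100):02d}"
            + _ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]
            + _ATC_LETTERS[rng.integers(len(_ATC_LETTERS))]
        )
        if not any(code.startswith(p) for p in DEFAULT_EXCLUDED_PREFIXES):
            return code


def _plan(spec: GeneratorSpec) -> list[PlannedCase]:
    """Draw the per-case intents. Uses its own stream so the plan (and hence
    the catalogue) is independent of consultation sampling."""
    rng = _rng(spec, 0)
    weights = np.asarray(spec.group_weights, dtype=float)
    weights = weights / weights.sum()
    cases = []
    for i in range(spec.n_products):
        group = Group(int(rng.choice([1, 2, 3, 4, 5], p=weights)))
        scheme = _SCHEMES[rng.integers(len(_SCHEMES))]
        strength = int(_STRENGTHS[rng.integers(len(_STRENGTHS))])
        factor = _FACTORS[rng.integers(len(_FACTORS))]
        atc = _atc_code(rng)
        is_combo = group == Group.NO_AUTOMATIC_SWITCH and i % 7 == 0
        cases.append(
            _build_case(i, group, scheme, strength, factor, atc, is_combo)
        )
    return cases


@dataclass(frozen=True)
class _CasePlan:
    case: PlannedCase
    products: tuple[DrugProduct, ...]
    kb_class: InterchangeClass | None


def _build_case(
    i: int,
    group: Group,
    scheme: tuple[int, int, int, int],
    strength: int,
    factor: Fraction,
    atc: str,
    four_way_combo: bool,
) -> _CasePlan:
    parent = f"drug{i:04d}"
    indication = f"cond{i:04d}"
    source_id = f"P{i:04d}S"
    units = sum(scheme)
    tdd = Fraction(units * strength)

    def product(pid, brand, par, amt, on_hdf, div=2, atc_codes=(), combo=None):
        ingredients = combo or (IngredientStrength(parent=par, amount=Fraction(amt), unit="mg"),)
        return DrugProduct(
            product_id=pid,
            brand_name=brand,
            ingredients=ingredients,
            dosage_form="tablet",
            release="immediate",
            route="oral",
            atc_codes=tuple(atc_codes),
            indications=frozenset({indication}),
            on_hdf=on_hdf,
            divisibility=div,
        )

    if four_way_combo:
        # >3 active ingredients: never switched automatically
        combo = tuple(
            IngredientStrength(parent=f"{parent}c{j}", amount=Fraction(strength), unit="mg")
            for j in range(4)
        )
        src = product(source_id, f"Combi {i}", parent, strength, False, combo=combo)
        case = PlannedCase(i, group, source_id, scheme, (), None)
        return _CasePlan(case, (src,), None)

    if group == Group.HDF_DRUG:
        src = product(source_id, f"Brand {i}", parent, strength, True, atc_codes=(atc + "01",))
        case = PlannedCase(i, group, source_id, scheme, (source_id,), tdd)
        return _CasePlan(case, (src,), None)

    if group == Group.PHARMACEUTICAL_EQUIVALENT:
        src = product(source_id, f"Brand {i}", parent, strength, False, atc_codes=(atc + "01",))
        twin = product(f"P{i:04d}E", f"Brand {i} HDF", parent, strength, True, atc_codes=(atc + "01",))
        case = PlannedCase(i, group, source_id, scheme, (f"P{i:04d}E",), tdd)
        return _CasePlan(case, (src, twin), None)

    if group == Group.PHARMACEUTICAL_ALTERNATIVE:
        src = product(source_id, f"Brand {i}", parent, strength, False, atc_codes=(atc + "01",))
        # double strength, divisibility 2: any integer-unit scheme redistributes
        alt = product(
            f"P{i:04d}A", f"Brand {i} forte", parent, 2 * strength, True,
            atc_codes=(atc + "01",),
        )
        case = PlannedCase(i, group, source_id, scheme, (f"P{i:04d}A",), tdd)
        return _CasePlan(case, (src, alt), None)

    if group == Group.THERAPEUTIC_EQUIVALENT:
        tgt_parent = f"{parent}t"
        src = product(source_id, f"Brand {i}", parent, strength, False, atc_codes=(atc + "01",))
        # target strength = factor x source strength, so the source scheme
        # carries over exactly and the conversion is always feasible
        tgt = DrugProduct(
            product_id=f"P{i:04d}T",
            brand_name=f"Brand {i} class-mate",
            ingredients=(
                IngredientStrength(parent=tgt_parent, amount=factor * strength, unit="mg"),
            ),
            dosage_form="tablet",
            release="immediate",
            route="oral",
            atc_codes=(atc + "02",),
            indications=frozenset({indication}),
            on_hdf=True,
            divisibility=2,
        )
        kb_class = InterchangeClass(
            class_id=f"class{i:04d}",
            name=f"Synthetic interchange class {i}",
            atc_codes=frozenset({atc}),
            members=(
                InterchangeMember(parent=parent, equipotent_daily_dose={indication: Fraction(10)}),
                InterchangeMember(parent=tgt_parent, equipotent_daily_dose={indication: 10 * factor}),
            ),
        )
        case = PlannedCase(i, group, source_id, scheme, (f"P{i:04d}T",), tdd * factor)
        return _CasePlan(case, (src, tgt), kb_class)

    # group 5: no relative anywhere, parent in no class
    src = product(source_id, f"Orphan {i}", parent, strength, False, atc_codes=(atc + "01",))
    case = PlannedCase(i, group, source_id, scheme, (), None)
    return _CasePlan(case, (src,), None)


def generate_catalogue(spec: GeneratorSpec) -> tuple[Catalogue, KnowledgeBase]:
    """Generate the synthetic catalogue and matching knowledge base.

    Reproducible from ``(seed, spec)``; the returned catalogue contains every
    engineered product (sources plus their planned HDF relatives), and the KB
    holds one two-member class per planned therapeutic case.
    """
    plans = _plan(spec)
    products = [p for plan in plans for p in plan.products]
    classes = [plan.kb_class for plan in plans if plan.kb_class is not None]
    cat = Catalogue(products)
    kb = KnowledgeBase(classes, ExclusionRules())
    return cat, kb


def planned_cases(spec: GeneratorSpec) -> list[PlannedCase]:
    """The deterministic per-case plan underlying :func:`generate_catalogue`."""
    return [plan.case for plan in _plan(spec)]


def _consultation_size(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Truncated-normal consultation size, minimum 1 drug."""
    if sd == 0:
        return max(1, int(round(mean)))
    while True:
        k = int(round(rng.normal(mean, sd)))
        if k >= 1:
            return k


def generate_consultations(
    spec: GeneratorSpec, cat: Catalogue, kb: KnowledgeBase
) -> tuple[list[list[Prescription]], GroundTruthManifest]:
    """Sample consultations against a catalogue from the same spec lineage.

    Each consultation draws its size from the truncated normal and its
    prescriptions uniformly from the planned cases; a fraction
    ``incomplete_rate`` of prescriptions is rendered unresolvable by blanking
    either the product reference or the dosage scheme (both marked in the
    manifest as expected group 5, incomplete).
    """
    cases = planned_cases(spec)
    rng = _rng(spec, 1)
    manifest = GroundTruthManifest(n_products=len(cat), n_hdf=cat.n_hdf)
    consultations: list[list[Prescription]] = []
    for c_idx in range(spec.n_consultations):
        size = _consultation_size(
            rng, spec.drugs_per_consultation_mean, spec.drugs_per_consultation_sd
        )
        consultation: list[Prescription] = []
        for pos in range(size):
            case = cases[int(rng.integers(len(cases)))]
            product = cat[case.source_id]
            regimen = Regimen(slots=tuple(Fraction(s) for s in case.scheme))
            incomplete = bool(rng.random() < spec.incomplete_rate)
            if incomplete:
                if rng.random() < 0.5:
                    # brand could not be identified from the handwritten fax
                    p = Prescription(
                        product=None,
                        regimen=regimen,
                        descriptor=f"illegible entry {c_idx}/{pos}",
                    )
                    src_id = None
                else:
                    # dosage scheme missing / unreadable
                    p = Prescription(product=product, regimen=Regimen(free_text=""))
                    src_id = case.source_id
                manifest.entries.append(
                    GroundTruthEntry(
                        consultation=c_idx,
                        position=pos,
                        source_id=src_id,
                        expected_group=Group.NO_AUTOMATIC_SWITCH,
                        expected_suggestion_ids=(),
                        expected_tdd=None,
                        incomplete=True,
                    )
                )
            else:
                p = Prescription(product=product, regimen=regimen)
                manifest.entries.append(
                    GroundTruthEntry(
                        consultation=c_idx,
                        position=pos,
                        source_id=case.source_id,
                        expected_group=case.group,
                        expected_suggestion_ids=case.expected_suggestion_ids,
                        expected_tdd=(
                            None if case.expected_tdd is None else float(case.expected_tdd)
                        ),
                        incomplete=False,
                    )
                )
            consultation.append(p)
        consultations.append(consultation)
    return consultations, manifest


def write_consultations(
    consultations: Sequence[Sequence[Prescription]], path: str | Path
) -> None:
    """Serialize consultations to the delimited medication-list dialect with
    a leading consultation index."""
    lines = ["consultation;brand_or_product_id;strength_text;scheme"]
    for c_idx, consultation in enumerate(consultations):
        for p in consultation:
            ident = p.product.product_id if p.resolved else p.descriptor
            strength = ""
            if p.resolved and p.product.is_single_ingredient:
                ing = p.product.ingredients[0]
                strength = f"{float(ing.amount):g} {ing.unit}"
            lines.append(f"{c_idx};{ident};{strength};{scheme_to_text(p.regimen)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
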