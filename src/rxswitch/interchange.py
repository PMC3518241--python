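"""Therapeutic-interchange knowledge base.

A therapeutic interchange class groups drug parents (scoped by ATC level-4
chemical subgroups, e.g. C10AA for the HMG-CoA reductase inhibitors) that can
substitute for one another at *equipotent daily doses*. The conversion factor
between two members is the ratio of their equipotent daily doses for the
matched indication:

    factor(src -> tgt, indication) = EDD(tgt, indication) / EDD(src, indication)

Storing per-member equipotent doses rather than pairwise factors makes
reciprocity (factor(a->b) x factor(b->a) = 1) and transitivity within a class
hold exactly by construction.

Indication handling: members carry an explicit indication -> equipotent-dose
table, and candidates are only offered when their labelled indications
intersect the source product's. This is what prevents, e.g., substituting
felodipine (hypertension) with nimodipine (prevention of cerebral vasospasm)
even though both are C08CA calcium-channel blockers. Where a shared pair of
drugs has different factors for different shared indications, the factor for
the lexicographically first indication is used and an indication-difference
warning is attached.

Exclusion rules capture drug groups withdrawn from automatic substitution
after pilot experience — insulins (A10A), alpha-adrenoceptor blockers
(C02CA), hyperkalemia/hyperphosphatemia drugs (V03AE) and other antianemics
(B03XA) — plus the restriction of therapeutic interchange to oral solid
dosage forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from ._util import as_fraction, is_valid_atc, is_valid_atc_prefix
from .catalogue import Catalogue, DrugProduct, normalize_ingredient_name
from .config import Annotation, AnnotationKind

__all__ = [
    "InterchangeMember",
    "InterchangeClass",
    "ExclusionRules",
    "KnowledgeBase",
    "KBError",
    "load_kb",
    "write_kb",
    "default_kb",
    "conversion_factor",
    "therapeutic_candidates",
    "TherapeuticCandidate",
    "CandidateSet",
    "DEFAULT_EXCLUDED_PREFIXES",
]

#: ATC prefixes excluded from automatic therapeutic substitution.
DEFAULT_EXCLUDED_PREFIXES = frozenset({"A10A", "C02CA", "V03AE", "B03XA"})


class KBError(ValueError):
    """Raised for malformed or rule-violating knowledge bases."""


@dataclass(frozen=True)
class InterchangeMember:
    """One drug parent in an interchange class with its equipotent daily
    doses per indication (mg/day, or IU/day for biologicals)."""

    parent: str
    equipotent_daily_dose: Mapping[str, Fraction]
    notes: str = ""

    def __post_init__(self):
        parent, _ = normalize_ingredient_name(self.parent)
        object.__setattr__(self, "parent", parent)
        edd = {str(k): as_fraction(v) for k, v in self.equipotent_daily_dose.items()}
        object.__setattr__(self, "equipotent_daily_dose", edd)
        if not edd:
            raise KBError(f"member {self.parent!r} needs >= 1 indication entry")
        for ind, dose in edd.items():
            if dose <= 0:
                raise KBError(
                    f"member {self.parent!r}: equipotent dose for {ind!r} must be > 0"
                )

    @property
    def indications(self) -> frozenset[str]:
        return frozenset(self.equipotent_daily_dose)


@dataclass(frozen=True)
class InterchangeClass:
    """ATC-scoped set of mutually exchangeable drug parents."""

    class_id: str
    name: str
    atc_codes: frozenset[str]
    members: tuple[InterchangeMember, ...]
    oral_solid_only: bool = True

    def __post_init__(self):
        object.__setattr__(self, "atc_codes", frozenset(self.atc_codes))
        object.__setattr__(self, "members", tuple(self.members))
        if not self.class_id:
            raise KBError("class_id must be non-empty")
        if not self.atc_codes:
            raise KBError(f"class {self.class_id!r}: atc_codes must be non-empty")
        for code in self.atc_codes:
            if not is_valid_atc(code):
                raise KBError(f"class {self.class_id!r}: malformed ATC code {code!r}")
        parents = [m.parent for m in self.members]
        if len(parents) != len(set(parents)):
            raise KBError(f"class {self.class_id!r}: duplicate member parents")

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(m.parent for m in self.members)

    def member(self, parent: str) -> InterchangeMember:
        for m in self.members:
            if m.parent == parent:
                return m
        raise KeyError(f"{parent!r} is not a member of class {self.class_id!r}")

    def matches_atc(self, codes: Iterable[str]) -> bool:
        """A product belongs to this class's ATC scope when any of its codes
        falls under any class code (prefix semantics: C10AA01 is in C10AA)."""
        return any(
            code.startswith(class_code)
            for code in codes
            for class_code in self.atc_codes
        )


@dataclass(frozen=True)
class ExclusionRules:
    """Drug groups and routes barred from automatic therapeutic interchange."""

    atc_prefixes: frozenset[str] = DEFAULT_EXCLUDED_PREFIXES
    oral_only: bool = True

    def __post_init__(self):
        object.__setattr__(self, "atc_prefixes", frozenset(self.atc_prefixes))
        for prefix in self.atc_prefixes:
            if not is_valid_atc_prefix(prefix):
                raise KBError(f"malformed ATC prefix {prefix!r}")

    def excluded_reason(self, product: DrugProduct) -> str | None:
        for code in product.atc_codes:
            for prefix in sorted(self.atc_prefixes):
                if code.startswith(prefix):
                    return f"ATC {code} falls under excluded prefix {prefix}"
        return None


class KnowledgeBase:
    """Validated collection of interchange classes plus exclusion rules."""

    def __init__(
        self,
        classes: Iterable[InterchangeClass],
        exclusions: ExclusionRules | None = None,
    ):
        self.exclusions = exclusions or ExclusionRules()
        by_id: dict[str, InterchangeClass] = {}
        for cls in classes:
            if cls.class_id in by_id:
                raise KBError(f"duplicate class_id {cls.class_id!r}")
            for code in cls.atc_codes:
                for prefix in sorted(self.exclusions.atc_prefixes):
                    if code.startswith(prefix):
                        raise KBError(
                            f"class {cls.class_id!r}: ATC code {code} falls under "
                            f"excluded prefix {prefix}"
                        )
            by_id[cls.class_id] = cls
        self._classes = dict(sorted(by_id.items()))

    def __len__(self) -> int:
        return len(self._classes)

    def __iter__(self) -> Iterator[InterchangeClass]:
        return iter(self._classes.values())

    def __getitem__(self, class_id: str) -> InterchangeClass:
        return self._classes[class_id]

    def classes_for_parent(self, parent: str) -> list[InterchangeClass]:
        parent, _ = normalize_ingredient_name(parent)
        return [c for c in self if parent in c.parents]

    def common_classes(self, src: str, tgt: str) -> list[InterchangeClass]:
        src, _ = normalize_ingredient_name(src)
        tgt, _ = normalize_ingredient_name(tgt)
        return [c for c in self if src in c.parents and tgt in c.parents]


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------


def _kb_from_mapping(doc: Mapping) -> KnowledgeBase:
    if not isinstance(doc, Mapping) or "classes" not in doc:
        raise KBError("KB document must be a mapping with a top-level 'classes' list")
    excl_doc = doc.get("exclusions") or {}
    exclusions = ExclusionRules(
        atc_prefixes=frozenset(
            excl_doc.get("atc_prefixes", sorted(DEFAULT_EXCLUDED_PREFIXES))
        ),
        oral_only=bool(excl_doc.get("oral_only", True)),
    )
    classes = []
    for cdoc in doc["classes"] or []:
        try:
            members = tuple(
                InterchangeMember(
                    parent=m["parent"],
                    equipotent_daily_dose=m["equipotent_daily_dose"],
                    notes=m.get("notes", ""),
                )
                for m in cdoc.get("members", [])
            )
            classes.append(
                InterchangeClass(
                    class_id=cdoc["class_id"],
                    name=cdoc.get("name", cdoc["class_id"]),
                    atc_codes=frozenset(cdoc["atc_codes"]),
                    members=members,
                    oral_solid_only=bool(cdoc.get("oral_solid_only", True)),
                )
            )
        except KeyError as e:
            raise KBError(f"class entry missing field {e.args[0]!r}") from e
    return KnowledgeBase(classes, exclusions)


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"knowledge base file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    return _kb_from_mapping(doc)


def write_kb(kb: KnowledgeBase, path: str | Path) -> None:
    doc = {
        "exclusions": {
            "atc_prefixes": sorted(kb.exclusions.atc_prefixes),
            "oral_only": kb.exclusions.oral_only,
        },
        "classes": [
            {
                "class_id": c.class_id,
                "name": c.name,
                "atc_codes": sorted(c.atc_codes),
                "oral_solid_only": c.oral_solid_only,
                "members": [
                    {
                        "parent": m.parent,
                        "equipotent_daily_dose": {
                            k: (v.numerator if v.denominator == 1 else float(v))
                            for k, v in sorted(m.equipotent_daily_dose.items())
                        },
                        **({"notes": m.notes} if m.notes else {}),
                    }
                    for m in c.members
                ],
            }
            for c in kb
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def default_kb() -> KnowledgeBase:
    """The shipped default knowledge base: 21 interchange classes.

    Class list and ATC scopes follow the published hospital implementation;
    the numeric equipotent daily doses are curator-editable placeholders
    derived from approved maintenance doses (SPC-style), except the
    simvastatin/pravastatin 20:40 mg/day pair, which is fixed.
    """
    text = resources.files("rxswitch.data").joinpath("default_kb.yaml").read_text(
        encoding="utf-8"
    )
    return _kb_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Conversion factors and candidate search
# ---------------------------------------------------------------------------


def _factor_for(
    src_m: InterchangeMember, tgt_m: InterchangeMember, indication: str
) -> Fraction:
    return tgt_m.equipotent_daily_dose[indication] / src_m.equipotent_daily_dose[indication]


def conversion_factor(
    src: str,
    tgt: str,
    kb: KnowledgeBase,
    indication: str | None = None,
) -> tuple[Fraction, list[Annotation]]:
    """Dose conversion factor from parent ``src`` to parent ``tgt``.

    With an explicit ``indication`` the factor for that indication is
    returned (KBError if either member lacks it). Without one, the factor for
    the lexicographically first shared indication is returned; if factors
    differ across shared indications an indication-difference warning is
    attached.
    """
    src_p, _ = normalize_ingredient_name(src)
    tgt_p, _ = normalize_ingredient_name(tgt)
    if src_p == tgt_p:
        raise KBError("source and target parent are the same drug")
    common = kb.common_classes(src_p, tgt_p)
    if not common:
        raise KBError(f"{src_p!r} and {tgt_p!r} are not members of a common class")
    cls = common[0]
    src_m, tgt_m = cls.member(src_p), cls.member(tgt_p)
    shared = sorted(src_m.indications & tgt_m.indications)
    if not shared:
        raise KBError(
            f"{src_p!r} and {tgt_p!r} share no indication in class {cls.class_id!r}"
        )
    warnings: list[Annotation] = []
    if indication is not None:
        if indication not in shared:
            raise KBError(
                f"no shared equipotent dose for indication {indication!r} "
                f"({src_p} -> {tgt_p})"
            )
        chosen = indication
    else:
        chosen = shared[0]
        factors = {_factor_for(src_m, tgt_m, i) for i in shared}
        if len(factors) > 1:
            warnings.append(
                Annotation(
                    AnnotationKind.INDICATION_DIFFERENCE,
                    f"conversion factor {src_p} -> {tgt_p} differs across "
                    f"indications {', '.join(shared)}; using {chosen!r}",
                )
            )
    return _factor_for(src_m, tgt_m, chosen), warnings


@dataclass(frozen=True)
class TherapeuticCandidate:
    """One HDF product offered as a therapeutic equivalent."""

    product: DrugProduct
    factor: Fraction
    indication: str
    warnings: tuple[Annotation, ...] = ()


@dataclass(frozen=True)
class CandidateSet:
    """Therapeutic candidates, or the reason the search was not attempted."""

    candidates: tuple[TherapeuticCandidate, ...] = ()
    exclusion_reason: str | None = None

    def __iter__(self) -> Iterator[TherapeuticCandidate]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __bool__(self) -> bool:
        return bool(self.candidates)


def therapeutic_candidates(
    source: DrugProduct, cat: Catalogue, kb: KnowledgeBase
) -> CandidateSet:
    """All HDF products eligible as therapeutic equivalents for ``source``.

    Eligibility gates, in order: the source must be a single-ingredient
    product; must not fall under an excluded ATC prefix; must be an oral
    solid when the oral-only restriction is active; its parent must belong to
    at least one class whose ATC scope matches the product. Candidates are
    single-ingredient HDF oral solids of a co-classed parent whose labelled
    indications intersect the source's; each comes with its conversion factor
    and any indication warnings. Order is deterministic: candidates whose
    strength best matches factor x source strength first, then product_id.
    """
    if not source.is_single_ingredient:
        return CandidateSet(exclusion_reason="combination products are not substituted therapeutically")
    reason = kb.exclusions.excluded_reason(source)
    if reason is not None:
        return CandidateSet(exclusion_reason=reason)
    if kb.exclusions.oral_only and not source.is_oral_solid:
        return CandidateSet(
            exclusion_reason=(
                f"only oral solid dosage forms are substituted therapeutically "
                f"(source is {source.route} {source.dosage_form})"
            )
        )
    src_parent = source.ingredients[0].parent
    classes = [
        c
        for c in kb.classes_for_parent(src_parent)
        if not source.atc_codes or c.matches_atc(source.atc_codes)
    ]
    if not classes:
        return CandidateSet(exclusion_reason=f"parent {src_parent!r} is in no interchange class")

    src_strength = source.strength_of(src_parent)
    found: dict[str, TherapeuticCandidate] = {}
    for cls in classes:
        src_m = cls.member(src_parent)
        for member in cls.members:
            if member.parent == src_parent:
                continue
            for cand in cat.with_parent(member.parent):
                if not cand.on_hdf or not cand.is_single_ingredient:
                    continue
                if (cls.oral_solid_only or kb.exclusions.oral_only) and not cand.is_oral_solid:
                    continue
                if kb.exclusions.excluded_reason(cand) is not None:
                    continue
                if cand.atc_codes and not cls.matches_atc(cand.atc_codes):
                    continue
                usable = sorted(
                    source.indications
                    & cand.indications
                    & src_m.indications
                    & member.indications
                )
                if not usable:
                    continue
                chosen = usable[0]
                factor = _factor_for(src_m, cls.member(member.parent), chosen)
                warnings: list[Annotation] = []
                factors = {
                    _factor_for(src_m, cls.member(member.parent), i) for i in usable
                }
                if len(factors) > 1:
                    warnings.append(
                        Annotation(
                            AnnotationKind.INDICATION_DIFFERENCE,
                            f"conversion factor {src_parent} -> {member.parent} "
                            f"differs across indications {', '.join(usable)}; "
                            f"using {chosen!r}",
                        )
                    )
                if cand.product_id not in found:
                    found[cand.product_id] = TherapeuticCandidate(
                        product=cand,
                        factor=factor,
                        indication=chosen,
                        warnings=tuple(warnings),
                    )

    def rank(tc: TherapeuticCandidate):
        target_strength = src_strength * tc.factor
        cand_strength = tc.product.strength_of(tc.product.ingredients[0].parent)
        dev = abs(cand_strength - target_strength) / target_strength
        return (dev, tc.product.product_id)

    ordered = tuple(sorted(found.values(), key=rank))
    return CandidateSet(candidates=ordered)
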