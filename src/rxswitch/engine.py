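"""The five-step formulary switch algorithm.

For each prescription the engine tries, strictly in order:

1. **HDF drug** — the prescribed product itself is on the hospital drug
   formulary; no switch needed.
2. **Pharmaceutical equivalent** — an HDF product with the same parent(s),
   strength and application form; the regimen carries over unchanged.
3. **Pharmaceutical alternative** — same parent(s), different strength,
   comparable form; the regimen is recomputed to preserve the total daily
   dose.
4. **Therapeutic equivalent** — a different parent of the same interchange
   class (single-ingredient oral solids only); the target daily dose is
   source dose x conversion factor, then the regimen is recomputed.
5. **No automatic switch** — everything else goes to a physician or
   pharmacist for manual handling.

Combination products that fail steps 1–3 as a whole are split into their
single agents, each re-run through steps 2–3; the split succeeds only if
*every* component resolves (all-or-nothing), and the recorded group is the
worst component's step. Combinations are never substituted therapeutically,
and products with more than ``max_combination_components`` active
ingredients are left to manual handling.

Every input yields exactly one :class:`SwitchResult`; unresolved or
free-text prescriptions become group-5 results with an incompleteness
warning rather than errors, mirroring how incomplete consultations are
accounted for in evaluation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from fractions import Fraction

from ._util import fraction_to_float
from .catalogue import (
    Catalogue,
    DrugProduct,
    alternatives_query,
    equivalents_query,
)
from .config import Annotation, AnnotationKind, EngineConfig
from .interchange import KnowledgeBase, therapeutic_candidates
from .regimen import (
    Prescription,
    RedistributionResult,
    redistribute,
    scheme_to_text,
    total_daily_dose,
)

__all__ = [
    "Group",
    "SwitchResult",
    "TraceStep",
    "ConsultationResult",
    "switch_prescription",
    "split_combination",
    "switch_consultation",
]


class Group(enum.IntEnum):
    """Outcome categories of the switch algorithm."""

    HDF_DRUG = 1
    PHARMACEUTICAL_EQUIVALENT = 2
    PHARMACEUTICAL_ALTERNATIVE = 3
    THERAPEUTIC_EQUIVALENT = 4
    NO_AUTOMATIC_SWITCH = 5


@dataclass(frozen=True)
class TraceStep:
    """One attempted step of the algorithm, for auditability."""

    step: int
    outcome: str  # "matched" | "no-match" | "skipped" | "infeasible-dose"
    detail: str = ""

    def to_dict(self) -> dict:
        return {"step": self.step, "outcome": self.outcome, "detail": self.detail}


@dataclass(frozen=True)
class SwitchResult:
    """The engine's verdict for one prescription."""

    group: Group
    source: Prescription
    suggestions: tuple[Prescription, ...] = ()
    annotations: tuple[Annotation, ...] = ()
    dose_deviations: tuple[Fraction, ...] = ()
    trace: tuple[TraceStep, ...] = ()

    def __post_init__(self):
        if (self.group == Group.NO_AUTOMATIC_SWITCH) != (not self.suggestions):
            raise ValueError("suggestions must be empty exactly for group 5")
        for s in self.suggestions:
            if s.product is None or not s.product.on_hdf:
                raise ValueError("every suggested product must be on the HDF")

    def has_annotation(self, kind: AnnotationKind) -> bool:
        return any(a.kind == kind for a in self.annotations)

    def to_dict(self) -> dict:
        src = {
            "product_id": self.source.product.product_id if self.source.resolved else None,
            "descriptor": self.source.descriptor,
            "scheme": scheme_to_text(self.source.regimen),
        }
        return {
            "group": int(self.group),
            "source": src,
            "suggestions": [
                {
                    "product_id": s.product.product_id,
                    "brand_name": s.product.brand_name,
                    "scheme": scheme_to_text(s.regimen),
                }
                for s in self.suggestions
            ],
            "annotations": [a.to_dict() for a in self.annotations],
            "dose_deviations": [fraction_to_float(d) for d in self.dose_deviations],
            "trace": [t.to_dict() for t in self.trace],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _salt_annotations(source: DrugProduct, cand: DrugProduct) -> list[Annotation]:
    out = []
    for parent in sorted(source.parents):
        s_salt = source.ingredient(parent).salt
        c_salt = cand.ingredient(parent).salt
        if s_salt != c_salt:
            out.append(
                Annotation(
                    AnnotationKind.SALT_DIFFERENCE,
                    f"{parent}: {s_salt or 'base'} vs {c_salt or 'base'}",
                )
            )
    return out


def _split_annotation(res: RedistributionResult, cand: DrugProduct) -> list[Annotation]:
    out = []
    if res.split_required:
        out.append(
            Annotation(
                AnnotationKind.TABLET_SPLITTING,
                f"{cand.brand_name}: scheme {scheme_to_text(res.regimen)} requires "
                f"splitting dose units (divisibility 1/{cand.divisibility})",
            )
        )
    if res.deviation > 0:
        out.append(
            Annotation(
                AnnotationKind.DOSE_DEVIATION,
                f"achieved daily dose deviates by {fraction_to_float(res.deviation):.1%}",
            )
        )
    return out


def _try_equivalents(
    p: Prescription, cat: Catalogue, cfg: EngineConfig
) -> tuple[Prescription, list[Annotation], Fraction] | None:
    """Step 2: first equivalent whose divisibility can express the regimen."""
    source = p.product
    for cand in equivalents_query(source, cat, cfg.rel_tol):
        if not p.regimen.fits_divisibility(cand.divisibility):
            continue
        annotations = _salt_annotations(source, cand)
        dev = Fraction(0)
        for parent in sorted(source.parents):
            s, c = source.strength_of(parent), cand.strength_of(parent)
            dev = max(dev, abs(s - c) / s)
        if dev > 0:
            annotations.append(
                Annotation(
                    AnnotationKind.DOSE_DEVIATION,
                    f"strength differs by {fraction_to_float(dev):.2%} "
                    f"(within tolerance)",
                )
            )
        return Prescription(product=cand, regimen=p.regimen), annotations, dev
    return None


def _try_alternatives(
    p: Prescription, cat: Catalogue, cfg: EngineConfig
) -> tuple[Prescription, list[Annotation], Fraction] | None:
    """Step 3: first alternative onto which the daily dose redistributes."""
    source = p.product
    ref_parent = sorted(source.parents)[0]
    target = total_daily_dose(p, ref_parent)
    for cand in alternatives_query(source, cat, cfg.rel_tol):
        res = redistribute(target, cand, ref_parent, cfg)
        if res is None:
            continue
        annotations = _salt_annotations(source, cand)
        annotations += _split_annotation(res, cand)
        return Prescription(product=cand, regimen=res.regimen), annotations, res.deviation
    return None


def _incomplete_result(p: Prescription, detail: str) -> SwitchResult:
    return SwitchResult(
        group=Group.NO_AUTOMATIC_SWITCH,
        source=p,
        annotations=(Annotation(AnnotationKind.INCOMPLETE, detail),),
        trace=(TraceStep(0, "skipped", detail),),
    )


def switch_prescription(
    p: Prescription,
    cat: Catalogue,
    kb: KnowledgeBase,
    cfg: EngineConfig = EngineConfig(),
) -> SwitchResult:
    """Run the full switch algorithm on one prescription.

    Total: every input yields a :class:`SwitchResult`; the result's group is
    the first step that produced a usable suggestion.
    """
    if not p.resolved:
        return _incomplete_result(
            p, f"unresolved prescription {p.descriptor!r}: no catalogue product"
        )
    if p.regimen.free_text_flag:
        return _incomplete_result(
            p,
            f"free-text dosage scheme {p.regimen.free_text!r} cannot be "
            f"processed automatically",
        )

    trace: list[TraceStep] = []
    source = p.product

    # step 1: already on the formulary
    if source.on_hdf:
        trace.append(TraceStep(1, "matched", source.product_id))
        return SwitchResult(
            group=Group.HDF_DRUG,
            source=p,
            suggestions=(p,),
            dose_deviations=(Fraction(0),),
            trace=tuple(trace),
        )
    trace.append(TraceStep(1, "no-match", "product not on HDF"))

    # step 2: pharmaceutical equivalent, regimen carried over
    eq = _try_equivalents(p, cat, cfg)
    if eq is not None:
        sugg, annotations, dev = eq
        trace.append(TraceStep(2, "matched", sugg.product.product_id))
        return SwitchResult(
            group=Group.PHARMACEUTICAL_EQUIVALENT,
            source=p,
            suggestions=(sugg,),
            annotations=tuple(annotations),
            dose_deviations=(dev,),
            trace=tuple(trace),
        )
    trace.append(TraceStep(2, "no-match", "no pharmaceutical equivalent on HDF"))

    # step 3: pharmaceutical alternative, daily dose preserved
    alt = _try_alternatives(p, cat, cfg)
    if alt is not None:
        sugg, annotations, dev = alt
        trace.append(TraceStep(3, "matched", sugg.product.product_id))
        return SwitchResult(
            group=Group.PHARMACEUTICAL_ALTERNATIVE,
            source=p,
            suggestions=(sugg,),
            annotations=tuple(annotations),
            dose_deviations=(dev,),
            trace=tuple(trace),
        )
    trace.append(TraceStep(3, "no-match", "no feasible pharmaceutical alternative"))

    # combination products: split into single agents (steps 2-3 per component)
    if not source.is_single_ingredient:
        if cfg.allow_split_combinations:
            return split_combination(p, cat, kb, cfg, _pre_trace=tuple(trace))
        trace.append(TraceStep(4, "skipped", "combination product"))
        trace.append(TraceStep(5, "matched", "manual handling"))
        return SwitchResult(
            group=Group.NO_AUTOMATIC_SWITCH, source=p, trace=tuple(trace)
        )

    # step 4: therapeutic equivalent within the interchange class
    cands = therapeutic_candidates(source, cat, kb)
    if cands.exclusion_reason is not None:
        kind = (
            AnnotationKind.EXCLUDED_CLASS
            if "excluded prefix" in cands.exclusion_reason
            else AnnotationKind.NOT_ORAL_SOLID
            if "oral solid" in cands.exclusion_reason
            else None
        )
        trace.append(TraceStep(4, "skipped", cands.exclusion_reason))
        annotations = (Annotation(kind, cands.exclusion_reason),) if kind else ()
        trace.append(TraceStep(5, "matched", "manual handling"))
        return SwitchResult(
            group=Group.NO_AUTOMATIC_SWITCH,
            source=p,
            annotations=annotations,
            trace=tuple(trace),
        )
    parent = source.ingredients[0].parent
    source_tdd = total_daily_dose(p, parent)
    for tc in cands:
        target = source_tdd * tc.factor
        tgt_parent = tc.product.ingredients[0].parent
        res = redistribute(target, tc.product, tgt_parent, cfg)
        if res is None:
            trace.append(
                TraceStep(
                    4,
                    "infeasible-dose",
                    f"{tc.product.product_id}: cannot achieve "
                    f"{fraction_to_float(target):g} within tolerance",
                )
            )
            continue
        trace.append(TraceStep(4, "matched", tc.product.product_id))
        annotations = list(tc.warnings) + _split_annotation(res, tc.product)
        return SwitchResult(
            group=Group.THERAPEUTIC_EQUIVALENT,
            source=p,
            suggestions=(Prescription(product=tc.product, regimen=res.regimen),),
            annotations=tuple(annotations),
            dose_deviations=(res.deviation,),
            trace=tuple(trace),
        )
    trace.append(TraceStep(4, "no-match", "no feasible therapeutic equivalent"))

    trace.append(TraceStep(5, "matched", "manual handling"))
    return SwitchResult(group=Group.NO_AUTOMATIC_SWITCH, source=p, trace=tuple(trace))


def split_combination(
    p: Prescription,
    cat: Catalogue,
    kb: KnowledgeBase,
    cfg: EngineConfig = EngineConfig(),
    _pre_trace: tuple[TraceStep, ...] = (),
) -> SwitchResult:
    """Switch a combination product by splitting it into single agents.

    Each component is projected to a virtual single-ingredient prescription
    (component strength, original scheme) and run through steps 2–3. The
    split is all-or-nothing: if any component fails, the whole product is
    group 5 and partial results are discarded. Therapeutic substitution
    (step 4) is never applied to components.
    """
    source = p.product
    if source is None or len(source.ingredients) < 2:
        raise ValueError("split_combination requires a resolved combination product")
    trace = list(_pre_trace)
    if len(source.ingredients) > cfg.max_combination_components:
        trace.append(
            TraceStep(
                5,
                "matched",
                f"combination with {len(source.ingredients)} active ingredients "
                f"(> {cfg.max_combination_components}) requires manual handling",
            )
        )
        return SwitchResult(
            group=Group.NO_AUTOMATIC_SWITCH, source=p, trace=tuple(trace)
        )

    suggestions: list[Prescription] = []
    annotations: list[Annotation] = [
        Annotation(
            AnnotationKind.COMBINATION_SPLIT,
            f"{source.brand_name}: combination switched as "
            f"{len(source.ingredients)} single agents",
        )
    ]
    deviations: list[Fraction] = []
    worst_step = 0
    for ing in source.ingredients:
        virtual = replace(
            source,
            product_id=f"{source.product_id}::{ing.parent}",
            ingredients=(ing,),
            on_hdf=False,
        )
        vp = Prescription(product=virtual, regimen=p.regimen)
        eq = _try_equivalents(vp, cat, cfg)
        if eq is not None:
            sugg, notes, dev = eq
            step = 2
        else:
            alt = _try_alternatives(vp, cat, cfg)
            if alt is None:
                trace.append(
                    TraceStep(5, "matched", f"component {ing.parent} has no HDF match")
                )
                return SwitchResult(
                    group=Group.NO_AUTOMATIC_SWITCH, source=p, trace=tuple(trace)
                )
            sugg, notes, dev = alt
            step = 3
        worst_step = max(worst_step, step)
        trace.append(TraceStep(step, "matched", f"{ing.parent} -> {sugg.product.product_id}"))
        suggestions.append(sugg)
        annotations.extend(notes)
        deviations.append(dev)

    return SwitchResult(
        group=Group(worst_step),
        source=p,
        suggestions=tuple(suggestions),
        annotations=tuple(annotations),
        dose_deviations=tuple(deviations),
        trace=tuple(trace),
    )


@dataclass(frozen=True)
class ConsultationResult:
    """Element-wise switch results for one consultation, with group counts."""

    results: tuple[SwitchResult, ...]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    @property
    def group_counts(self) -> dict[int, int]:
        counts = {g: 0 for g in range(1, 6)}
        for r in self.results:
            counts[int(r.group)] += 1
        return counts


def switch_consultation(
    prescriptions: list[Prescription],
    cat: Catalogue,
    kb: KnowledgeBase,
    cfg: EngineConfig = EngineConfig(),
) -> ConsultationResult:
    """Switch a whole consultation (one patient's medication list), order
    preserved."""
    return ConsultationResult(
        results=tuple(switch_prescription(p, cat, kb, cfg) for p in prescriptions)
    )
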