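"""The five-step switch algorithm: step order, groups, warnings, splitting."""

from __future__ import annotations

from fractions import Fraction

import pytest

from rxswitch import (
    AnnotationKind,
    Catalogue,
    EngineConfig,
    Group,
    IngredientStrength,
    KnowledgeBase,
    Prescription,
    Regimen,
    default_kb,
    parse_scheme,
    scheme_to_text,
    split_combination,
    switch_consultation,
    switch_prescription,
    total_daily_dose,
)

from conftest import make_product

F = Fraction
EMPTY_KB = KnowledgeBase([])


def _switch(p, cat, kb=EMPTY_KB, **cfg):
    return switch_prescription(p, cat, kb, EngineConfig(**cfg))


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------


def test_step1_hdf_drug_kept(kb):
    prod = make_product("A", on_hdf=True)
    p = Prescription(product=prod, regimen=parse_scheme("1-0-1"))
    res = _switch(p, Catalogue([prod]), kb)
    assert res.group == Group.HDF_DRUG
    assert res.suggestions == (p,)
    assert res.trace[0].step == 1 and res.trace[0].outcome == "matched"


def test_step2_equivalent_carries_regimen_over():
    src = make_product("A", salt="tartrate")
    twin = make_product("B", on_hdf=True, salt="succinate")
    cat = Catalogue([src, twin])
    p = Prescription(product=src, regimen=parse_scheme("1-0-1"))
    res = _switch(p, cat)
    assert res.group == Group.PHARMACEUTICAL_EQUIVALENT
    assert res.suggestions[0].product.product_id == "B"
    assert res.suggestions[0].regimen == p.regimen
    assert res.has_annotation(AnnotationKind.SALT_DIFFERENCE)
    assert res.dose_deviations == (F(0),)


def test_step3_alternative_preserves_daily_dose():
    src = make_product("S20", "simvastatin", 20)
    alt = make_product("S40", "simvastatin", 40, on_hdf=True, divisibility=2)
    cat = Catalogue([src, alt])
    p = Prescription(product=src, regimen=parse_scheme("1-0-1"))  # 40 mg/day
    res = _switch(p, cat)
    assert res.group == Group.PHARMACEUTICAL_ALTERNATIVE
    sugg = res.suggestions[0]
    assert sugg.product.product_id == "S40"
    assert total_daily_dose(sugg, "simvastatin") == 40
    assert res.dose_deviations == (F(0),)


def test_step4_statin_switch_with_dose_adjustment(kb, statin_catalogue):
    """Simvastatin 20 mg once daily, only pravastatin 40 mg on the HDF:
    therapeutic switch with conversion factor 2 gives 40 mg once daily."""
    p = Prescription(product=statin_catalogue["SIM20"], regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, statin_catalogue, kb)
    assert res.group == Group.THERAPEUTIC_EQUIVALENT
    sugg = res.suggestions[0]
    assert sugg.product.product_id == "PRA40"
    assert scheme_to_text(sugg.regimen) == "1-0-0-0"
    assert total_daily_dose(sugg, "pravastatin") == 40


def test_step5_no_relative_anywhere(kb):
    src = make_product("ORPHAN", "orphanol", 5, atc_codes=("N07XX01",))
    res = _switch(Prescription(product=src, regimen=parse_scheme("1-0-0")), Catalogue([src]), kb)
    assert res.group == Group.NO_AUTOMATIC_SWITCH
    assert res.suggestions == ()


def test_step_monotonicity_prefers_earliest_step():
    """When an equivalent and an alternative both exist, step 2 wins."""
    src = make_product("S20", "simvastatin", 20)
    twin = make_product("T20", "simvastatin", 20, on_hdf=True)
    alt = make_product("S40", "simvastatin", 40, on_hdf=True)
    res = _switch(
        Prescription(product=src, regimen=parse_scheme("1-0-0")),
        Catalogue([src, twin, alt]),
    )
    assert res.group == Group.PHARMACEUTICAL_EQUIVALENT
    assert res.suggestions[0].product.product_id == "T20"


def test_infeasible_dose_demotes_to_manual():
    """An alternative exists, but no admissible scheme hits the target dose
    within tolerance: the prescription goes to manual handling."""
    src = make_product("S50", "simvastatin", 50, divisibility=1)
    alt = make_product("S40", "simvastatin", 40, on_hdf=True, divisibility=1)
    p = Prescription(product=src, regimen=parse_scheme("1-0-0"))  # 50 mg/day
    res = _switch(p, Catalogue([src, alt]))
    assert res.group == Group.NO_AUTOMATIC_SWITCH


def test_incomplete_prescriptions_get_group5_with_warning():
    unresolved = Prescription(product=None, regimen=parse_scheme("1-0-0"), descriptor="Aspirin?")
    res = _switch(unresolved, Catalogue([]))
    assert res.group == Group.NO_AUTOMATIC_SWITCH
    assert res.has_annotation(AnnotationKind.INCOMPLETE)

    free_text = Prescription(
        product=make_product("A"), regimen=Regimen(free_text="2 Hub morgens")
    )
    res2 = _switch(free_text, Catalogue([make_product("A")]))
    assert res2.group == Group.NO_AUTOMATIC_SWITCH
    assert res2.has_annotation(AnnotationKind.INCOMPLETE)


def test_tablet_splitting_annotated():
    src = make_product("S60", "simvastatin", 60, divisibility=1)
    alt = make_product("S40", "simvastatin", 40, on_hdf=True, divisibility=2)
    p = Prescription(product=src, regimen=parse_scheme("1-0-0"))  # 60 mg/day
    res = _switch(p, Catalogue([src, alt]))
    assert res.group == Group.PHARMACEUTICAL_ALTERNATIVE
    assert res.has_annotation(AnnotationKind.TABLET_SPLITTING)
    assert res.suggestions[0].regimen.total_units == F(3, 2)


def test_excluded_class_never_reaches_step4(kb):
    insulin = make_product("INS", "insulin glargine", 100, unit="IU", atc_codes=("A10AE04",))
    other_insulin = make_product(
        "INS2", "insulin detemir", 100, unit="IU", atc_codes=("A10AE05",), on_hdf=True
    )
    res = _switch(
        Prescription(product=insulin, regimen=parse_scheme("1-0-0")),
        Catalogue([insulin, other_insulin]),
        kb,
    )
    assert res.group == Group.NO_AUTOMATIC_SWITCH
    assert res.has_annotation(AnnotationKind.EXCLUDED_CLASS)


# ---------------------------------------------------------------------------
# combination splitting
# ---------------------------------------------------------------------------


def _combo(parents_amounts, pid="CMB", divisibility=2):
    return make_product(
        pid,
        ingredients=tuple(
            IngredientStrength(parent=par, amount=F(a), unit="mg")
            for par, a in parents_amounts
        ),
        divisibility=divisibility,
    )


def test_combination_split_into_two_single_agents():
    combo = _combo([("ramipril", 5), ("hydrochlorothiazide", 25)])
    rami = make_product("RAM", "ramipril", 5, on_hdf=True)
    hct = make_product("HCT", "hydrochlorothiazide", 25, on_hdf=True)
    cat = Catalogue([combo, rami, hct])
    p = Prescription(product=combo, regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, cat, EMPTY_KB, EngineConfig())
    assert res.group == Group.PHARMACEUTICAL_EQUIVALENT  # worst component step
    assert sorted(s.product.product_id for s in res.suggestions) == ["HCT", "RAM"]
    assert all(scheme_to_text(s.regimen) == "1-0-0-0" for s in res.suggestions)
    assert res.has_annotation(AnnotationKind.COMBINATION_SPLIT)


def test_combination_split_records_worst_component_step():
    combo = _combo([("ramipril", 5), ("hydrochlorothiazide", 25)])
    rami = make_product("RAM", "ramipril", 5, on_hdf=True)
    hct50 = make_product("HCT50", "hydrochlorothiazide", 50, on_hdf=True, divisibility=2)
    cat = Catalogue([combo, rami, hct50])
    p = Prescription(product=combo, regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, cat, EMPTY_KB, EngineConfig())
    assert res.group == Group.PHARMACEUTICAL_ALTERNATIVE  # one component needed step 3
    hct_sugg = next(s for s in res.suggestions if s.product.product_id == "HCT50")
    assert total_daily_dose(hct_sugg, "hydrochlorothiazide") == 25


def test_combination_with_more_than_three_components_is_manual():
    combo = _combo([("a", 1), ("b", 2), ("c", 3), ("d", 4)])
    singles = [make_product(f"S{i}", par, a, on_hdf=True)
               for i, (par, a) in enumerate([("a", 1), ("b", 2), ("c", 3), ("d", 4)])]
    p = Prescription(product=combo, regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, Catalogue([combo] + singles), EMPTY_KB, EngineConfig())
    assert res.group == Group.NO_AUTOMATIC_SWITCH


def test_combination_split_is_all_or_nothing():
    combo = _combo([("ramipril", 5), ("hydrochlorothiazide", 25)])
    rami = make_product("RAM", "ramipril", 5, on_hdf=True)  # no HCT match at all
    p = Prescription(product=combo, regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, Catalogue([combo, rami]), EMPTY_KB, EngineConfig())
    assert res.group == Group.NO_AUTOMATIC_SWITCH
    assert res.suggestions == ()


def test_combination_never_substituted_therapeutically(kb):
    """Even with a KB class covering both parents, a combination that fails
    steps 1-3 must not be offered therapeutic equivalents."""
    combo = _combo([("simvastatin", 20), ("fenofibrate", 200)])
    prava = make_product("PRA", "pravastatin", 40, atc_codes=("C10AA03",), on_hdf=True)
    p = Prescription(product=combo, regimen=parse_scheme("1-0-0"))
    res = switch_prescription(p, Catalogue([combo, prava]), kb, EngineConfig())
    assert res.group == Group.NO_AUTOMATIC_SWITCH


def test_split_combination_requires_combination():
    single = make_product("A")
    with pytest.raises(ValueError):
        split_combination(
            Prescription(product=single, regimen=parse_scheme("1-0-0")),
            Catalogue([single]), EMPTY_KB, EngineConfig(),
        )


# ---------------------------------------------------------------------------
# consultations and determinism
# ---------------------------------------------------------------------------


def test_consultation_is_elementwise_and_ordered(kb, statin_catalogue):
    p1 = Prescription(product=statin_catalogue["SIM20"], regimen=parse_scheme("1-0-0"))
    p2 = Prescription(product=None, regimen=parse_scheme("1-0-0"), descriptor="?")
    res = switch_consultation([p1, p2, p1], statin_catalogue, kb)
    assert len(res) == 3
    assert [int(r.group) for r in res] == [4, 5, 4]
    assert res.group_counts == {1: 0, 2: 0, 3: 0, 4: 2, 5: 1}
    assert len(switch_consultation([], statin_catalogue, kb)) == 0


def test_switch_results_serialize_deterministically(kb, statin_catalogue):
    p = Prescription(product=statin_catalogue["SIM20"], regimen=parse_scheme("1-0-0"))
    a = switch_prescription(p, statin_catalogue, kb).to_json()
    b = switch_prescription(p, statin_catalogue, kb).to_json()
    assert a.encode() == b.encode()
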