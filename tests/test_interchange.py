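"""Interchange knowledge base: classes, factors, exclusions, candidates."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from rxswitch import (
    AnnotationKind,
    Catalogue,
    ExclusionRules,
    InterchangeClass,
    InterchangeMember,
    KBError,
    KnowledgeBase,
    conversion_factor,
    load_kb,
    therapeutic_candidates,
    write_kb,
)

from conftest import make_product

F = Fraction

#: the 26 ATC level-4 codes of the shipped default KB's 21 classes
TABLE_CODES = [
    "A02AA", "A02AB", "A02AC", "A02AD", "A02AF", "A02AH",
    "A02BA", "A02BC", "A04AA", "A10BB", "A10BG",
    "A12AA", "A12BA", "A12CB", "A12CC", "B03AA",
    "C03AA", "C03BA", "C03CA", "C07AA", "C07AB", "C07AG",
    "C08CA", "C09AA", "C09CA", "C10AA", "C10AB",
    "G04CA", "N02CC", "N05BA", "N05CD", "N05CF",
]


# ---------------------------------------------------------------------------
# default KB and loading
# ---------------------------------------------------------------------------


def test_default_kb_has_21_classes(kb):
    assert len(kb) == 21


def test_default_kb_codes_present_exactly_once(kb):
    codes = [code for cls in kb for code in cls.atc_codes]
    assert sorted(codes) == sorted(set(codes))
    assert set(codes) == set(TABLE_CODES)


def test_benzodiazepine_classes_do_not_interchange(kb):
    """Anxiolytics (N05BA), hypnotics (N05CD) and related drugs (N05CF) are
    separate classes: no cross-class substitution."""
    with pytest.raises(KBError, match="common class"):
        conversion_factor("diazepam", "zolpidem", kb)
    with pytest.raises(KBError, match="common class"):
        conversion_factor("temazepam", "lorazepam", kb)


def test_kb_with_excluded_atc_rejected():
    cls = InterchangeClass(
        class_id="insulins",
        name="Insulins",
        atc_codes=frozenset({"A10AB"}),
        members=(
            InterchangeMember("insulin aspart", {"type-1-diabetes": 40}),
            InterchangeMember("insulin lispro", {"type-1-diabetes": 40}),
        ),
    )
    with pytest.raises(KBError, match="excluded prefix"):
        KnowledgeBase([cls], ExclusionRules())


def test_empty_classes_kb_is_valid(tmp_path):
    f = tmp_path / "kb.yaml"
    f.write_text("classes: []\n", encoding="utf-8")
    kb = load_kb(f)
    assert len(kb) == 0
    src = make_product("S", atc_codes=("C10AA01",))
    cands = therapeutic_candidates(src, Catalogue([src]), kb)
    assert len(cands) == 0 and "no interchange class" in cands.exclusion_reason


def test_load_kb_schema_violations(tmp_path):
    dup = {
        "classes": [
            {"class_id": "x", "atc_codes": ["C10AA"],
             "members": [{"parent": "a", "equipotent_daily_dose": {"i": 1}}]},
            {"class_id": "x", "atc_codes": ["C10AB"],
             "members": [{"parent": "b", "equipotent_daily_dose": {"i": 1}}]},
        ]
    }
    f = tmp_path / "kb.yaml"
    f.write_text(yaml.safe_dump(dup), encoding="utf-8")
    with pytest.raises(KBError, match="duplicate class_id"):
        load_kb(f)
    f.write_text("classes:\n  - class_id: x\n    atc_codes: [C10AA]\n", encoding="utf-8")
    kb = load_kb(f)  # memberless class is syntactically fine
    assert len(kb["x"].members) == 0
    f.write_text("not-a-kb: true\n", encoding="utf-8")
    with pytest.raises(KBError):
        load_kb(f)


def test_kb_yaml_round_trip(kb, tmp_path):
    f = tmp_path / "kb.yaml"
    write_kb(kb, f)
    again = load_kb(f)
    assert len(again) == len(kb)
    for cls in kb:
        other = again[cls.class_id]
        assert other.atc_codes == cls.atc_codes
        assert {m.parent for m in other.members} == {m.parent for m in cls.members}
        for m in cls.members:
            assert other.member(m.parent).equipotent_daily_dose == m.equipotent_daily_dose


def test_member_invariants():
    with pytest.raises(KBError, match="> 0"):
        InterchangeMember("a", {"i": 0})
    with pytest.raises(KBError, match="indication"):
        InterchangeMember("a", {})


# ---------------------------------------------------------------------------
# conversion factors
# ---------------------------------------------------------------------------


def test_statin_factor_is_two(kb):
    f, warnings = conversion_factor("simvastatin", "pravastatin", kb, "hypercholesterolemia")
    assert f == 2
    assert warnings == []


def test_same_parent_rejected(kb):
    with pytest.raises(KBError, match="same drug"):
        conversion_factor("simvastatin", "Simvastatin", kb)


def test_factor_reciprocity_and_transitivity_across_default_kb(kb):
    """factor(a->b) x factor(b->a) = 1 and factor(a->c) = factor(a->b) x
    factor(b->c), exactly, for every shared-indication pair/triple."""
    for cls in kb:
        for a, b in itertools.permutations(cls.members, 2):
            shared = sorted(a.indications & b.indications)
            for ind in shared:
                fab, _ = conversion_factor(a.parent, b.parent, kb, ind)
                fba, _ = conversion_factor(b.parent, a.parent, kb, ind)
                assert fab * fba == 1
        for a, b, c in itertools.permutations(cls.members, 3):
            for ind in sorted(a.indications & b.indications & c.indications):
                fab, _ = conversion_factor(a.parent, b.parent, kb, ind)
                fbc, _ = conversion_factor(b.parent, c.parent, kb, ind)
                fac, _ = conversion_factor(a.parent, c.parent, kb, ind)
                assert fac == fab * fbc


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    doses=st.lists(
        st.fractions(min_value=F(1, 10), max_value=100), min_size=2, max_size=2
    ),
)
def test_factor_reciprocity_for_arbitrary_equipotent_doses(doses):
    kb = KnowledgeBase(
        [
            InterchangeClass(
                class_id="c", name="c", atc_codes=frozenset({"C10AA"}),
                members=(
                    InterchangeMember("a", {"i": doses[0]}),
                    InterchangeMember("b", {"i": doses[1]}),
                ),
            )
        ]
    )
    fab, _ = conversion_factor("a", "b", kb)
    fba, _ = conversion_factor("b", "a", kb)
    assert fab * fba == 1 and fab == doses[1] / doses[0]


def test_differing_indication_factors_warn(kb):
    """Ramipril -> enalapril differs between heart failure (5:20) and
    hypertension (5:10): the unqualified factor carries a warning."""
    f, warnings = conversion_factor("ramipril", "enalapril", kb)
    assert f == 4  # lexicographically first shared indication: heart-failure
    assert [w.kind for w in warnings] == [AnnotationKind.INDICATION_DIFFERENCE]
    f_ht, warnings_ht = conversion_factor("ramipril", "enalapril", kb, "hypertension")
    assert f_ht == 2 and warnings_ht == []


def test_no_shared_indication_is_an_error(kb):
    with pytest.raises(KBError, match="share no indication"):
        conversion_factor("felodipine", "nimodipine", kb)


# ---------------------------------------------------------------------------
# therapeutic candidates
# ---------------------------------------------------------------------------


def _statin_pair():
    src = make_product("SIM", "simvastatin", 20, atc_codes=("C10AA01",))
    tgt = make_product("PRA", "pravastatin", 40, atc_codes=("C10AA03",), on_hdf=True)
    return src, tgt


def test_candidates_found_with_factor(kb):
    src, tgt = _statin_pair()
    cands = therapeutic_candidates(src, Catalogue([src, tgt]), kb)
    assert [c.product.product_id for c in cands] == ["PRA"]
    assert cands.candidates[0].factor == 2


def test_insulin_products_excluded(kb):
    src = make_product(
        "INS", "insulin glargine", 100, unit="IU", atc_codes=("A10AE04",)
    )
    cands = therapeutic_candidates(src, Catalogue([src]), kb)
    assert len(cands) == 0
    assert "A10A" in cands.exclusion_reason


def test_non_oral_solid_source_excluded(kb):
    src = make_product(
        "NEB", "salbutamol", 5, dosage_form="inhalation", route="inhaled",
        atc_codes=("R03AC02",),
    )
    cands = therapeutic_candidates(src, Catalogue([src]), kb)
    assert len(cands) == 0 and "oral solid" in cands.exclusion_reason


def test_combination_source_never_substituted(kb):
    from rxswitch import IngredientStrength

    combo = make_product(
        "CMB", ingredients=(
            IngredientStrength("ramipril", F(5), "mg"),
            IngredientStrength("hydrochlorothiazide", F(25), "mg"),
        ),
        atc_codes=("C09BA05",),
    )
    cands = therapeutic_candidates(combo, Catalogue([combo]), kb)
    assert len(cands) == 0 and "combination" in cands.exclusion_reason


def test_indication_mismatch_blocks_candidate(kb):
    """Felodipine (hypertension) must not be offered nimodipine (cerebral
    vasospasm prevention) although both are C08CA calcium-channel blockers."""
    felo = make_product(
        "FELO", "felodipine", 5, atc_codes=("C08CA02",), indications=("hypertension",)
    )
    nimo = make_product(
        "NIMO", "nimodipine", 30, atc_codes=("C08CA06",),
        indications=("cerebral-vasospasm-prevention",), on_hdf=True,
    )
    cands = therapeutic_candidates(felo, Catalogue([felo, nimo]), kb)
    assert len(cands) == 0
    # with a shared labelled indication the class-mate is offered
    amlo = make_product(
        "AMLO", "amlodipine", 5, atc_codes=("C08CA01",),
        indications=("hypertension",), on_hdf=True,
    )
    cands2 = therapeutic_candidates(felo, Catalogue([felo, nimo, amlo]), kb)
    assert [c.product.product_id for c in cands2] == ["AMLO"]


def test_candidates_agree_with_bruteforce_filter(kb):
    """On a mixed catalogue the candidate set equals an independent scan of
    the membership, exclusion, form and indication predicates."""
    products = [
        make_product("SIM", "simvastatin", 20, atc_codes=("C10AA01",)),
        make_product("PRA", "pravastatin", 40, atc_codes=("C10AA03",), on_hdf=True),
        make_product("ATO", "atorvastatin", 10, atc_codes=("C10AA05",), on_hdf=True),
        make_product("FLU-OFF", "fluvastatin", 40, atc_codes=("C10AA04",)),  # not on HDF
        make_product("PRA-SOL", "pravastatin", 40, atc_codes=("C10AA03",),
                     dosage_form="solution", on_hdf=True),  # not oral solid
        make_product("PRA-OTHERIND", "pravastatin", 40, atc_codes=("C10AA03",),
                     indications=("something-else",), on_hdf=True),
        make_product("FENO", "fenofibrate", 200, atc_codes=("C10AB05",), on_hdf=True),
    ]
    cat = Catalogue(products)
    src = cat["SIM"]
    got = {c.product.product_id for c in therapeutic_candidates(src, cat, kb)}

    cls = next(c for c in kb if "C10AA" in c.atc_codes)
    expected = set()
    for cand in cat:
        if not cand.on_hdf or not cand.is_single_ingredient or not cand.is_oral_solid:
            continue
        parent = cand.ingredients[0].parent
        if parent == "simvastatin" or parent not in {m.parent for m in cls.members}:
            continue
        if not any(code.startswith("C10AA") for code in cand.atc_codes):
            continue
        member = cls.member(parent)
        usable = (
            src.indications & cand.indications
            & cls.member("simvastatin").indications & member.indications
        )
        if usable:
            expected.add(cand.product_id)
    assert got == expected == {"PRA", "ATO"}
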