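"""Switch one prescription to the formulary: the classic statin example.

A patient takes simvastatin 20 mg once daily; the hospital stocks no
simvastatin but does stock pravastatin 40 mg. Steps 1-3 fail (no identical
product, no equivalent, no alternative), so the engine switches within the
HMG-CoA reductase inhibitor class using the 20:40 mg/day equipotent doses
(conversion factor 2.0) and recomputes the regimen.
"""

from fractions import Fraction

from rxswitch import (
    Catalogue,
    DrugProduct,
    IngredientStrength,
    Prescription,
    default_kb,
    parse_scheme,
    scheme_to_text,
    switch_prescription,
    total_daily_dose,
)

simvastatin = DrugProduct(
    product_id="SIM20",
    brand_name="Simvastatin 20 mg",
    ingredients=(IngredientStrength("simvastatin", Fraction(20), "mg"),),
    dosage_form="tablet", release="immediate", route="oral",
    atc_codes=("C10AA01",), indications=frozenset({"hypercholesterolemia"}),
    on_hdf=False, divisibility=2,
)
pravastatin = DrugProduct(
    product_id="PRA40",
    brand_name="Pravastatin 40 mg",
    ingredients=(IngredientStrength("pravastatin", Fraction(40), "mg"),),
    dosage_form="tablet", release="immediate", route="oral",
    atc_codes=("C10AA03",), indications=frozenset({"hypercholesterolemia"}),
    on_hdf=True, divisibility=2,
)

catalogue = Catalogue([simvastatin, pravastatin])
prescription = Prescription(product=simvastatin, regimen=parse_scheme("1-0-0"))

result = switch_prescription(prescription, catalogue, default_kb())

print(f"group: {int(result.group)} ({result.group.name})")
for s in result.suggestions:
    parent = s.product.ingredients[0].parent
    print(
        f"suggestion: {s.product.brand_name}, scheme {scheme_to_text(s.regimen)}"
        f" -> {float(total_daily_dose(s, parent)):g} mg/day {parent}"
    )
print("trace:", " | ".join(f"step {t.step}: {t.outcome}" for t in result.trace))
print()
print("Group 4 means a therapeutic equivalent was needed: 20 mg/day simvastatin")
print("times the class conversion factor 2.0 gives the 40 mg/day pravastatin dose.")
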