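from __future__ import annotations

from fractions import Fraction

import pytest

from rxswitch import (
    Catalogue,
    DrugProduct,
    IngredientStrength,
    default_kb,
)


def make_product(
    product_id: str,
    parent: str = "simvastatin",
    amount=20,
    unit: str = "mg",
    dosage_form: str = "tablet",
    release: str = "immediate",
    route: str = "oral",
    atc_codes: tuple = (),
    indications=("hypercholesterolemia",),
    on_hdf: bool = False,
    divisibility: int = 2,
    salt: str | None = None,
    brand_name: str | None = None,
    ingredients: tuple | None = None,
) -> DrugProduct:
    if ingredients is None:
        ingredients = (
            IngredientStrength(parent=parent, amount=Fraction(amount), unit=unit, salt=salt),
        )
    return DrugProduct(
        product_id=product_id,
        brand_name=brand_name or f"{parent.title()} {amount}",
        ingredients=ingredients,
        dosage_form=dosage_form,
        release=release,
        route=route,
        atc_codes=tuple(atc_codes),
        indications=frozenset(indications),
        on_hdf=on_hdf,
        divisibility=divisibility,
    )


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture()
def statin_catalogue():
    """Off-formulary simvastatin 20 mg with only pravastatin 40 mg on HDF:
    the canonical therapeutic-equivalence situation."""
    simva = make_product(
        "SIM20", "simvastatin", 20, atc_codes=("C10AA01",), on_hdf=False
    )
    prava = make_product(
        "PRA40", "pravastatin", 40, atc_codes=("C10AA03",), on_hdf=True
    )
    return Catalogue([simva, prava])
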