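"""Drug-product catalogue: data model and indexed matching queries.

The catalogue is the universe of marketed drug products; the hospital drug
formulary (HDF) is the on-formulary subset of it. Two queries implement the
middle steps of the switch algorithm:

* :func:`equivalents_query` — *pharmaceutical equivalents*: same active moiety
  (drug parent), same strength (within a configurable relative tolerance),
  same application form, release type and route.
* :func:`alternatives_query` — *pharmaceutical alternatives*: same parent in a
  comparable dosage form but a different strength, which therefore require the
  dose regimen to be recomputed.

Equivalence and comparability are decided on the *parent* — the active moiety
irrespective of salt or ester form — with salt differences surfaced as
warnings rather than blocking a match, and on a dosage-form *comparability
group* (plain, film-coated and sugar-coated tablets and capsules are one
oral-solid group; liquids, parenterals etc. are separate). Modified-release
products are never comparable to immediate-release ones: that would change
the release characteristics, which this tool does not attempt to convert.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from ._util import as_fraction, is_valid_atc

__all__ = [
    "IngredientStrength",
    "DrugProduct",
    "Catalogue",
    "CatalogueError",
    "load_catalogue",
    "write_catalogue",
    "equivalents_query",
    "alternatives_query",
    "normalize_ingredient_name",
    "DEFAULT_FORM_GROUPS",
]

UNITS = frozenset({"mg", "microgram", "IU"})

RELEASES = frozenset({"immediate", "modified"})

ROUTES = frozenset({"oral", "parenteral", "inhaled", "topical", "other"})

DIVISIBILITIES = frozenset({1, 2, 4})

#: dosage_form -> comparability group. Config-overridable: pass ``form_groups``
#: to the loaders/constructors. Forms absent from the mapping form their own
#: singleton group (conservative: nothing unexpected is ever cross-matched).
DEFAULT_FORM_GROUPS: Mapping[str, str] = {
    "tablet": "oral-solid",
    "film-coated-tablet": "oral-solid",
    "coated-tablet": "oral-solid",
    "orodispersible-tablet": "oral-solid",
    "capsule": "oral-solid",
    "solution": "liquid",
    "suspension": "liquid",
    "syrup": "liquid",
    "drops": "liquid",
    "injection": "parenteral",
    "infusion": "parenteral",
    "inhalation": "inhalation",
    "suppository": "rectal",
    "patch": "transdermal",
    "cream": "topical",
    "ointment": "topical",
}

#: Common salt / ester / hydrate descriptors stripped from ingredient names to
#: obtain the drug parent. Multi-word descriptors are stripped word by word
#: from the right ("metoprolol tartrate dihydrate" -> parent "metoprolol").
SALT_WORDS = frozenset(
    {
        "acetate", "besilate", "besylate", "bromide", "chloride", "citrate",
        "decanoate", "dihydrate", "dipropionate", "disodium", "embonate",
        "enantate", "fumarate", "furoate", "hemihydrate", "hydrobromide",
        "hydrochloride", "hydrogen", "lactate", "maleate", "malate",
        "mesilate", "mesylate", "monohydrate", "nitrate", "oxalate",
        "palmitate", "pamoate", "phosphate", "propionate", "sodium",
        "stearate", "succinate", "sulfate", "sulphate", "tartrate",
        "tosilate", "trihydrate", "valerate",
    }
)


def normalize_ingredient_name(name: str) -> tuple[str, str | None]:
    """Case-fold an ingredient name and split off a trailing salt descriptor.

    Returns ``(parent, salt)`` where ``salt`` is None when the name carries no
    recognised salt/ester/hydrate suffix. At least one word is always kept as
    the parent ("sodium chloride" keeps "sodium").
    """
    words = name.strip().casefold().split()
    if not words:
        raise ValueError("empty ingredient name")
    salt_words: list[str] = []
    while len(words) > 1 and words[-1] in SALT_WORDS:
        salt_words.insert(0, words.pop())
    parent = " ".join(words)
    salt = " ".join(salt_words) if salt_words else None
    return parent, salt


@dataclass(frozen=True)
class IngredientStrength:
    """One active ingredient of a product with its per-dose-unit strength."""

    parent: str
    amount: Fraction
    unit: str
    salt: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "amount", as_fraction(self.amount))
        if not self.parent:
            raise ValueError("ingredient parent must be non-empty")
        if self.amount <= 0:
            raise ValueError(f"ingredient amount must be > 0, got {self.amount}")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {sorted(UNITS)}, got {self.unit!r}")

    @classmethod
    def parse(cls, text: str) -> "IngredientStrength":
        """Parse the ``name:amount:unit`` sub-field dialect, e.g.
        ``metoprolol tartrate:95:mg``. The salt, if present, is split off the
        name and kept as informational metadata."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"ingredient must be name:amount:unit, got {text!r}")
        name, amount, unit = (p.strip() for p in parts)
        parent, salt = normalize_ingredient_name(name)
        return cls(parent=parent, amount=as_fraction(amount), unit=unit, salt=salt)

    @property
    def unit_class(self) -> str:
        """Mass amounts (mg, microgram) are mutually convertible; IU amounts
        are comparable only to IU — the IU-to-mass factor is drug-specific."""
        return "IU" if self.unit == "IU" else "mass"

    @property
    def normalized_amount(self) -> Fraction:
        """Amount in mg for mass units (microgram / 1000), or IU as-is."""
        if self.unit == "microgram":
            return self.amount / 1000
        return self.amount

    def serialize(self) -> str:
        name = self.parent if self.salt is None else f"{self.parent} {self.salt}"
        amt = self.amount
        amt_s = str(amt.numerator) if amt.denominator == 1 else f"{float(amt):g}"
        return f"{name}:{amt_s}:{self.unit}"


@dataclass(frozen=True)
class DrugProduct:
    """One marketed brand: ingredients with strengths, form, ATC codes,
    formulary membership and how finely a dose unit can be divided."""

    product_id: str
    brand_name: str
    ingredients: tuple[IngredientStrength, ...]
    dosage_form: str
    release: str
    route: str
    atc_codes: tuple[str, ...] = ()
    indications: frozenset[str] = frozenset()
    on_hdf: bool = False
    divisibility: int = 1
    form_group: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        object.__setattr__(self, "atc_codes", tuple(self.atc_codes))
        object.__setattr__(self, "indications", frozenset(self.indications))
        if not self.product_id:
            raise ValueError("product_id must be non-empty")
        if not self.ingredients:
            raise ValueError(f"{self.product_id}: product needs >= 1 ingredient")
        if self.release not in RELEASES:
            raise ValueError(f"{self.product_id}: release must be one of {sorted(RELEASES)}")
        if self.route not in ROUTES:
            raise ValueError(f"{self.product_id}: route must be one of {sorted(ROUTES)}")
        for code in self.atc_codes:
            if not is_valid_atc(code):
                raise ValueError(f"{self.product_id}: malformed ATC code {code!r}")
        if self.divisibility not in DIVISIBILITIES:
            raise ValueError(f"{self.product_id}: divisibility must be 1, 2 or 4")
        if not self.form_group:
            object.__setattr__(
                self,
                "form_group",
                DEFAULT_FORM_GROUPS.get(self.dosage_form, self.dosage_form),
            )

    # -- convenience -------------------------------------------------------

    @property
    def parents(self) -> frozenset[str]:
        return frozenset(i.parent for i in self.ingredients)

    @property
    def is_single_ingredient(self) -> bool:
        return len(self.ingredients) == 1

    @property
    def is_oral_solid(self) -> bool:
        return self.route == "oral" and self.form_group == "oral-solid"

    def ingredient(self, parent: str) -> IngredientStrength:
        for i in self.ingredients:
            if i.parent == parent:
                return i
        raise KeyError(f"{parent!r} not an ingredient of {self.product_id}")

    def strength_of(self, parent: str) -> Fraction:
        """Normalized strength (mg or IU) of one parent per dose unit."""
        return self.ingredient(parent).normalized_amount

    def with_form_group(self, form_groups: Mapping[str, str]) -> "DrugProduct":
        return replace(
            self, form_group=form_groups.get(self.dosage_form, self.dosage_form)
        )


class CatalogueError(ValueError):
    """Raised for malformed catalogue files; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class Catalogue:
    """Indexed collection of :class:`DrugProduct` with an HDF subset.

    Iteration order and every query result are deterministic and invariant
    under input row permutation (products are indexed by sorted product_id).
    """

    def __init__(self, products: Iterable[DrugProduct]):
        by_id: dict[str, DrugProduct] = {}
        for p in products:
            if p.product_id in by_id:
                raise CatalogueError(f"duplicate product_id {p.product_id!r}")
            by_id[p.product_id] = p
        self._by_id = dict(sorted(by_id.items()))
        self._by_parents: dict[frozenset[str], list[str]] = {}
        self._by_parent: dict[str, list[str]] = {}
        for pid, p in self._by_id.items():
            self._by_parents.setdefault(p.parents, []).append(pid)
            for parent in p.parents:
                self._by_parent.setdefault(parent, []).append(pid)
        self.n_skipped: int = 0
        self.errors: list[str] = []

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[DrugProduct]:
        return iter(self._by_id.values())

    def __contains__(self, product_id: str) -> bool:
        return product_id in self._by_id

    def __getitem__(self, product_id: str) -> DrugProduct:
        return self._by_id[product_id]

    def get(self, product_id: str) -> DrugProduct | None:
        return self._by_id.get(product_id)

    def hdf_products(self) -> Iterator[DrugProduct]:
        return (p for p in self if p.on_hdf)

    @property
    def n_hdf(self) -> int:
        return sum(1 for _ in self.hdf_products())

    def with_same_parents(self, parents: frozenset[str]) -> list[DrugProduct]:
        return [self._by_id[pid] for pid in self._by_parents.get(parents, [])]

    def with_parent(self, parent: str) -> list[DrugProduct]:
        return [self._by_id[pid] for pid in self._by_parent.get(parent, [])]

    def by_atc_prefix(self, prefix: str) -> list[DrugProduct]:
        return [p for p in self if any(c.startswith(prefix) for c in p.atc_codes)]

    def by_brand(self, brand: str) -> list[DrugProduct]:
        key = brand.strip().casefold()
        return [p for p in self if p.brand_name.strip().casefold() == key]


# ---------------------------------------------------------------------------
# File I/O: semicolon-delimited text (header mandatory, decimal point) or an
# equivalent JSON records file with the same field names.
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "product_id", "brand_name", "ingredients", "dosage_form", "release",
    "route", "atc_codes", "indications", "on_hdf", "divisibility",
]


def _product_from_record(rec: Mapping, row: int) -> DrugProduct:
    try:
        raw_ing = rec["ingredients"]
        if isinstance(raw_ing, str):
            parts = [s for s in (x.strip() for x in raw_ing.split("+")) if s]
        else:
            parts = [str(x) for x in raw_ing]
        if not parts:
            raise ValueError("ingredients field is empty")
        ingredients = tuple(IngredientStrength.parse(s) for s in parts)

        def split_list(value) -> tuple[str, ...]:
            if isinstance(value, str):
                return tuple(s for s in (x.strip() for x in value.split(",")) if s)
            return tuple(str(x) for x in value)

        raw_hdf = rec["on_hdf"]
        if isinstance(raw_hdf, bool):
            on_hdf = raw_hdf
        elif str(raw_hdf).strip() in {"0", "1"}:
            on_hdf = str(raw_hdf).strip() == "1"
        else:
            raise ValueError(f"on_hdf must be 0 or 1, got {raw_hdf!r}")

        return DrugProduct(
            product_id=str(rec["product_id"]).strip(),
            brand_name=str(rec["brand_name"]).strip(),
            ingredients=ingredients,
            dosage_form=str(rec["dosage_form"]).strip(),
            release=str(rec["release"]).strip(),
            route=str(rec["route"]).strip(),
            atc_codes=split_list(rec["atc_codes"]),
            indications=frozenset(split_list(rec["indications"])),
            on_hdf=on_hdf,
            divisibility=int(rec["divisibility"]),
        )
    except KeyError as e:
        raise CatalogueError(f"missing field {e.args[0]!r}", row) from e
    except (ValueError, ZeroDivisionError) as e:
        raise CatalogueError(str(e), row) from e


def load_catalogue(
    path: str | Path,
    strict: bool = True,
    form_groups: Mapping[str, str] | None = None,
) -> Catalogue:
    """Load a catalogue from delimited text (``;``-separated, header row
    mandatory, UTF-8, decimal point) or from a JSON records file.

    In strict mode any invalid row aborts the load with a
    :class:`CatalogueError` naming the row; otherwise invalid rows are
    skipped, counted in ``Catalogue.n_skipped`` and described in
    ``Catalogue.errors``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"catalogue file not found: {path}")
    text = path.read_text(encoding="utf-8")
    records: list[tuple[int, Mapping]] = []
    if text.lstrip().startswith("["):
        for i, rec in enumerate(json.loads(text), start=1):
            records.append((i, rec))
    else:
        reader = csv.reader(text.splitlines(), delimiter=";")
        try:
            header = next(reader)
        except StopIteration:
            raise CatalogueError("empty catalogue file") from None
        if [h.strip() for h in header] != CSV_COLUMNS:
            raise CatalogueError(
                f"header must be {';'.join(CSV_COLUMNS)!r}, got {';'.join(header)!r}",
                row=1,
            )
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(CSV_COLUMNS):
                records.append((i, {"__bad_row__": row}))
            else:
                records.append((i, dict(zip(CSV_COLUMNS, row))))

    products: list[DrugProduct] = []
    seen_ids: dict[str, int] = {}
    skipped: list[str] = []
    for row_no, rec in records:
        try:
            if "__bad_row__" in rec:
                raise CatalogueError(
                    f"expected {len(CSV_COLUMNS)} fields, got {len(rec['__bad_row__'])}",
                    row_no,
                )
            product = _product_from_record(rec, row_no)
            if product.product_id in seen_ids:
                raise CatalogueError(
                    f"duplicate product_id {product.product_id!r}"
                    f" (first seen at row {seen_ids[product.product_id]})",
                    row_no,
                )
            seen_ids[product.product_id] = row_no
            if form_groups is not None:
                product = product.with_form_group(form_groups)
            products.append(product)
        except CatalogueError as e:
            if strict:
                raise
            skipped.append(str(e))
    cat = Catalogue(products)
    cat.n_skipped = len(skipped)
    cat.errors = skipped
    return cat


def write_catalogue(cat: Catalogue, path: str | Path) -> None:
    """Serialize a catalogue back to the delimited-text dialect."""
    lines = [";".join(CSV_COLUMNS)]
    for p in cat:
        lines.append(
            ";".join(
                [
                    p.product_id,
                    p.brand_name,
                    "+".join(i.serialize() for i in p.ingredients),
                    p.dosage_form,
                    p.release,
                    p.route,
                    ",".join(p.atc_codes),
                    ",".join(sorted(p.indications)),
                    "1" if p.on_hdf else "0",
                    str(p.divisibility),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Matching queries
# ---------------------------------------------------------------------------


def _strength_profile_comparable(a: DrugProduct, b: DrugProduct) -> bool:
    """True when every shared parent has comparable units in both products."""
    for parent in a.parents:
        ia, ib = a.ingredient(parent), b.ingredient(parent)
        if ia.unit_class != ib.unit_class:
            return False
    return True


def _max_rel_deviation(source: DrugProduct, cand: DrugProduct) -> Fraction:
    """Largest per-parent relative strength deviation, relative to source."""
    dev = Fraction(0)
    for parent in source.parents:
        s = source.strength_of(parent)
        c = cand.strength_of(parent)
        dev = max(dev, abs(s - c) / s)
    return dev


def _ranking_key(source: DrugProduct, cand: DrugProduct):
    """Deterministic candidate ranking: (1) smallest relative strength
    deviation, (2) fewest implied dose units per day (i.e. prefer the higher
    strength: source/candidate strength ratio), (3) product_id."""
    implied_units = sum(
        (source.strength_of(p) / cand.strength_of(p) for p in sorted(source.parents)),
        Fraction(0),
    )
    return (_max_rel_deviation(source, cand), implied_units, cand.product_id)


def _same_presentation(source: DrugProduct, cand: DrugProduct) -> bool:
    return (
        cand.form_group == source.form_group
        and cand.release == source.release
        and cand.route == source.route
    )


def equivalents_query(
    source: DrugProduct, cat: Catalogue, rel_tol: Fraction | float = 0
) -> list[DrugProduct]:
    """HDF products pharmaceutically equivalent to ``source``.

    Same parent set, each parent's normalized strength within relative
    tolerance ``rel_tol`` of the source's, same form group, release and
    route. The source itself (same product_id) is excluded; results are
    deterministically ranked.
    """
    rel_tol = as_fraction(rel_tol)
    if rel_tol < 0:
        raise ValueError("rel_tol must be >= 0")
    out = []
    for cand in cat.with_same_parents(source.parents):
        if not cand.on_hdf or cand.product_id == source.product_id:
            continue
        if not _same_presentation(source, cand):
            continue
        if not _strength_profile_comparable(source, cand):
            continue
        if _max_rel_deviation(source, cand) <= rel_tol:
            out.append(cand)
    out.sort(key=lambda c: _ranking_key(source, c))
    return out


def _proportional_strengths(source: DrugProduct, cand: DrugProduct) -> bool:
    """For combination products an alternative must scale every component by
    the same factor, otherwise no single regimen preserves all daily doses."""
    parents = sorted(source.parents)
    ratios = {cand.strength_of(p) / source.strength_of(p) for p in parents}
    return len(ratios) == 1


def alternatives_query(
    source: DrugProduct, cat: Catalogue, rel_tol: Fraction | float = 0
) -> list[DrugProduct]:
    """HDF products with the source's parent(s) in a comparable form but a
    strength outside the equivalence tolerance (pharmaceutical alternatives).

    ``rel_tol`` must be the tolerance used for the equivalence query so the
    two result sets are disjoint by construction. Multi-ingredient sources
    only match candidates whose component strengths are scaled uniformly.
    """
    rel_tol = as_fraction(rel_tol)
    out = []
    for cand in cat.with_same_parents(source.parents):
        if not cand.on_hdf or cand.product_id == source.product_id:
            continue
        if not _same_presentation(source, cand):
            continue
        if not _strength_profile_comparable(source, cand):
            continue
        if _max_rel_deviation(source, cand) <= rel_tol:
            continue  # that is an equivalent, not an alternative
        if not _proportional_strengths(source, cand):
            continue
        out.append(cand)
    out.sort(key=lambda c: _ranking_key(source, c))
    return out
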