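# Methods

## The switching problem

On admission, a patient's pre-admission medication must be mapped onto the
hospital drug formulary (HDF) — the restricted list of products the hospital
stocks. Done by hand this is slow and error-prone: dose errors and wrongly
split combination products are the typical failure modes. `rxswitch`
implements the rule-based procedure hospital pharmacies use for this, as a
deterministic, auditable engine over pluggable drug catalogues.

## The five-step algorithm

Each prescription is tried against the steps strictly in order; the outcome
group is the first step that produces a usable suggestion.

1. **HDF drug** — the product itself is on the formulary; it is kept,
   regimen untouched.
2. **Pharmaceutical equivalent** — an HDF product with the same drug
   parent(s), the same strength (within `rel_tol`, see below), the same
   dosage-form comparability group, release type and route. The regimen
   carries over unchanged.
3. **Pharmaceutical alternative** — same parent(s) in a comparable form but
   a different strength. The total daily dose (TDD = Σ slot units ×
   strength) is preserved by recomputing the administration scheme against
   the candidate's strength and divisibility.
4. **Therapeutic equivalent** — a different parent of the same interchange
   class. The target daily dose is TDD × conversion factor, where the
   factor is the ratio of equipotent daily doses (target/source) for the
   matched indication; the scheme is then recomputed as in step 3. Only
   single-ingredient oral solid products are eligible on both sides.
5. **No automatic switch** — everything else (including incomplete
   prescriptions) is routed to a physician or pharmacist.

Combination products that fail steps 1–3 as a whole are split into virtual
single-agent prescriptions (component strength × original scheme), each run
through steps 2–3. Step 1 is not meaningful for a virtual component (it is
not a marketed product), and step 4 is deliberately never applied to
components. The split is all-or-nothing and the recorded group is the worst
component's step. Products with more than `max_combination_components`
(default 3) active ingredients are never split automatically.

## Matching semantics

* **Parent normalisation.** Equivalence is decided on the active moiety:
  ingredient names are case-folded and recognised trailing salt/ester/
  hydrate descriptors are stripped ("Metoprolol Tartrate" → parent
  `metoprolol`, salt `tartrate`). A differing salt never blocks a match but
  is surfaced as a typed `salt-difference` warning, since the choice of
  salt can occasionally matter clinically.
* **Units.** Microgram strengths are normalised to mg (÷1000) before
  comparison. IU strengths compare only to IU: the IU↔mass factor is
  drug-specific and out of scope.
* **Strength tolerance** `rel_tol` (default 0). Exact matching reproduces
  the historical behaviour, which notoriously fails on salt-rounding
  differences such as 78.09 vs 77.82 mg metoprolol (relative difference
  ≈ 0.35%). Setting `rel_tol = 0.01` absorbs these; the same tolerance is
  applied as the lower bound of the *alternative* definition so the two
  candidate sets stay disjoint at any tolerance.
* **Form comparability.** A shipped mapping assigns each dosage form to a
  comparability group (plain/film-coated/sugar-coated tablets and capsules
  form one oral-solid group; liquids, parenterals, inhalations etc. are
  separate; unknown forms become singleton groups). The mapping is
  overridable per catalogue load. Modified-release products are never
  comparable to immediate-release ones — that would change release
  characteristics, which this engine does not convert.
* **Divisibility guard in step 2.** An equivalent product whose
  divisibility cannot express the source scheme (e.g. "1/2-0-0" onto a
  product only dispensable as whole tablets) is skipped and the next
  candidate tried, rather than suggested with an unadministrable regimen.
* **Candidate ranking** (where several HDF products qualify): smallest
  relative strength deviation, then fewest implied dose units per day
  (prefer the higher-strength product), then lexicographic product id.
  This makes results deterministic and invariant under catalogue row
  permutation.

## Regimen arithmetic

Schemes use the German `morning-noon-evening(-night)` notation ("1-0-1");
slots are exact rationals (`fractions.Fraction`), so half/quarter tablets
and all dose comparisons are free of floating-point artefacts, and repeated
runs serialize byte-identically. Unparseable schemes ("2 Hub morgens") are
flagged as free text and routed to group 5, never silently dropped.

`redistribute` searches schemes whose slots are multiples of
1/divisibility with at most `max_units_per_slot` (default 4) units per
slot — a bound chosen because realistic oral regimens never exceed it, and
it keeps exhaustive verification of the search trivial. The search is
two-phase: first the achievable total unit counts are scanned for the
minimal relative deviation |achieved − target|/target; then the winning
totals are distributed over the four slots preferring (in order) fewest
administrations per day, fewest split dose units, doses earlier in the
day. The preference order encodes regimen simplicity — complicated schemes
and tablet splitting promote non-adherence — and fractional slots always
carry a `tablet-splitting` annotation. Note the order implies "1½ in the
morning" is preferred over "1-0-½" when both hit the target: one
administration beats two.

If even the best scheme deviates more than `max_dose_deviation` (default
10%), the conversion is *infeasible* and the prescription demotes to group
5 rather than emitting a wrong dose. The 10% default is a documented
policy choice (no published threshold exists for the tolerated
post-conversion deviation) and is configurable.

## The interchange knowledge base

Conversion factors are stored as per-member *equipotent daily doses* per
indication, not as n² pairwise factors; factors are derived as exact dose
ratios, which makes reciprocity (f(a→b)·f(b→a)=1) and in-class
transitivity hold identically by construction. Indication handling is a
flat controlled vocabulary with set-intersection matching: a candidate is
offered only when its labelled indications intersect the source product's
(this is what stops felodipine, a hypertension drug, from being replaced
by nimodipine, a cerebral-vasospasm drug, although both are C08CA
calcium-channel blockers). When a pair converts differently for different
shared indications, the lexicographically first indication is used and an
`indication-difference` warning is attached.

The shipped default KB contains 21 interchange classes scoped by ATC
level-4 codes (each code appearing exactly once across classes), with the
three benzodiazepine groups kept separate — no cross-class interchange.
Exclusion rules bar insulins (A10A), alpha-adrenoceptor blockers (C02CA),
hyperkalemia/hyperphosphatemia drugs (V03AE) and other antianemics (B03XA)
from automatic substitution, and restrict therapeutic interchange to oral
solid forms. The numeric equipotent doses in the default KB are
curator-editable placeholders taken from approved maintenance doses
(SPC-style); only the simvastatin:pravastatin 20:40 mg/day pair is fixed as
the reference example. Nothing in the test suite depends on the placeholder
values.

Open design points resolved here: products carrying several ATC codes are
tested against every class code (prefix semantics, so C10AA01 falls under
C10AA); class membership requires both the parent and, when the product
carries codes, an ATC match.

## Synthetic data generator

No real catalogue or patient data can ship, so `fixtures` engineers both.
For each of `n_products` planned cases it draws an intended outcome group
from the mix (defaults 31.7 / 40.7 / 12.2 / 7.0 / 8.4 percent — the field
mix of the final evaluated version) and emits a source product plus exactly
the HDF relative that realises that path: an identical twin for group 2, a
double-strength sibling for group 3, a co-classed different parent with a
known factor (1, 2 or ½) and matching strength for group 4, nothing for
group 5 (every seventh group-5 case is a four-ingredient combination
instead). Parents, indications and class ATC codes are unique per case, so
each planned prescription has exactly one resolution path and the manifest
is a sound oracle. Consultation sizes are truncated-normal (mean 7.5, SD
3.9, minimum 1 — a zero-drug consultation is meaningless) and 12.2% of
prescriptions are rendered incomplete by blanking either the product
reference or the scheme, emulating illegible handwritten consultation
faxes.

What the generator does *not* emulate: realistic brand names,
market-share-weighted drug sampling, correlated drug classes within one
patient, near-miss strengths, multi-candidate ambiguity, or messy free-text
dose instructions beyond the blanking mechanism. Passing the recovery test
therefore shows the engine implements the intended decision logic exactly;
it does not certify performance on a real national drug catalogue.

## Evaluation bookkeeping

`classify` calls an engine suggestion *identical* to the manual reference
iff the multisets of (product id, scheme) pairs match exactly — order
never matters, a changed scheme on the same product does. Whether a
*different* suggestion is equivalent, better or worse is an expert
judgement read from an external label file, never inferred.
`performance_table` tallies groups over the assessable prescriptions
(documented minus incomplete) with percentages rounded half-up to one
decimal per cell; the automatic-switch total (Σ groups 1–4) is the sum of
the rounded cells, as such tables are conventionally printed (a column may
sum to 100.1), with the exact value carried alongside.

## Problem sizes and numerical choices

The test suite verifies the matching predicates against brute-force scans
on catalogues of up to 100 products, regimen redistribution against
exhaustive scheme enumeration, and ground-truth recovery on ~150 planned
cases / ≥500 generated prescriptions — sizes at which the independent
oracles are trivially correct by inspection while still exercising every
code path. All dose arithmetic is exact rational arithmetic; the only
floating-point values are those serialized for display. Determinism is
absolute: same inputs give byte-identical outputs, and the generator uses
separate child streams of one seeded generator per artefact kind, so
requesting more consultations never changes the catalogue.

## Known limitations

* Release-form conversion (modified ↔ immediate), parenteral and inhaled
  switching, and oral↔IV conversion at ICU admission are out of scope by
  design; such prescriptions end in group 5.
* PRN dosing, weekly/alternate-day regimens and titration schedules are
  not representable in the four-slot scheme model.
* The default KB's equipotent doses are placeholders; a deployment must
  curate them from the literature and local policy.
* IU-denominated products never match mass-denominated ones, even where a
  drug-specific conversion exists.
* Indication matching is flat token intersection; no ontology or synonym
  handling.
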