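# rxswitch

Rule-based switching of pre-admission medications to a hospital drug
formulary (HDF), for pharmacists, hospital-pharmacy informaticians and
medication-reconciliation researchers.

When a patient is admitted, drugs that are not on the hospital's restricted
formulary must be substituted. `rxswitch` implements the standard multi-step
decision procedure for this as a tested Python library with a thin CLI:

1. **HDF drug** — the product is already on the formulary: keep it.
2. **Pharmaceutical equivalent** — same active moiety (drug parent), same
   strength, same application form on the HDF: switch product, keep the
   regimen.
3. **Pharmaceutical alternative** — same parent, different strength,
   comparable form: switch and recompute the administration scheme so the
   total daily dose (TDD = Σ slot units × strength) is preserved.
4. **Therapeutic equivalent** — a different parent of the same interchange
   class (e.g. another HMG-CoA reductase inhibitor under ATC C10AA): the
   target dose is TDD × *f*, where the conversion factor
   *f* = EDD(target, indication) / EDD(source, indication) is the ratio of
   equipotent daily doses for the matched indication; then recompute the
   scheme.
5. **No automatic switch** — everything else goes to a pharmacist, including
   incomplete prescriptions, excluded drug groups (insulins A10A,
   alpha-adrenoceptor blockers C02CA, hyperkalemia/hyperphosphatemia drugs
   V03AE, other antianemics B03XA), non-oral-solid therapeutic switches and
   combinations with more than three active ingredients.

Combination products are split into single agents (steps 2–3 per component,
all-or-nothing). Every suggestion carries typed warnings
(indication-difference, tablet-splitting, salt-difference, dose-deviation)
and a full step-by-step trace. All dose arithmetic is exact rational
arithmetic and every result is deterministic.

The package also ships a synthetic fixture generator (catalogues,
knowledge bases and consultations with constructed ground truth, shaped
like real admission workloads: truncated-normal 7.5 ± 3.9 drugs per
consultation, 12.2% incomplete prescriptions) and the evaluation
bookkeeping used to score an engine against manual reference switches.
See `docs/methods.md` for the full model description.

## Worked example

A patient takes simvastatin 20 mg once daily ("1-0-0"); the hospital stocks
no simvastatin, but pravastatin 40 mg is on the formulary and both are
C10AA statins with equipotent daily doses 20 and 40 mg/day:

```sh
python examples/01_switch_single_prescription.py
```

```
group: 4 (THERAPEUTIC_EQUIVALENT)
suggestion: Pravastatin 40 mg, scheme 1-0-0-0 -> 40 mg/day pravastatin
trace: step 1: no-match | step 2: no-match | step 3: no-match | step 4: matched
```

Steps 1–3 find nothing (no identical product, no equivalent, no
same-parent alternative), so the engine applies the class conversion
factor 2.0 to the 20 mg/day source dose and proposes pravastatin 40 mg
once daily — 40 mg/day, one whole tablet, no splitting warning.

`examples/02_interchange_factors.py` shows the knowledge-base side
(exact factor reciprocity, the indication-difference warning for
ramipril → enalapril, and the indication gate that refuses
felodipine → nimodipine), and `examples/03_simulate_and_evaluate.py` runs a
full synthetic evaluation:

```
generated 189 products (109 on the formulary), 60 consultations, 517 prescriptions (65 incomplete)
ground-truth group recovery: 452/452 complete prescriptions

Documented prescriptions: 517
Excluded (incomplete):    65  (assessable 87.4%)
Assessable:               452

Group 1: HDF drug                      147   32.5%
Group 2: Pharmaceutical equivalent     186   41.2%
Group 3: Pharmaceutical alternative     50   11.1%
Group 4: Therapeutic equivalent         23    5.1%
Σ: automatic switch                    406   89.9%
Group 5: No automatic switch            46   10.2%
```

The Σ row is the share the engine switches without human help; group 5 is
the manual workload that remains. Percentages are per-cell half-up, so a
column can sum to slightly more than 100.

## Command line

```sh
rxswitch simulate --seed 42 --n-products 100 --out-dir data/   # synthetic fixtures
rxswitch run      --catalogue data/catalogue.csv --kb data/kb.yaml \
                  --input data/consultations.csv --format table
rxswitch evaluate --catalogue data/catalogue.csv --kb data/kb.yaml \
                  --input data/consultations.csv --reference ref.csv
rxswitch lint-kb  --kb data/kb.yaml
```

Catalogues are semicolon-delimited text (or equivalent JSON records) and
knowledge bases are YAML; JSON-Schema documents for both dialects ship in
`src/rxswitch/data/schemas/`. The default knowledge base
(`rxswitch.default_kb()`) contains 21 interchange classes with
curator-editable placeholder equipotent doses.

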