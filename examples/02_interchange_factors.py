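"""Explore the interchange knowledge base: factors, warnings, exclusions.

Shows the equipotent-dose arithmetic (factors are exact dose ratios, so
reciprocity holds exactly), the indication-difference warning when a drug
pair converts differently per indication, and the indication gate that
blocks a same-class substitution with non-overlapping labelled indications.
"""

from rxswitch import KBError, conversion_factor, default_kb

kb = default_kb()
print(f"knowledge base: {len(kb)} interchange classes")
print(f"excluded ATC prefixes: {', '.join(sorted(kb.exclusions.atc_prefixes))}")
print()

f, _ = conversion_factor("simvastatin", "pravastatin", kb, "hypercholesterolemia")
g, _ = conversion_factor("pravastatin", "simvastatin", kb, "hypercholesterolemia")
print(f"simvastatin -> pravastatin factor: {f} (reciprocal {g}; product {f * g})")

f, warnings = conversion_factor("ramipril", "enalapril", kb)
print(f"ramipril -> enalapril without an indication: factor {f}")
for w in warnings:
    print(f"  warning [{w.kind.value}]: {w.message}")
f_ht, _ = conversion_factor("ramipril", "enalapril", kb, "hypertension")
print(f"ramipril -> enalapril for hypertension: factor {f_ht}")
print()

try:
    conversion_factor("felodipine", "nimodipine", kb)
except KBError as e:
    print(f"felodipine -> nimodipine refused: {e}")
    print("(both are C08CA calcium-channel blockers, but their labelled")
    print(" indications do not overlap, so no factor is ever offered)")
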