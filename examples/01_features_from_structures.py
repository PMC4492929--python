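"""Extract the ten scoring features from a WT/MT complex pair.

Builds a toy two-chain complex (partner A mutated S4A), supplies a small
imported energy-components table for the force-field/PB terms, and prints
the assembled feature vector.
"""

import warnings

import ddgbind as dg
from ddgbind.terms import EnergyComponents

case = dg.make_toy_complex(
    {"A": "AKDSG", "B": "GSEKA"},
    mutation=dg.MutationDescriptor("A", 4, "S", "A"),
    gap=12.0, seed=1)
print("case:", case.case_id, "| validation:", dg.validate_case(case) or "clean")

# energies normally come from external minimization / PB runs via
# load_energy_components(); here a hand-written table stands in
energies = EnergyComponents()
rows = {("WT", "AB"): (-120.0, -40.0, -30.0, -55.0),
        ("WT", "A"): (-60.0, -18.0, -14.0, -25.0),
        ("WT", "B"): (-58.0, -17.0, -13.0, -24.0),
        ("MT", "AB"): (-118.0, -39.5, -29.6, -54.4),
        ("MT", "A"): (-59.0, -17.8, -13.8, -24.7),
        ("MT", "B"): (-58.0, -17.0, -13.0, -24.0)}
for (state, part), vals in rows.items():
    for comp, v in zip(("IE", "EE", "VE", "SP"), vals):
        energies.set(state, part, comp, v)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    terms = dg.assemble_terms(case, energies=energies)

for name, value in terms.as_dict().items():
    print(f"  {name:24s} {value:10.4f}   ({terms.provenance.get(name, '-')})")

print("\nEnergy terms are double differences (MT binding minus WT binding,")
print("kcal/mol); interface_mt is the buried MT interface area in A^2; the")
print("entropy, hydrophobicity, H-bond and normalized-SASA terms are")
print("dimensionless structure-derived quantities.")
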