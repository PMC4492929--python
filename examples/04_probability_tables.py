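"""Build effect-probability tables from data and apply the alteration pass.

A mutation causes a "large" effect when |ddG_exp| >= 1 kcal/mol.  Each of
the four flags (WT residue, MT residue, WT/MT site location) gets an
empirical probability of a large effect; an alteration pass reconciles
cases whose flags disagree.
"""

import numpy as np
import pandas as pd

import ddgbind as dg
from ddgbind.surface import LocationClass

rng = np.random.default_rng(0)
aa = list("ACDEFGHIKLMNPQRSTVWY")
locs = [LocationClass.COR, LocationClass.RIM, LocationClass.SUR]
n = 400
records = pd.DataFrame({
    "wt_aa": rng.choice(aa, n), "mt_aa": rng.choice(aa, n),
    "loc_wt": rng.choice(locs, n), "loc_mt": rng.choice(locs, n),
    "abs_ddg": np.abs(rng.normal(1.0, 1.0, n)),
})

initial = dg.build_probability_tables(records)
altered = dg.reweight_tables(records, initial)

print("P(large) by WT-site location, before -> after one alteration pass:")
for loc in locs:
    p0 = initial.wt_location[loc][1]
    p1 = altered.wt_location[loc][1]
    n_loc = initial.wt_location[loc][2]
    print(f"  {loc}: {p0:.2f} -> {p1:.2f}   (n = {n_loc})")

# the worked alteration: flag probabilities (0.2, 0.86, 0.68, 0.56),
# |ddG| = 10 -> the flag-1 altered value is 6.0
print("\nalter_ddg(10, flag 1, (0.2, 0.86, 0.68, 0.56)) =",
      dg.alter_ddg(10.0, 1, (0.2, 0.86, 0.68, 0.56)))
print("With all probabilities at 0.5 the alteration is the identity:",
      dg.alter_ddg(2.4, 3, (0.5, 0.5, 0.5, 0.5)))
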