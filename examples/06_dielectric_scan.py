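"""Scan residue-class dielectric constants for the best correlation.

Charged, polar and other residues carry their own effective dielectric
constants (eps1, eps2, eps3) in the electrostatic terms.  The scan refits
the reduced formula (Coulomb + van der Waals + polar solvation only) on a
grid of dielectric triples and reports the argmax of the training
correlation.  Here the dataset is synthetic with the optimum planted at
the protocol values (9, 8, 7).
"""

import ddgbind as dg

provider, ddg = dg.make_dielectric_scan_problem(n_cases=300, seed=11)
result = dg.scan_dielectrics(provider, ddg,
                             eps2_values=(4, 6, 8, 10, 12, 14))

print("grid shape:", result.r_grid.shape)
print(f"best triple (charged, polar, other): {result.best}  "
      f"with r = {result.best_r:.4f}")
e1 = result.eps1_values.index(result.best[0])
print("\nr over (polar, other) at the best charged epsilon:")
header = "      " + "".join(f"e3={e:<6}" for e in result.eps3_values)
print(header)
for j, e2 in enumerate(result.eps2_values):
    row = "".join(f"{result.r_grid[e1, j, k]:.4f}  "
                  for k in range(len(result.eps3_values)))
    print(f"e2={e2:<3} {row}")

print("\nThe correlation peaks at the planted (9, 8, 7): higher effective")
print("dielectrics for charged and polar residues mimic the conformational")
print("and ionization response a rigid-body model cannot sample.")
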