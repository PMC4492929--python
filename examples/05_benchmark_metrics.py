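"""Benchmark a predictor with the four-outcome flags and six ROC metrics.

A prediction is a called effect when |ddG_calc| >= 1.5 kcal/mol and a
called no-effect when |ddG_calc| < 0.5; the same bands apply to the
experimental value.  Pairs in the middle band, or large pairs of opposite
sign, are excluded as unclassified.
"""

import numpy as np

import ddgbind as dg

rng = np.random.default_rng(4)
exp = rng.normal(0.8, 1.6, size=600)
calc = 0.8 * exp + rng.normal(0, 0.7, size=600)  # an imperfect predictor

counts = dg.ConfusionCounts.from_pairs(calc, exp)
print(f"counts: tp={counts.tp} tn={counts.tn} fp={counts.fp} "
      f"fn={counts.fn}  (unclassified: {counts.n_unclassified} of 600)")

metrics = dg.roc_metrics(counts)
for name, value in metrics.as_dict().items():
    print(f"  {name:12s} {value:.3f}")

print("\nOnly confidently-called pairs enter the counts, so the classified")
print("total is well below the dataset size.  MCC balances all four cells;")
print("1 is perfect agreement, 0 is chance.")
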