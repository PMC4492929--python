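# Methods

## Scope and model

`ddgbind` predicts the change in protein–protein binding free energy
(ΔΔG, kcal/mol; positive = weaker binding) caused by a single point
mutation. It is a **rigid-body** method: the unbound monomer structures are
carved out of the complex with bit-identical coordinates, so no
binding-induced conformational change is modelled explicitly. Every
mutation-sensitive quantity is the double difference

    ΔΔE = (E_AB^MT − E_A^MT − E_B^MT) − (E_AB^WT − E_A^WT − E_B^WT)

and the prediction is a weighted linear combination of ten such terms (see
README). Mutant structures are *inputs*: building a physically sensible
mutant side chain requires a rotamer-modelling tool and energy minimization,
both outside this package's scope. A `naive_mutate` helper (relabel +
truncate to Cβ) exists for fixtures only and is flagged non-physical.

Because the rigid-body picture cannot relax, the electrostatic terms mimic
conformational and ionization response through residue-class dielectric
constants: charged side chains (Asp, Glu, Lys, Arg, His) ε₁ = 9, polar
(Ser, Thr, Asn, Gln, Tyr) ε₂ = 8, everything else ε₃ = 7; the Coulomb term
uses the uniform lowest value ε = 7.

## Term provenance

| term | source | notes |
|---|---|---|
| ΔIE | imported | complexes only: the rigid-body split cancels the full double difference identically (a deliberate, documented inconsistency with standard MM/PBSA) |
| ΔΔEE | imported, or internal fallback | fallback: formal charges (Asp/Glu −1 at carboxylate-O midpoint, Lys +1 at NZ, Arg +1 at CZ, His +1 at ND1/NE2 midpoint), 332.0636·q₁q₂/(εr), pair distance clamped at 1.0 Å, intra-residue pairs excluded, uniform ε = 7. A coarse stand-in for a PB solver's Coulombic energy; imported values always win. |
| ΔΔVE, ΔΔSP | imported only | van der Waals and PB reaction-field energies need a force field / PB solver; absent values are explicit (never silent zeros) and predicting with a weight set that needs them raises an error naming the term |
| ΔΔSN | structure | nonpolar solvation is linear in total SASA; its slope and offset are absorbed by the fitted weight and intercept, so the feature is the raw SASA double difference |
| ΔΔS | structure | S = Σ ln[rSASA·(R−1)+1] with R the maximum rotamer count per residue type; state-appropriate rSASA (complex rSASA in the complex, monomer rSASA in each monomer); rSASA clipped to [0,1] so the log argument stays ≥ 1 |
| ΔΔHYDR | structure | Σ H_j·rSASA_j, Wimley–White H; same clipping |
| ΔHB | structure | net = inter-partner − intra-partner counts; bond = (H, O) pair < 2.4 Å, H not a nonpolar Cα/Cβ hydrogen (names HA*/HB*), both residues polar∪charged, intra-residue and covalent (< 1.2 Å) pairs excluded, N acceptors and angular geometry deliberately ignored. The eligibility filter is applied to *both* residues of a pair; any O atom of an eligible residue (backbone carbonyl included) can accept. Hydrogens are required; an optional heavy-atom proxy (donor N/O within 3.4 Å) is a flagged deviation for hydrogen-free inputs. |
| Interface^MT | structure | buried area SASA_A + SASA_B − SASA_AB, **positive** by convention (the sign-flipped version of "complex minus parts"), so a positive interface weight penalizes large interfaces |
| ΔΔSASA/Interface^MT | structure | defined 0 with a warning when the MT partners do not touch |

## Surface areas and location classes

SASA is Shrake–Rupley quadrature (via biotite) with a deterministic
Fibonacci point set, 960 points/atom default, probe 1.4 Å, Chothia-style
heavy-atom radii (C 1.87, N 1.65, O 1.40, S 1.85 Å); hydrogens never carry
surface. Relative SASA divides by Tien-et-al. theoretical maximum areas
(the upstream protocol's reference values are unpublished; the table is an
explicit argument everywhere). rSASA is not clipped in the surface module
(mild excursions above 1 are real); clipping happens only inside the
entropy/hydrophobicity formulas.

Location classes from monomer/complex rSASA: COR (rSASAm ≥ 25 %, rSASAc
< 25 %, ΔrSASA > 0), SUP (both < 25 %, Δ > 0), RIM (rSASAc ≥ 25 %, Δ > 0),
INT (rSASAc < 25 %, Δ = 0), SUR (rSASAc ≥ 25 %, Δ = 0). Boundary policy:
exactly 0.25 takes the exposed ("> 25 %") branch; |Δ| ≤ 1e-6 counts as
Δ = 0. A residue with Δ < 0 (impossible rigid-body) is reported
UNCLASSIFIABLE rather than silently assigned.

## Classifier

Effect sizes split at |ΔΔG| = 1 kcal/mol (≥ 1 is "large", including exactly
1). Four flags — WT residue type, MT residue type, WT-site and MT-site
location class — each carry an empirical P(large). The alteration pass
reconciles disagreeing flags: for flag dimension i, each case's |ΔΔG| is
rescaled by (2/3)·Σ_{j≠i} p_j (small cases) or (2/3)·Σ_{j≠i}(1−p_j) (large
cases), and dimension i's table is rebuilt from its own altered values in
**one pass** (the upstream description leaves the merge under-specified;
iterating to a fixed point was rejected as unstated). All-0.5 tables are a
fixed point. Undefined rows raise instead of defaulting to 0.5. Prediction
routes on the mean of the four probabilities: P ≥ 0.5 (boundary inclusive)
→ large-effect weights.

The bundled probability tables and the three weight sets (small / large /
all, with per-weight p-values and case counts) are transcriptions of the
published fit on a curated ~1300-case training set; the slope/y-intercept
rows that accompany them have an unexplained role (y-intercept ≡ 1) and are
stored as opaque metadata, never applied.

## Fitting and validation

Weights are ordinary least squares with intercept (statsmodels; QR-based),
p-values from two-sided t tests with n−p−1 degrees of freedom. Rank
deficiency is an error naming the collinear columns. Cross-validation uses
a seeded uniform random k-fold partition (default seed 20150706, fold sizes
differing by ≤ 1). The ±2-SD trim fits experimental ~ predicted once, drops
|residual| > 2·SD(residuals) in a single pass, and re-computes Pearson r; a
numerically perfect fit (SD ≤ 1e-10 × data scale) trims nothing.

The dielectric scan refits the reduced formula (ΔΔEE, ΔΔVE, ΔΔSP only) at
each grid point of (ε₁, ε₂, ε₃) and reports the correlation argmax. Default
ranges are the protocol's (5–15, 3–13, 3–13, step 2). Note an upstream
inconsistency: that polar axis contains odd values only and cannot
represent the protocol optimum ε₂ = 8; the planted-optimum tests therefore
scan an even polar axis 4–14 (still six values). The provider is a callable
`(ε₁, ε₂, ε₃) → feature frame`, so imported per-ε energy tables and the
internal Coulomb can both back it.

## Benchmarking

Predictions are flagged tp / fp / tn / fn using two bands: a called effect
at |ΔΔG| ≥ 1.5 kcal/mol and a called no-effect at |ΔΔG| < 0.5 (both axes);
tp additionally requires matching signs, with the sign of 0 positive.
Pairs in the middle band or sign-mismatched large pairs are excluded as
unclassified — which is why benchmark totals sit well below dataset sizes.
Six metrics follow; MCC uses the conventional numerator tp·tn − fp·fn (the
upstream text prints a "+" there, which contradicts its own reported MCC
values; the conventional form reproduces them exactly). Metrics with zero
denominators are None, never 0.

## Dataset curation

Within each (pdb, chain, site, insertion code, WT, MT) group: exact
duplicates collapse; spread (max − min) < 1.5 kcal/mol fuses to the mean;
spread ≥ 1.5 deletes the group (the boundary is assigned to deletion —
the upstream rule states both "< 1.5 fuse" and "> 1.5 delete" and is silent
at exactly 1.5). Disordered-site rows are removed. Every action lands in an
audit log; curation is idempotent.

## Synthetic data

`make_toy_complex` builds schematic complexes from idealized residue
templates: chains along x, residues 3.8 Å apart, side chains pointing at
the partner across a configurable gap, polar hydrogens on donor atoms, and
optional exact-distance hydrogen-bond planting. Per-residue jitter comes
from a seed-derived RNG keyed by (seed, chain, site), so WT and MT share
every off-site coordinate bit-for-bit. These structures are substrates for
surface/H-bond/Coulomb arithmetic — they have no real backbone dihedrals,
rotamers or packing, so green structure tests establish the *arithmetic*,
not predictive accuracy on real complexes.

`simulate_dataset` draws independent Gaussian features (spreads chosen once
to match each term's typical magnitude in the fitted formula: energies of a
few kcal/mol, entropy ~1.5, interface 1600 ± 400 Å², normalized SASA
~0.03) and generates ΔΔG = w₀ + w·x + N(0, σ), default σ = 0.5 kcal/mol.
The analytic check r = √(Vₛ/(Vₛ+σ²)) with Vₛ = Σ(w_k·sd_k)² holds because
features are independent. The dielectric-scan generator gives each term
latent per-class magnitudes plus an ε-independent component
(a/ε₁ + b/ε₂ + c/ε₃ + d); without d, proportional ε-triples span the same
OLS subspace and the correlation grid has a flat ridge instead of a peak.

## Numerical choices and limitations

- Altloc resolution: highest occupancy, first-in-file on ties; waters are
  always removed (counted, not modelled); non-canonical polymer residues
  are rejected because every constant table covers exactly the 20 types.
- SASA determinism: fixed point count (960 default) and a deterministic
  point set; tests compare against an independent 10,000-point quadrature
  at 2 %.
- The internal Coulomb fallback is qualitative: no PB reaction field, no
  multi-dielectric boundaries, formal charges only. Any serious use should
  import solver energies.
- No structure repair, protonation assignment, mmCIF input, or
  symmetry-mate generation; the chains in the input file are the complex.
- The bundled weights were fitted upstream against experimental data whose
  energy components this package does not recompute; reproducing the
  published training correlation therefore requires those external inputs
  and is out of scope — the tests validate the machinery on simulated data
  with known ground truth instead.
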