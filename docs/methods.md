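# Methods

## Model system and data

The model set is glycylglycine methyl ester (GGMe) and nine derivatives
carrying *tert*-butyl groups at up to three sites: the N-terminal amino
nitrogen (R1), the N-terminal α-carbon (R2, always *S* when substituted)
and the C-terminal α-carbon (R3, *S* by default, *R* when the code carries
a prime). The four-character code `N<d1><d2><d3>0` encodes the pattern; the
trailing digit is the fixed methyl ester. Parsing accepts both the ASCII
apostrophe and the typographic prime (both occur in published material) and
canonicalizes to ASCII.

All energies are kcal/mol. The packaged reference data are published
B3LYP results shipped verbatim as tab-separated text (one file per printed
table, cells keeping thousands separators and the typographic minus; the
loader normalizes both). Blank and "ND" (not determined) cells map to an
explicit missing value, never 0. A hartree→kcal/mol constant
(627.5094740631) is provided for ingesting raw QM output, but the only
structure format parsed is plain XYZ.

One quirk of the reference data is carried as-is: the water-phase trans
block sits on a different absolute energy scale than the other three
(isomer, phase) blocks (its N0000 base is ≈ −381,812 vs ≈ −333,806
kcal/mol). The additivity model therefore keeps a separate base energy per
block and never mixes blocks; water-phase cis-minus-trans energies are
taken from the published relative-energy column rather than recomputed
across the mismatched scales. Gas-phase relative energies are recomputed
from the optimized energies and cross-checked against the printed column.
The water-phase cis solvation energies are printed with the relative-energy
table, so the dataset loader joins them onto the cis water conformer
records by compound code.

## Additivity analysis

Increments: E_tb^N = E(*tert*-butylamine) − E(ammonia), E_tb^C =
E(neopentane) − E(methane), per phase. Additive estimate: AddE =
optE(N0000, isomer, phase) + n_N·E_tb^N + n_C·E_tb^C with n_N ∈ {0,1},
n_C ∈ {0,1,2} from the compound code (chirality does not affect counts).
Steric energy: stE = optE − AddE. The prose definition of the steric
effect ("the difference between AddE and optE") leaves the sign open; the
convention here makes strain positive, consistent with every published
value. Machine-precision values are kept internally; the display helper
rounds to 3 decimals as in the published tables, and tests compare at
±0.001 kcal/mol.

## Geometry

Torsions use the IUPAC sign convention, range (−180°, 180°] with +180
preferred over −180 (matching the "−179.7 / 178.3" style of the reference
dihedral tables), computed with the atan2 formulation. The IUPAC torsion is
invariant under rigid motion *and under full reversal of the point order*;
mirror reflection negates it. Both properties are asserted in the tests,
with an independently coded projection-based oracle (and MDAnalysis as an
external cross-check during development).

Planarity: deviation of ω from the nearer of 0° and 180°, so one rule
serves cis and trans rows; distorted when the deviation exceeds 5°
(configurable). H-bond: distance-only criterion on the amino-N···amide-H
distance, present when ≤ 2.3 Å, inclusive at the boundary — the criterion
is defined by absence strictly above the cutoff. No angular term is used.

Superposition is a least-squares rigid fit (scipy's proper-rotation
Kabsch); reflections are forbidden so chirality is preserved, and
degenerate (collinear, < 3 pairs) alignment sets are rejected. Exact atom
quadruples for ψᴺ/φᶜ/ψᶜ depend on atom naming in the source structures, so
the atom map is user input; the synthetic fragment builder documents the
standard peptide convention used as default.

## Scan driver

The relaxed-coordinate-scan driver treats the energy backend as a 1-D
function E(ω): geometry relaxation at fixed ω is the backend's
responsibility. This keeps the driver testable against analytic potentials
and correct over any future constrained-optimization backend.

Each scan covers exactly 180° of arc from a minimum-energy conformer
towards the opposite isomer, in rounds: a 15° coarse sweep, then
re-scans of ± one previous-round step around the incumbent maximum at 2°
and finally 0.125° (0.25° for the water schedule). The published protocol
fixes the step sizes but not the refinement window; ± one previous step is
the narrowest window that always brackets the incumbent peak, and because
the window contains the incumbent point, refinement can only raise the
barrier estimate. Windows are clamped to the scanned arc. The start point
must be a local minimum within one coarse step; flat or boundary-peaked
profiles are errors rather than silent barriers.

The barrier (EBG) is the profile argmax, classified syn/anti by angular
proximity to ±60° vs ±120°; the exact tie at |ω*| = 90° is classified syn
with an explicit ambiguity flag (keeping batch runs alive) rather than an
error. In the full protocol, trans-start scans supply the syn± entries and
cis-start scans the anti± entries; for compounds with unsubstituted
α-carbons only one direction is scanned and the mirror entries are marked
absent, mirroring the symmetry argument in the reference tables. Cis-start
barrier heights are additionally re-referenced to the trans minimum,
assuming the two backends share one absolute energy scale. Reverse-scan
hysteresis is not assumed: syn entries come only from trans starts and anti
entries only from cis starts.

The effective barrier ΔG_eff is the minimum Gibbs barrier over present
entries; ties resolve to the canonically first key (anti before syn, +
before −), which does not affect the value.

## Synthetic generators

Torsional potentials are Fourier sums E(ω) = offset + Σ V_k/2·(1 −
cos k(ω − γ_k)) with at least one k ≥ 2 term, giving 360°-periodic
double wells near 0/180°. The dense-grid oracle uses a 0.001° grid with
local quadratic refinement — an order of magnitude below the finest scan
step, so oracle error is negligible in comparisons; it requires exactly two
minima per period and reports well positions plus the four directional
barriers with start-referenced and trans-referenced heights. The random
battery draws a dominant 2-fold term (V ~ U(8,16) kcal/mol) with weak
1- and 3-fold perturbations: wells stay near 0/180° and the ± barriers
differ, as in the substituted compounds.

Synthetic energy tables inject non-negative steric offsets (half-normal,
scale 4 kcal/mol by default — spanning the 0.7–16.5 kcal/mol range of the
reference tables) on top of an exact additive baseline; the default base
energies and increments are the reference values, so generated tables look
like the real ones. The reference compound never carries an offset. Because
construction is exactly additive plus offset, the steric analysis must
recover the offsets to machine precision — a sharp recovery test, not a
statistical one.

Backbone fragments are built by internal-coordinate (NeRF) placement of a
10-atom dipeptide-ester skeleton (N1, CA1, C1, N2, CA2, C2, O-ester, C-methyl,
plus the carbonyl O and amide H) with fixed canonical bond lengths
(C–N 1.33 Å amide, N–CA 1.47 Å, C–C 1.52 Å, C=O 1.23 Å, N–H 1.01 Å,
ester C–O 1.34 Å / O–C 1.44 Å) and 120°/109.5° angles; only the four named
dihedrals vary. These fragments exercise the torsion code (round-trip
within 1e−6°); they are not energetic or sterically realistic models, so
passing geometry tests says nothing about conformational energetics of
real structures.

## What the synthetic tests do and do not show

Analytic 1-D potentials have no relaxation hysteresis: a trans-start and a
cis-start scan of the same backend find the same maxima. The hysteresis
seen in real relaxed scans (syn barriers from trans starts, anti from cis
starts) is emulated by giving the two starts *different* backends; the test
battery includes such a pair where the effective barrier crosses a syn
geometry, the situation observed for one compound in water. Passing these
tests validates the driver's search, refinement and bookkeeping — not any
claim about real multidimensional energy surfaces.

## Numerical choices

- Steric-table and increment comparisons: ±0.001 kcal/mol (printed
  precision). Gas-phase relative energies: ±0.005 kcal/mol, with a 1e−9
  guard for the one compound that lands exactly on the boundary in decimal
  arithmetic.
- Scan acceptance: barrier position within one final step (0.125°), height
  within 0.01 kcal/mol of the dense-grid oracle; evaluation count bounded
  by the coarse sweep plus two bracketing windows (≈ 110 points), which the
  driver meets with ~60–70 evaluations per scan.
- Collinearity guards: cross-product norms (torsions), matrix rank
  (superposition); degenerate inputs raise typed errors.
- Problem sizes: the scan battery uses 20 random potentials × 4
  directional scans; the dense oracle grid is 360,000 points per potential.
- Two-state equilibrium fractions use R = 1.987204e−3 kcal/(mol·K) and a
  numerically stable logistic form.

## Known limitations

- No QM or force-field energies are computed anywhere; every energetic
  statement is conditional on the supplied tables or synthetic surfaces.
- The scan driver is strictly 1-D in ω; no (ω × ψ) surfaces, no
  transition-state eigenvector verification (EBGs are barrier proxies).
- No nitrogen-pyramidalization measures; the H-bond criterion has no
  angular term; atom maps are not inferred from connectivity.
- The additivity model covers tert-butyl increments only and uses single
  minimum-energy conformers, not conformational averages.
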