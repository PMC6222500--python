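# amideiso

Steric effects and cis/trans isomerization of secondary amides, analysed on a
dipeptide-ester model system.

Rotation about the amide C–N bond interconverts the planar trans (ω ≈ 180°)
and cis (ω ≈ 0°) forms of a secondary amide. Bulky substituents near the
amide change both sides of this equilibrium: they destabilize the cis isomer
and raise the rotation barrier. `amideiso` packages the analysis layer of a
DFT study of this effect on glycylglycine methyl ester (GGMe) and its nine
*tert*-butyl-substituted derivatives (codes `N0000` … `N111'0`, one digit per
substitution site, a prime marking the unnatural *R* configuration at the
C-terminal α-carbon). Quantum chemistry itself is out of scope: optimized
energies enter as data (the published tables ship with the package as TSV),
or from synthetic analytic energy surfaces with known ground truth.

It is aimed at computational/medicinal chemists who want to reuse the
analysis: group-additivity strain accounting, barrier bookkeeping, backbone
geometry checks, or the scan driver over their own energy backends.

## What it computes

**Group-additivity steric energies.** The additive estimate of a substituted
compound is

    AddE = optE(N0000) + n_N·E_tb^N + n_C·E_tb^C

where the increments are small-molecule energy differences
(E_tb^N = E(*t*-BuNH₂) − E(NH₃); E_tb^C = E(neopentane) − E(CH₄)), per phase
(gas / water continuum). The steric energy is the excess of the directly
optimized energy over the estimate, `stE = optE − AddE` (strain is
positive). Each (isomer, phase) block carries its own N0000 base energy.

**Isomer energetics.** Cis-minus-trans relative energies ΔE/ΔG, solvation
shifts, a two-state equilibrium cis fraction, and the effective rotation
barrier ΔG_eff = min over the four directional barriers (syn ±, anti ±),
with "not determined" entries of symmetric compounds skipped.

**Geometry analytics.** IUPAC backbone torsions (ψᴺ, ω, φᶜ, ψᶜ) from
Cartesian coordinates, amide planarity (deviation of ω from the nearer of
0/180°, distorted beyond 5°), a distance-only N···H hydrogen-bond criterion
(≤ 2.3 Å), chirality-preserving least-squares superposition, and
inter-group contact distances.

**Relaxed-coordinate-scan driver.** Directional ω sweeps in three rounds of
decreasing step (15° / 2° / 0.125°, final round 0.25° in water) against a
pluggable 1-D energy backend; locates the energy-barrier geometry (EBG) and
classifies it syn (near ±60°) or anti (near ±120°).

**Synthetic data.** Fourier double-well torsional potentials with a
dense-grid oracle, additive energy tables with injected steric offsets, and
idealized backbone fragments with prescribed dihedrals — ground-truth-known
inputs for every stage.

## Worked example

```python
from amideiso import datasets, steric_table, effective_barrier

model = datasets.build_model()              # increments re-derived from data
records = datasets.conformer_records("trans", "gas")
table = steric_table(records, model)
row = table[("N1110", "trans", "gas")]
print(f"AddE = {row.add_e:.3f}  stE = {row.st_e:.3f}")

entries, _ = datasets.barrier_entries("water")["N011'0"]
summary = effective_barrier(entries, "N011'0", "water")
print(f"dG_eff = {summary.dg_eff}  via {summary.argmin}")
```

prints

```
AddE = -629939.470  stE = 7.155
dG_eff = 18.55  via ('syn', '+')
```

i.e. the fully substituted trans compound in the gas phase carries
7.155 kcal/mol of steric strain beyond the additive estimate, and for
`N011'0` in water the easiest rotation path crosses a *syn* barrier
geometry at 18.55 kcal/mol — the one compound whose effective barrier is
not an *anti* path.

The same analyses are available from a thin CLI:

```bash
amideiso steric --isomer trans --phase gas
amideiso barriers --phase water
amideiso scan --potential pot.yaml --start trans --direction both
amideiso geometry --xyz fragment.xyz --atom-map map.yaml
```

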