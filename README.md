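# picomd

A compact molecular dynamics engine for studying the algorithms that make
all-atom biomolecular simulation fast on a single CPU: mixed single/multiple
time-step integration, a tuned LINCS constraint solver that also constrains
hydrogen angles, grid neighbor search fused with the nonbonded force pass
(with reusable "sloppy" pair lists), smooth particle-mesh Ewald
electrostatics, and pressure coupling via either the classic virial barostat
or a water-density densostat.

It is written for method developers and students who want working,
test-covered reference implementations of these algorithms on synthetic
systems (water boxes, small molecules, capped amino acids) — not as a
production force-field package.

## The core ideas

**Mixed time stepping.**  Molecules whose internal degrees of freedom are
fully removed by constraints (rigid waters, ions) advance with one large
step (5 fs) under nonbonded forces only.  Flexible molecules integrate
bonded forces with a 2.5 fs step and receive the nonbonded forces *doubled*
on every other step (the impulse / Verlet-I recipe), in sync with the large
step.

**Hydrogen-angle constraints with LINCS.**  Constraining the angle A–B–C
means fixing the A–C distance to
√(AB² + BC² − 2·AB·BC·cos∠ABC).  LINCS inverts the constraint coupling
matrix by the power series (1−A)⁻¹ ≈ 1 + A + … + A⁸, valid while all
|eigenvalues| of the zero-diagonal matrix A = I − S·B·M⁻¹·Bᵀ·S stay below 1.
Because heavy-atom bonds are left unconstrained, a selection heuristic can
give every hydrogen one or two angle constraints while keeping all coupled
groups inside that gate — except a heavy atom carrying three hydrogens
(–CH₃, –NH₃⁺), whose six constraints form a tetrahedron with max|λ| ≈ 1.37;
those groups are flagged and solved by inverting the 6×6 matrix exactly.
Waters use the analytic SETTLE solution.

**Sloppy pair lists.**  The grid search (cube spacing cutoff/3, corner-
pruned 311-offset pattern) runs fused with the force loop and can store a
pair list out to an enlarged cutoff on the fly, reused for several steps:

    cutoff_pairlist = cutoff_force + √(N−1) · dt · T · 0.001 / M

with N the update frequency and M the mean particle mass (waters count as
one particle).

**Densostat.**  Instead of the virial, the pressure signal is the bulk
water density measured over grid cubes whose entire neighborhood is
water-only, averaged over 50 measurements taken every 10 steps, driving a
weak-coupling rescale S = max(0.999, min(1.001, 1 + C·(ρ/ρ₀ − 1)/3)).

## Worked example

Inspect the constraint machinery on ethane — two methyl groups, each a
flagged tetrahedron solved by exact inversion:

```sh
$ picomd constraints-report test:ethane
 group  n_constraints   atoms                                   targets  max_abs_eigenvalue    solver
     0              6 0,2,3,4 1.0941,1.0941,1.0941,1.7742,1.7742,1.7742              1.3607 exact-6x6
     1              6 1,5,6,7 1.0941,1.0941,1.0941,1.7742,1.7742,1.7742              1.3607 exact-6x6
```

Each methyl carries three C–H bond constraints (1.094 Å) plus the three
H–H distances (1.774 Å) that freeze the H–C–H angles; the coupling-matrix
spectrum (1.36 > 1) shows why the series inversion cannot be used there.

Run a short water-box simulation from a YAML config:

```yaml
# run.yaml
system: water_box
n_per_edge: 3
cutoff: 4.5
coupling_mode: NVT
temperature: 298.0
duration_fs: 1000.0
seed: 7
energy_csv: energy.csv
```

```sh
$ picomd run run.yaml
completed 200 steps to t = 1000.0 fs
final T = 332.3 K, E_total = -812.37 kJ/mol
```

(1 ps of weak-coupling equilibration from a fresh lattice: the temperature
is still settling toward 298 K while packing strain relaxes.)

The energy CSV has one row per 5 fs step (time, kinetic, potential and its
components, temperature, virial); `picomd drift --dof 159 energy.csv` fits
the conserved-energy slope in kB·T/ns per degree of freedom, the standard
integrator-quality diagnostic.  Other subcommands: `rama` (72×72 φ/ψ
free-energy map via Boltzmann inversion, 4 kJ/mol contour levels),
`bfactors` (B = 8π²/3 · ⟨|r−⟨r⟩|²⟩ after least-squares superposition), and
`make-fixture` (write synthetic systems as PDB).

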