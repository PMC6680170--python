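# Methods

`picomd` is a compact, single-threaded molecular dynamics engine built
around four acceleration ideas for all-atom simulations of biomolecules in
water: a mixed single/multiple time-step integrator, a tuned LINCS
constraint solver that also constrains hydrogen *angles*, a grid neighbor
search fused with the nonbonded force pass (optionally storing reusable
"sloppy" pair lists), and pressure coupling through either the classic
virial barostat or a water-density "densostat" that avoids the virial
entirely.  This note records the model, the numerical choices, and what the
synthetic test systems do and do not probe.

Units throughout: Å, fs, Dalton, kJ/mol, Kelvin, elementary charges;
kB = 0.00831446 kJ/(mol·K), e²/(4πε₀) = 1389.35458 kJ·Å/mol.

## Mixed multiple time-step integration

Hydrogen vibrations limit the usable time step: bond stretches destabilize
leap-frog integration beyond roughly 1.75 fs, hydrogen angles around
2.5 fs.  Two standard remedies are combined:

* **Rigid molecules step once.**  A molecule whose internal degrees of
  freedom are all removed by constraints (rigid 3-site waters, monoatomic
  ions, fully constrained small molecules: 3N − Nc − 6 ≤ 0, with 5/3
  external degrees of freedom for diatomics/atoms) advances with one large
  step (default 5 fs) under nonbonded forces only — its bonded terms sit
  at equilibrium by construction and contribute zero force.
* **Flexible molecules use the impulse scheme.**  Bonded intra-actions are
  integrated with the small step (default 2.5 fs); nonbonded forces are
  applied *doubled* on every other small step, in sync with the large step,
  and omitted in between (Verlet-I/impulse flavor of multiple time
  stepping).  There are no distance classes: all nonbonded interactions
  share the large step.

The propagator is kick-drift leap-frog.  Constraints receive the old
positions plus the proposed *steps*; corrected steps divided by the step
length define the new half-step velocities, so velocities and positions
remain exactly consistent with the constraint manifold.  The conserved
energy is bookkept as the potential at the synchronization points plus the
mean of the two adjacent half-step kinetic energies (the standard leap-frog
convention).  A "single-precision emulation" switch rounds positions and
steps to 32-bit floats after every update; the step (delta) formulation of
the constraint solvers exists precisely so this mode does not accumulate
round-off (verified over 10⁴ constraint applications far from the origin).

Degrees of freedom are counted as 3N − Nc − 3, subtracting the three
conserved components of total linear momentum; drift and temperature both
use this count.

## Constraints

All bonds involving hydrogens are constrained.  Bonds between heavy atoms
are deliberately **not** constrained — the small bonded step handles them —
which keeps the constraint coupling matrix sparse enough that selected
hydrogen angles can be constrained too (as A–C distances via the law of
cosines from the equilibrium bond lengths and angle).

**Selection heuristic.**  A recursive routine assigns angle constraints by
hydrogen count: four hydrogens (methane-like) get two constraints over
disjoint pairs; three hydrogens (–CH3/–NH3⁺) get the full H–H triangle;
sp3 CH2 groups couple both hydrogens to the best-scored *next* heavy atom
(preferring to walk along CH2 chains); sp2 =CH2 couples its two hydrogens
directly; a single hydrogen gets one constraint to the best-scored heavy
neighbor.  sp3/sp2 classification is purely by bond count (> 3 bonds ⇒
sp3).  The driver visits atoms in six phases (methyl-like first, then
hydroxyl/thiol, then CH2 chains seeded next to CH groups, the remaining
CH2 chains, CH chains/rings, then the rest), each atom once, in ascending
atom id; ties among equal scores go to the lowest atom id.  A hydrogen
whose only heavy neighbor carries three hydrogens (methanol's hydroxyl)
legitimately gets no angle constraint.  The scoring can occasionally prefer
the adjacent backbone carbonyl over a crowded CA for an amide hydrogen, so
constraint groups may bridge one peptide bond; they never extend further
along the chain.

**Coupling matrix and the eigenvalue gate.**  With constraint gradients B
(rows: ± unit direction at the two atoms) and S = diag(1/√(1/mₐ+1/m_b)),
the zero-diagonal simplified coupling matrix is A = I − S B M⁻¹ Bᵀ S.
The truncated series (1−A)⁻¹ ≈ 1 + A + … + A^order converges only while
every |eigenvalue| < 1.  Directions are taken from the equilibrium
geometry: the spectrum is treated as a topology property, not a
per-configuration quantity.  For every group the selection produces on the
20 amino acids and the fixture molecules, max|λ| stays below 1 — except
the three-hydrogen tetrahedron (3 bonds + 3 angle distances), whose
largest |λ| ≈ 1.37.  That group is flagged and solved by inverting the
6×6 matrix (1−A) exactly; the same inverse serves the initial projection
and every rotational correction.

**LINCS (step formulation).**  The initial projection solves
(1−A) y = S·(u·Δp + l_old − d₀) and distributes −M⁻¹BᵀSy over the steps.
Rotational-lengthening corrections then re-project to the target length:
with proj = u·r and the perpendicular component ⊥² = l² − proj², the
correction target is p = √(d₀² − ⊥²).  This equals the classic
√(2d₀² − l²) to leading order (where proj ≈ d₀) but uses the actual
perpendicular component, which makes repeated corrections contract
monotonically at the series-truncation rate λ^(order+1) per pass instead
of oscillating.  Defaults: expansion order 8, three corrections,
tolerance 1e-6 relative (1e-4 in single-precision emulation) — reached
for MD-step-scale violations (~1e-3 relative).

**SETTLE.**  Rigid 3-site waters bypass LINCS entirely and use the
analytic (non-iterative) rigid-triangle solution, vectorized across all
waters: canonical triangle in a frame built from the old plane normal and
the new oxygen–center-of-mass axis, rotation angles φ, ψ, θ solved in
closed form.  Distances are exact to machine precision and the center of
mass is preserved, so momentum conservation is exact.  Degenerate
(collinear) inputs fall back to an iterative solve and are logged.  SETTLE
and a tightly converged iterative solver agree to O(Δ²) in the step size —
about 1e-6 Å at realistic MD steps; they are *different* projections
(SETTLE preserves angular momentum), so exact agreement is not expected.

## Neighbor search and sloppy pair lists

Atoms are binned into a grid of parallelepiped cubes with target spacing
cutoff/3 below 9.5 Å and cutoff/4 at and above (the boundary value is
assigned to the /4 branch).  The search volume around a cube is a
(2k+1)³ block from which geometrically unreachable cubes are pruned: an
offset is dropped when the minimum distance between the two cubes — an
exact box-constrained least squares over the parallelepiped geometry,
valid for triclinic cells — reaches the cutoff.  Pair inclusion is strict
(r < cutoff), so pruning at exactly the cutoff is lossless.  In the
canonical cutoff/3 case this removes 4 cubes from each of the 8 corners:
343 − 32 = 311 offsets.  Patterns are precomputed and cached per cell
shape; periodic wrapping happens in cube-index space, and each unordered
pair is enumerated once via the forward half of the pattern (offsets that
alias their own reverse on small grids get an i<j filter).  Cells thinner
than twice the cutoff along any axis are rejected rather than silently
violating the minimum-image convention.

The search runs every step, fused with the force pass; a pair list out to
a larger cutoff can be stored on the fly at no extra search cost and
reused for a fixed number of steps, accepting transiently missed
interactions.  The pair-list cutoff follows a random-walk estimate:
cutoff_force + √(update_frequency − 1) × time_step × temperature ×
0.001/M, with M the mean particle mass (waters count as single particles,
as do ions) and 0.001 Å·Da/(K·fs) the empirical constant.  A stale list
(age ≥ update frequency) is a hard error.

## Forces

Functional forms are conventional: harmonic bonds and angles
(0.5·k·x² convention), periodic cosine dihedrals k(1+cos(nφ−γ)), 12-6
Lennard-Jones with Lorentz–Berthelot combination, 1-4 scaling 1/1.2
(electrostatics) and 1/2 (LJ), and Ewald electrostatics: erfc-damped
real space truncated at the cutoff (no switching — truncation is handled
by pair selection) plus smooth particle-mesh reciprocal space with
fourth-order B-splines.  β is chosen so erfc(β·cutoff) = 1e-5; the mesh
spacing is min(0.9 Å, 0.3/β) — the stricter bound keeps the spline force
interpolation artifact, which decays more slowly than the energy error,
negligible.  The B-spline forces are the exact gradient of the mesh
energy; the small spurious net force inherent to the interpolation is
subtracted so momentum is conserved exactly.  Excluded (1-2/1-3) and 1-4
pairs get the −erf(βr)/r reciprocal-space removal.  Non-neutral systems
are rejected unless the uniform-background correction is explicitly
enabled.

Four linear-interpolation lookup tables are provided (PME damping factor
vs distance, and complete O–O / O–H / H–H water–water forces with the
water model's charges and intra-water exclusions baked in); solute LJ is
always evaluated explicitly.  At the default 4096 points/Å the
interpolation error in the physically sampled range is a few 1e-6
relative.  The integration engine evaluates the exact functions in double
precision — the tables are the documented fast path, not a prerequisite.

Instantaneous pressure uses the Clausius virial, P = 2/(3V)·(KE + ½Σr·f),
with Σr·f accumulated pairwise over minimum-image vectors (the
image-consistent form).  The reciprocal-space contribution is obtained
from −3·dU/dlnV by central finite difference of the mesh energy under
isotropic scaling; pair terms are analytic.

## Pressure coupling

**Densostat.**  All cubes of the ~2.6 Å neighbor grid whose 27-cube
neighborhood contains water and no solute atom are tagged (a 57-cube
exclusion environment is available behind a switch; cubes with no water
anywhere in their neighborhood — vacuum — are never tagged, so they cannot
dilute the density).  Water mass in tagged cubes over tagged volume is the
current water density; it is measured every 10 steps and averaged over a
ring buffer of 50 measurements before use, so fluctuations are not
artificially suppressed.  The cell and coordinates are then rescaled by
S = max(0.999, min(1.001, 1 + C·(ρ_meas/ρ_set − 1)/3)).  The /3 is the
first-order cube root converting a relative density error into a linear
scale factor; the alternative cubed-error reading of the ambiguous
formula is implemented behind a flag but responds negligibly to realistic
errors.  The clamp guarantees no single rescale changes the cell by more
than 0.1% (larger jumps heat the system through scaled bond lengths;
constraints re-idealize the geometry on the next step).  The default
coupling strength C = 0.05 comes from loop stability: the ring-buffer
average lags the cell by up to 500 steps, so the per-event gain C/3 times
the ~25 lagged events must stay below one — stronger couplings oscillate
between the clamps instead of converging.  Coordinates — not molecule
centers — are scaled.  With no usable water cubes the
densostat reports insufficient solvent and makes no update.

**Barostat.**  The Berendsen factor μ = [1 − κ·dt/τ·(P₀ − P̄)]^{1/3} per
axis, fed with the *time-averaged* virial pressure (same ring-buffer
idea), clamped to the same 0.1% per-step limit; isotropic mode applies the
trace average to all axes, anisotropic mode lets each axis respond to its
own diagonal component (membranes/crystals, where a scalar density cannot
express the pressure and the densostat must not be used).

## Synthetic systems

The generator provides (i) cubic-lattice boxes of rigid TIP3P-like waters
(O–H 0.9572 Å, H–O–H 104.52°, q_O = −0.834, σ_O = 3.15061 Å,
ε_O = 0.6364 kJ/mol — the water model is configurable since no specific
model is mandated for the reference numbers) at a requested mass density
with random orientations and Maxwell–Boltzmann velocities, bit-reproducible
per seed; and (ii) small molecules covering every hydrogen configuration
the selection heuristic distinguishes (methane, methanol, ethane, ethanol,
ammonium, ethene, an N-propyl-guanidinium arginine side-chain analog, the
capped alanine dipeptide with its two backbone torsions annotated), plus
all 20 amino acids as ACE-X-NME capped residues.  Molecular geometries
come from a deterministic distance-geometry embedding refined with MMFF;
the equilibrium value of every bond and angle term is *defined* as its
value in that relaxed geometry, so "all bonded terms at equilibrium" holds
exactly by construction.  Stiffnesses are generic (2800 kJ/mol/Å² bonds,
420 kJ/mol/rad² angles, 4 kJ/mol 3-fold torsions); fixture molecules carry
zero partial charges.

What these fixtures do *not* emulate: real force-field charge sets and
torsion profiles, protein-scale systems, heterogeneous solvents, and long
(multi-ns) time scales.  Passing tests demonstrate the correctness of the
algorithms (constraint spectra, pair enumeration, Ewald sums, integrator
conservation, coupling control loops) at desk scale, not force-field
accuracy against experiment.

## Study conditions for the expensive checks

* **Energy drift:** 216-water box at 0.997 g/ml, 8 Å cutoff, PME, mixed
  5/2.5 fs protocol with constraints; 3 ps weak-coupling equilibration at
  298 K, then 20 ps NVE; drift = least-squares slope of the conserved
  energy in kB·T per ns per degree of freedom (1293 here), sign preserved.
  Sloppy pair lists use update frequency 10 with the random-walk cutoff
  (8.25 Å for pure water, M = 18.015 Da).
* **Densostat convergence:** the same box built 3.7% too dilute
  (0.96 g/ml), NVT plus densostat targeting 0.997 g/ml, 25 ps; the
  50-measurement average must end within 0.5% of target.
* Reference eigenvalues (1.37 for the tetrahedron, 0.82 for methane) use
  ideal tetrahedral geometry and masses 12.011/1.008; the values shift by
  less than 0.02 for plausible equilibrium-angle variations (e.g. 1.349
  at a 106.4° H–X–H angle), which is why a ±0.02 band is quoted.

## Known limitations

* **Sloppy pair lists are atom-granular.**  The random-walk buffer of the
  pair-list formula models particle *translation* (waters counted as
  single particles), but the stored list holds atom pairs: hydrogens of
  rotating rigid waters swing several times farther than the molecular
  center within a 10-step reuse window, so hydrogen-involving pairs churn
  in and out of the cutoff faster than the buffer anticipates.  On a
  216-water box this produces a reproducible conserved-energy drift of
  roughly +0.08 kB·T/ns/DOF with reused lists (exact per-step lists:
  |drift| < 0.03).  A molecule-granular list would remove the churn but
  switches whole 9-site interaction blocks at the O–O cutoff, which at
  this small system size makes even the exact-list drift noticeably
  noisier, and guaranteed site coverage would need list radii beyond the
  minimum-image limit of a 216-water cell.  Users who need tight NVE
  conservation at desk scale should update the pair list every step.
* No virtual/dummy sites, no hydrogen-mass repartitioning.
* Residue connectivity on PDB input comes from the bundled
  chemical-component templates or CONECT records only; there is no
  distance-based bond perception, and PDB-loaded systems get generic
  bonded parameters and zero solute charges (the engine is not a
  force-field distribution).
* Single-threaded throughout; the cube-ordered atom layout exists for
  correctness parity with cache-aware layouts, not for speed.
* The densostat requires bulk water; mixed solvents need a measured
  reference density, and anisotropic systems must use the barostat.
* Dispersion (long-range LJ) corrections beyond the cutoff are not
  applied.
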