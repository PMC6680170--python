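"""Mixed single/multiple time-step leap-frog integration.

Molecules whose internal degrees of freedom are fully removed by constraints
(rigid waters, monoatomic ions, fully constrained small molecules) advance
with one large step per cycle under nonbonded forces only — their bonded
terms sit exactly at equilibrium and contribute zero force.  All other
molecules use the impulse (Verlet-I) recipe: bonded intra-actions are
integrated with the small step (default 2.5 fs) and the nonbonded forces are
added, doubled, on every other small step, in sync with the large step
(default 5 fs).  There are no distance classes: all nonbonded forces share
the large time step.

The propagator is leap-frog.  Constraints receive the old positions and the
position *steps*; corrected steps define the constrained half-step
velocities, so constraint corrections and velocities stay exactly
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constraints as _constraints
from .forces import kinetic_energy
from .system import IntegrationClass, classify_molecules, \
    count_degrees_of_freedom
from .units import ACC_FACTOR, KB


@dataclass
class StepSchedule:
    """Time-step layout of the mixed scheme (fs)."""

    dt_intra: float = 2.5
    dt_inter: float = 5.0
    nonbonded_scale_on_even_step: float = 2.0

    def __post_init__(self):
        if abs(self.dt_inter - 2.0 * self.dt_intra) > 1e-12:
            raise ValueError("dt_inter must equal 2 × dt_intra")


@dataclass
class ThermostatState:
    """Weak-coupling (Berendsen) thermostat fed with time-averaged T."""

    target_temperature: float = 298.0
    coupling_time: float = 100.0      # fs
    enabled: bool = True
    window: int = 25
    _history: list = field(default_factory=list)

    def record(self, temperature: float):
        self._history.append(temperature)
        if len(self._history) > self.window:
            self._history.pop(0)

    @property
    def averaged_temperature(self) -> float:
        if not self._history:
            return self.target_temperature
        return float(np.mean(self._history))


def berendsen_lambda(thermo: ThermostatState, dt: float) -> float:
    """Velocity scaling λ = sqrt(1 + dt/τ·(T_target/T_avg − 1))."""
    t_avg = thermo.averaged_temperature
    if t_avg <= 0:
        return 1.0
    lam2 = 1.0 + dt / thermo.coupling_time * (
        thermo.target_temperature / t_avg - 1.0)
    return float(np.sqrt(np.clip(lam2, 0.64, 1.5625)))


def berendsen_thermostat(state, thermo: ThermostatState, dt: float,
                         dof: int):
    """Rescale velocities toward the target temperature (in place)."""
    if not thermo.enabled:
        return state
    state.velocities *= berendsen_lambda(thermo, dt)
    return state


def kinetic_energy_and_temperature(state, masses, dof: int):
    """(kJ/mol, K); T = 2·KE/(dof·kB)."""
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    ke = kinetic_energy(state.velocities, masses)
    return ke, 2.0 * ke / (dof * KB)


@dataclass
class DriftReport:
    """Least-squares slope of the conserved-energy series."""

    slope_kbt_per_ns_per_dof: float
    dof: int
    temperature: float
    window_fs: float


def drift_measure(energy_series, times_fs, dof: int,
                  temperature: float) -> DriftReport:
    """Energy drift per nanosecond and degree of freedom, in kB·T.

    The slope of the total-energy time series is obtained by least squares
    (sign preserved: inaccuracies do not always drift upward).
    """
    energy_series = np.asarray(energy_series, dtype=float)
    times_fs = np.asarray(times_fs, dtype=float)
    if len(energy_series) < 10:
        raise ValueError("energy series too short for a drift fit")
    slope_per_fs = np.polyfit(times_fs, energy_series, 1)[0]
    slope_per_ns = slope_per_fs * 1e6
    return DriftReport(
        slope_kbt_per_ns_per_dof=float(slope_per_ns / (dof * KB * temperature)),
        dof=dof, temperature=temperature,
        window_fs=float(times_fs[-1] - times_fs[0]))


class MixedIntegrator:
    """Leap-frog propagation with the mixed single/multiple time-step scheme.

    ``single_precision`` emulates storage of absolute coordinates as 32-bit
    floats (positions and steps are rounded after every update), which is
    what motivates the delta formulation of the constraint solvers.
    """

    def __init__(self, topology, engine, constraint_set,
                 schedule: StepSchedule | None = None,
                 lincs_params: _constraints.LincsParams | None = None,
                 single_precision: bool = False):
        self.topology = topology
        self.engine = engine
        self.cset = constraint_set
        self.schedule = schedule or StepSchedule()
        self.lincs_params = lincs_params or _constraints.LincsParams(
            tolerance=1e-4 if single_precision else 1e-6)
        self.single_precision = single_precision
        self.masses = topology.masses
        self.classes = classify_molecules(topology, constraint_set)
        self.dof = count_degrees_of_freedom(topology, constraint_set)
        mol_class = {i: c for i, c in enumerate(self.classes)}
        labels = topology.molecule_id
        mols = topology.molecules
        atom_class = np.empty(topology.n_atoms, dtype=object)
        for i, mol in enumerate(mols):
            atom_class[mol] = mol_class[i]
        self.single_mask = atom_class == IntegrationClass.SINGLE_STEP
        self.multi_mask = ~self.single_mask
        self.step_index = 0

    def _f32(self, x):
        return x.astype(np.float32).astype(float) if self.single_precision else x

    def _constrain(self, positions, steps, subset_mask=None):
        """Apply LINCS to constraint groups and SETTLE to waters."""
        steps = self._f32(steps)
        if self.cset.groups:
            steps = _constraints.lincs_apply(positions, steps,
                                             self.cset.groups, self.masses,
                                             self.lincs_params)
        if len(self.cset.settle_triads):
            steps = _constraints.settle_apply(positions, steps,
                                              self.cset.settle_triads,
                                              self.masses,
                                              self.cset.water_geometry)
        return self._f32(steps)

    def initialize_velocities(self, state):
        """Project constraint-violating components out of the velocities."""
        pairs = self.cset.all_pairs()
        if len(pairs):
            state.velocities = _constraints.remove_constraint_velocities(
                state.velocities, state.positions, pairs, self.masses)
        # remove COM drift
        m = self.masses[:, None]
        state.velocities -= np.sum(m * state.velocities, axis=0) / m.sum()
        return state

    def step(self, state, thermostat: ThermostatState | None = None):
        """One macro step of dt_inter; returns per-step records.

        Sequence: evaluate nonbonded (and bonded) at the sync point, advance
        single-step molecules by dt_inter with 1× nonbonded, advance
        multi-step molecules by dt_intra with bonded + 2× nonbonded (the
        impulse), then a second dt_intra substep under bonded forces only.
        """
        sch = self.schedule
        top = self.topology
        dt = sch.dt_inter
        half = sch.dt_intra
        masses = self.masses[:, None]
        v_before = state.velocities.copy()

        e_nb, f_nb, virial = self.engine.nonbonded(state, self.step_index)
        e_b, f_b = self.engine.bonded(state)

        new_v = state.velocities.copy()
        acc_nb = f_nb * ACC_FACTOR / masses

        # --- single-step molecules: one dt_inter step, 1× nonbonded
        sm = self.single_mask
        new_v[sm] += acc_nb[sm] * dt
        steps = np.zeros_like(state.positions)
        steps[sm] = new_v[sm] * dt

        # --- multi-step molecules, even substep: bonded + 2× nonbonded
        mm = self.multi_mask
        acc_b = f_b * ACC_FACTOR / masses
        new_v[mm] += (acc_b[mm]
                      + sch.nonbonded_scale_on_even_step * acc_nb[mm]) * half
        steps[mm] = new_v[mm] * half

        steps = self._constrain(state.positions, steps)
        state.positions = self._f32(state.positions + steps)
        new_v[sm] = steps[sm] / dt
        new_v[mm] = steps[mm] / half
        state.velocities = new_v

        # --- multi-step molecules, odd substep: bonded only
        if np.any(mm):
            _, f_b2 = self.engine.bonded(state)
            acc_b2 = f_b2 * ACC_FACTOR / masses
            new_v2 = state.velocities.copy()
            new_v2[mm] += acc_b2[mm] * half
            steps2 = np.zeros_like(state.positions)
            steps2[mm] = new_v2[mm] * half
            steps2 = self._constrain(state.positions, steps2)
            state.positions = self._f32(state.positions + steps2)
            new_v2[mm] = steps2[mm] / half
            state.velocities = new_v2

        state.time += dt
        self.step_index += 1

        # on-step kinetic energy: average of the two half-step kinetic
        # energies, the standard leap-frog conserved-energy bookkeeping
        ke = 0.5 * (kinetic_energy(v_before, self.masses)
                    + kinetic_energy(state.velocities, self.masses))
        temperature = 2.0 * ke / (self.dof * KB)
        if thermostat is not None and thermostat.enabled:
            thermostat.record(temperature)
            berendsen_thermostat(state, thermostat, dt, self.dof)

        record = {
            "time": state.time,
            "kinetic": ke,
            "temperature": temperature,
            "potential": e_b + e_nb["nonbonded_total"],
            "bonded": e_b,
            "virial_rf": virial,
        }
        record.update({f"e_{k}": v for k, v in e_nb.items()})
        record["total"] = record["kinetic"] + record["potential"]
        return record

    def run(self, state, n_steps: int, thermostat=None, coupling=None,
            callback=None):
        """Integrate n macro steps; returns the list of per-step records."""
        records = []
        for _ in range(n_steps):
            rec = self.step(state, thermostat)
            if coupling is not None:
                coupling.apply(state, self, rec)
            if callback is not None:
                callback(state, rec)
            records.append(rec)
        return records
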