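"""Pressure coupling: water-cube densostat and virial-based Berendsen barostat.

The densostat sidesteps the virial entirely: pressure spreads through the
cell, so the bulk-solvent density carries the same information.  All cubes of
the neighbor-search grid whose full 27-cube neighborhood contains only water
atoms are tagged; the water mass inside them divided by their volume is the
current water density.  It fluctuates far less than the virial pressure, so
measuring every 10 steps and averaging 50 measurements gives a stable value
that feeds a weak-coupling scale factor, clamped so no single rescale changes
the cell by more than 0.1% (larger jumps would heat the system through scaled
bond lengths; constraints re-idealize the geometry on the next step).

The classic barostat computes the virial pressure and rescales with the
Berendsen factor; it supports independent per-axis factors for systems where
pressure is not a scalar (membranes, crystals), which is exactly where the
densostat cannot be used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .forces import VirialAccumulator, virial_pressure, kinetic_energy
from .neighbor import Grid
from .units import DALTON_PER_A3_TO_G_ML

# 27-cube block, and the 57-cube variant (block + 5-cube cross on each face)
_OFFSETS_27 = np.array(list(product((-1, 0, 1), repeat=3)), dtype=int)


def _offsets_57() -> np.ndarray:
    offs = set(map(tuple, _OFFSETS_27))
    cross = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
    for axis in range(3):
        for sign in (-2, 2):
            for a, b in cross:
                o = [0, 0, 0]
                o[axis] = sign
                o[(axis + 1) % 3] = a
                o[(axis + 2) % 3] = b
                offs.add(tuple(o))
    return np.array(sorted(offs), dtype=int)


_OFFSETS_57 = _offsets_57()


class InsufficientSolventError(RuntimeError):
    pass


def tag_water_cubes(grid: Grid, topology, exclusion: int = 27) -> np.ndarray:
    """Boolean mask over grid cubes whose neighborhood is water-only.

    Equivalent to excluding the ``exclusion``-cube environment (27 or 57)
    around every non-water atom, with periodic wrapping.
    """
    if exclusion == 27:
        offsets = _OFFSETS_27
    elif exclusion == 57:
        offsets = _OFFSETS_57
    else:
        raise ValueError("exclusion must be 27 or 57")
    counts = grid.counts
    n2, n3 = int(counts[1]), int(counts[2])

    def dilate(ijk_list, offs):
        mask = np.zeros(grid.n_cubes, dtype=bool)
        if len(ijk_list):
            ijk = (ijk_list[:, None, :] + offs[None, :, :]) % counts
            cid = (ijk[..., 0] * n2 + ijk[..., 1]) * n3 + ijk[..., 2]
            mask[np.unique(cid)] = True
        return mask

    # a cube counts as bulk water when its immediate neighborhood contains
    # water (vacuum cubes must not dilute the density) and the exclusion
    # environment of every solute atom is avoided
    near_water = dilate(grid.cube_ijk[topology.is_water], _OFFSETS_27)
    near_solute = dilate(grid.cube_ijk[~topology.is_water], offsets)
    return near_water & ~near_solute


def measure_water_density(positions, topology, grid: Grid,
                          tagged: np.ndarray) -> float:
    """Water mass in tagged cubes over their volume, in g/ml."""
    n_tagged = int(np.sum(tagged))
    if n_tagged == 0:
        raise InsufficientSolventError(
            "no water-only cubes available for the density measurement")
    in_tagged = tagged[grid.cube_id] & topology.is_water
    mass = float(np.sum(topology.masses[in_tagged]))
    volume = n_tagged * grid.cube_volume
    return mass / volume * DALTON_PER_A3_TO_G_ML


def densostat_scale(measured: float, target: float, coupling: float = 1.0,
                    cubic_response: bool = False) -> float:
    """Weak-coupling scale factor S for the coordinates and cell.

    S = max(0.999, min(1.001, 1 + C·(ρ_measured/ρ_set − 1)/3)); the division
    by three is the first-order cube root turning a relative density error
    into a linear scale factor, and the clamp caps any single rescale at
    0.1%.  ``cubic_response`` switches to the alternative cubed-error
    reading, available for comparison.
    """
    if target <= 0:
        raise ValueError("target density must be positive")
    err = measured / target - 1.0
    response = coupling * (err ** 3 if cubic_response else err / 3.0)
    return float(max(0.999, min(1.001, 1.0 + response)))


@dataclass
class DensostatState:
    """Densostat configuration plus its measurement ring buffer.

    The default coupling strength keeps the feedback loop stable: the
    ring-buffer average lags the cell by up to window × interval steps, so
    the per-event gain C/3 times the ~window/2 events of lag must stay
    below one (C ≲ 6/window).  Larger couplings oscillate between the
    clamps instead of converging.
    """

    target_density: float = 0.997      # g/ml
    coupling: float = 0.05
    measure_interval: int = 10         # steps
    window: int = 50                   # averaged measurements
    exclusion: int = 27
    cubic_response: bool = False
    min_measurements: int = 5
    measurements: list = field(default_factory=list)
    measured_density: float = float("nan")
    insufficient_solvent: bool = False

    def record(self, density: float):
        self.measurements.append(density)
        if len(self.measurements) > self.window:
            self.measurements.pop(0)

    @property
    def averaged_density(self) -> float:
        if not self.measurements:
            return float("nan")
        return float(np.mean(self.measurements))


class Densostat:
    """Integrator plug-in: measure density periodically and rescale the cell."""

    def __init__(self, state: DensostatState | None = None,
                 grid_spacing: float = 2.6):
        self.state = state or DensostatState()
        self.grid_spacing = grid_spacing
        self.log: list[dict] = []

    def apply(self, sim_state, integrator, record):
        ds = self.state
        step = integrator.step_index
        if step % ds.measure_interval:
            return
        grid = Grid(sim_state.cell, sim_state.positions, self.grid_spacing)
        tagged = tag_water_cubes(grid, integrator.topology, ds.exclusion)
        if not np.any(tagged):
            ds.insufficient_solvent = True
            return
        ds.insufficient_solvent = False
        density = measure_water_density(sim_state.positions,
                                        integrator.topology, grid, tagged)
        ds.measured_density = density
        ds.record(density)
        if len(ds.measurements) < ds.min_measurements:
            return
        s = densostat_scale(ds.averaged_density, ds.target_density,
                            ds.coupling, ds.cubic_response)
        rescale_cell(sim_state, s)
        integrator.engine.invalidate_pairlist()
        self.log.append({"step": step, "density": density,
                         "density_avg": ds.averaged_density, "scale": s,
                         "volume": sim_state.cell.volume})


@dataclass
class BarostatState:
    """Berendsen barostat fed with time-averaged virial pressure."""

    target_pressure: float = 1.0       # bar
    coupling_time: float = 500.0       # fs
    compressibility: float = 4.5e-5    # 1/bar
    window: int = 50
    isotropic: bool = True
    max_step_scale: float = 0.001
    pressure_history: list = field(default_factory=list)

    def record(self, pressure):
        self.pressure_history.append(np.asarray(pressure, dtype=float))
        if len(self.pressure_history) > self.window:
            self.pressure_history.pop(0)

    @property
    def averaged_pressure(self) -> np.ndarray:
        if not self.pressure_history:
            return np.full(3, self.target_pressure)
        return np.mean(np.stack(self.pressure_history), axis=0)


def barostat_scale(baro: BarostatState, dt: float) -> np.ndarray:
    """Per-axis Berendsen scale factors from the time-averaged pressure.

    μ_a = [1 − κ·dt/τ·(P_target − P_avg,a)]^{1/3}, clamped to the same 0.1%
    per-step limit as the densostat.  In isotropic mode the trace average is
    applied to all axes.
    """
    p_avg = baro.averaged_pressure
    if baro.isotropic:
        p_avg = np.full(3, float(np.mean(p_avg)))
    mu3 = 1.0 - baro.compressibility * dt / baro.coupling_time * (
        baro.target_pressure - p_avg)
    mu = np.cbrt(mu3)
    lo, hi = 1.0 - baro.max_step_scale, 1.0 + baro.max_step_scale
    return np.clip(mu, lo, hi)


class Barostat:
    """Integrator plug-in computing the virial pressure and rescaling."""

    def __init__(self, state: BarostatState | None = None,
                 measure_interval: int = 10):
        self.state = state or BarostatState()
        self.measure_interval = measure_interval
        self.log: list[dict] = []

    def apply(self, sim_state, integrator, record):
        step = integrator.step_index
        if step % self.measure_interval:
            return
        acc = VirialAccumulator(
            kinetic_energy=record["kinetic"],
            rf_sum=record["virial_rf"] + self._reciprocal_virial(
                sim_state, integrator),
            volume=sim_state.cell.volume)
        pressure = virial_pressure(acc)
        self.state.record(pressure)
        mu = barostat_scale(self.state, integrator.schedule.dt_inter
                            * self.measure_interval)
        rescale_cell(sim_state, mu)
        integrator.engine.invalidate_pairlist()
        self.log.append({"step": step, "pressure": pressure,
                         "pressure_avg": float(np.mean(
                             self.state.averaged_pressure)),
                         "scale": float(np.mean(mu)),
                         "volume": sim_state.cell.volume})

    def _reciprocal_virial(self, sim_state, integrator) -> float:
        """Σr·f contribution of the reciprocal-space energy.

        Obtained from −3·dU_rec/dlnV by central finite difference of the
        reciprocal energy under isotropic scaling (the pair terms are
        accumulated analytically; only the mesh term needs this).
        """
        from . import pme as _pme

        top = integrator.topology
        if not integrator.engine.params.use_pme or not np.any(
                top.charges != 0.0):
            return 0.0
        eps = 5e-4
        out = []
        for s in (1.0 + eps, 1.0 - eps):
            cell = sim_state.cell.scaled(s)
            pos = sim_state.positions * s
            ew = _pme.EwaldParams(
                beta=integrator.engine.params.resolved_beta(),
                grid=_pme.pme_grid_size(cell,
                                        integrator.engine.params.pme_spacing),
                cutoff=integrator.engine.params.cutoff)
            e, _ = _pme.pme_reciprocal(pos, top.charges, cell, ew)
            e += _pme.self_energy(top.charges, ew.beta)
            out.append(e)
        # dU/ds ≈ (U₊ − U₋)/2ε;  dlnV = 3 dln s;  Σr·f = −3·dU/dlnV
        return float(-(out[0] - out[1]) / (2.0 * eps))


def rescale_cell(state, scale) -> None:
    """Scale the cell vectors and atom coordinates (per axis), in place.

    Constraints are re-satisfied on the next integration step.
    """
    f = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
    state.cell = state.cell.scaled(f)
    state.positions = state.positions * f[None, :]
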