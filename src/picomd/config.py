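"""Run configuration: a small YAML-serializable description of a simulation.

A config names the system source (a built-in fixture or a PDB file), the
nonbonded settings, the time-step layout, the constraint mode, the pair-list
policy and the coupling ensemble.  ``run()`` assembles everything and
integrates, returning the per-step records (optionally writing an energy CSV
and a multi-MODEL PDB trajectory).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

CONSTRAINT_MODES = ("none", "bonds", "bonds+angles")
COUPLING_MODES = ("NVE", "NVT", "NPT-barostat", "NPT-densostat")


@dataclass
class RunConfig:
    # system source: fixture name ("water_box", "test:<name>") or PDB path
    system: str = "water_box"
    n_per_edge: int = 4
    density_g_ml: float = 0.997
    pdb_path: str | None = None
    box: list | None = None

    cutoff: float = 8.0
    dt_intra: float = 2.5
    dt_inter: float = 5.0
    constraint_mode: str = "bonds+angles"
    pairlist_update_frequency: int = 1
    pairlist_constant: float = 0.001
    coupling_mode: str = "NVE"
    temperature: float = 298.0
    thermostat_tau: float = 100.0
    target_pressure: float = 1.0
    target_density: float = 0.997
    seed: int = 0
    duration_fs: float = 1000.0
    single_precision: bool = False
    use_pme: bool = True
    energy_csv: str | None = None
    trajectory_pdb: str | None = None
    trajectory_interval: int = 50

    def validate(self):
        if self.constraint_mode not in CONSTRAINT_MODES:
            raise ValueError(f"constraint_mode must be one of "
                             f"{CONSTRAINT_MODES}")
        if self.coupling_mode not in COUPLING_MODES:
            raise ValueError(f"coupling_mode must be one of {COUPLING_MODES}")
        if self.constraint_mode == "none" and self.dt_inter > 2.0:
            warnings.warn(
                f"{self.dt_inter} fs without constraints is expected to blow "
                "up (hydrogen vibrations); proceeding anyway", stacklevel=2)
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (FileNotFoundError, OSError):
                data = yaml.safe_load(source)
        return cls(**data).validate()


def build_system(config: RunConfig):
    """(topology, state) from the configured source."""
    from . import fixtures, pdbio

    if config.system == "water_box":
        return fixtures.build_water_box(
            config.n_per_edge, config.density_g_ml, seed=config.seed,
            temperature=config.temperature)
    if config.system.startswith("test:"):
        top, state = fixtures.build_test_molecule(config.system[5:])
        rng = np.random.default_rng(config.seed)
        state.velocities = fixtures.maxwell_boltzmann_velocities(
            top.masses, config.temperature, rng)
        return top, state
    if config.system == "pdb":
        top, state = pdbio.load_pdb(config.pdb_path, box=config.box)
        rng = np.random.default_rng(config.seed)
        state.velocities = fixtures.maxwell_boltzmann_velocities(
            top.masses, config.temperature, rng)
        return top, state
    raise ValueError(f"unknown system source {config.system!r}")


def build_constraints(config: RunConfig, topology):
    from . import constraints as _c

    if config.constraint_mode == "none":
        return _c.ConstraintSet()
    cset = _c.build_all_constraints(topology)
    if config.constraint_mode == "bonds":
        bonds_only = [c for c in cset.constraints if c.origin == _c.BOND]
        groups = _c._group_constraints(bonds_only, topology.is_hydrogen)
        return _c.ConstraintSet(constraints=bonds_only, groups=groups,
                                settle_triads=cset.settle_triads,
                                water_geometry=cset.water_geometry)
    return cset


def run(config: RunConfig):
    """Assemble and integrate; returns (records, state, integrator)."""
    from . import coupling as _coupling
    from . import neighbor as _neighbor
    from .engine import ForceField
    from .forces import NonbondedParams
    from .integrate import (MixedIntegrator, StepSchedule, ThermostatState)

    config.validate()
    top, state = build_system(config)
    cset = build_constraints(config, top)
    policy = None
    if config.pairlist_update_frequency > 1:
        policy = _neighbor.PairListPolicy(
            cutoff_force=config.cutoff,
            update_frequency=config.pairlist_update_frequency,
            time_step=config.dt_inter, temperature=config.temperature,
            avg_particle_mass=_neighbor.average_particle_mass(top),
            constant=config.pairlist_constant)
    params = NonbondedParams(cutoff=config.cutoff, use_pme=config.use_pme)
    engine = ForceField(top, params, pairlist_policy=policy,
                        constraint_set=cset)
    schedule = StepSchedule(dt_intra=config.dt_intra, dt_inter=config.dt_inter)
    integrator = MixedIntegrator(top, engine, cset, schedule,
                                 single_precision=config.single_precision)
    integrator.initialize_velocities(state)

    thermostat = None
    if config.coupling_mode in ("NVT", "NPT-barostat", "NPT-densostat"):
        thermostat = ThermostatState(target_temperature=config.temperature,
                                     coupling_time=config.thermostat_tau)
    coupling = None
    if config.coupling_mode == "NPT-densostat":
        coupling = _coupling.Densostat(_coupling.DensostatState(
            target_density=config.target_density))
    elif config.coupling_mode == "NPT-barostat":
        coupling = _coupling.Barostat(_coupling.BarostatState(
            target_pressure=config.target_pressure))

    n_steps = int(round(config.duration_fs / config.dt_inter))
    frames = []

    def callback(st, rec):
        if (config.trajectory_pdb is not None
                and integrator.step_index % config.trajectory_interval == 0):
            frames.append(st.copy())

    records = integrator.run(state, n_steps, thermostat=thermostat,
                             coupling=coupling, callback=callback)

    if config.energy_csv is not None:
        import pandas as pd

        pd.DataFrame(records).to_csv(config.energy_csv, index=False)
    if config.trajectory_pdb is not None and frames:
        from . import pdbio

        pdbio.write_pdb(config.trajectory_pdb, top, frames)
    return records, state, integrator
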