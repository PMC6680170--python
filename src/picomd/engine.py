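"""Force provider orchestrating neighbor search, real-space, PME and bonded terms.

The :class:`ForceField` bundles a topology with nonbonded settings, manages
the neighbor grid, the precalculated search pattern and the optional sloppy
pair list, and exposes the two evaluations the mixed integrator needs:
``bonded(state)`` (cheap, every small substep) and ``nonbonded(state, step)``
(every large step, with pair-list reuse according to the policy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forces as _forces
from . import neighbor as _neighbor
from . import pme as _pme


class ForceField:
    """Evaluates all force classes for one topology.

    If a ``PairListPolicy`` with update_frequency > 1 is supplied, the fused
    search stores a pair list out to the enlarged pair-list cutoff and the
    intermediate steps reuse it; otherwise the grid search runs every step
    (exact mode).
    """

    def __init__(self, topology, params: _forces.NonbondedParams,
                 pairlist_policy: _neighbor.PairListPolicy | None = None,
                 constraint_set=None):
        self.topology = topology
        self.params = params
        self.policy = pairlist_policy
        self._pattern = None
        self._pattern_key = None
        self._pairlist = None
        self._ewald = None
        self._ewald_key = None
        self.skip_bonds = np.zeros(len(topology.bonds), dtype=bool)
        self.skip_angles = np.zeros(len(topology.angles), dtype=bool)
        if constraint_set is not None:
            self._mask_constrained_terms(constraint_set)

    def _mask_constrained_terms(self, cset):
        """Bonded terms frozen by constraints contribute zero force."""
        pairs = {(int(a), int(b)) for a, b in cset.all_pairs()}
        pairs |= {(b, a) for a, b in pairs}
        for n, (a, b) in enumerate(self.topology.bonds):
            if (int(a), int(b)) in pairs:
                self.skip_bonds[n] = True
        for n, (a, b, c) in enumerate(self.topology.angles):
            # an angle is frozen when both its arms and the 1-3 distance are
            # constrained (directly or via rigid-water handling)
            if ((int(a), int(b)) in pairs and (int(b), int(c)) in pairs
                    and (int(a), int(c)) in pairs):
                self.skip_angles[n] = True

    # -- cached helpers ----------------------------------------------------

    @property
    def search_cutoff(self) -> float:
        if self.policy is not None and self.policy.update_frequency > 1:
            return _neighbor.pairlist_cutoff(self.policy)
        return self.params.cutoff

    def pattern_for(self, cell) -> _neighbor.SearchPattern:
        spacing = _neighbor.grid_spacing(self.params.cutoff)
        key = (cell.matrix.tobytes(), round(self.search_cutoff, 9))
        if self._pattern_key != key:
            self._pattern = _neighbor.build_search_pattern(
                self.search_cutoff, spacing, cell)
            self._pattern_key = key
        return self._pattern

    def ewald_for(self, cell) -> _pme.EwaldParams:
        key = cell.matrix.tobytes()
        if self._ewald_key != key:
            beta = self.params.resolved_beta()
            # keep the mesh fine enough for the damping width; the force
            # interpolation artifact decays more slowly than the energy
            # error, hence the conservative 0.3/β bound
            spacing = min(self.params.pme_spacing, 0.3 / beta)
            self._ewald = _pme.EwaldParams(
                beta=beta,
                grid=_pme.pme_grid_size(cell, spacing),
                cutoff=self.params.cutoff)
            self._ewald_key = key
        return self._ewald

    def invalidate_pairlist(self):
        self._pairlist = None

    # -- evaluations -------------------------------------------------------

    def bonded(self, state):
        return _forces.bonded_forces(state.positions, self.topology,
                                     cell=state.cell,
                                     skip_bonds=self.skip_bonds,
                                     skip_angles=self.skip_angles)

    def nonbonded(self, state, step_index: int = 0):
        """Full nonbonded pass: returns (energies dict, forces, rf_virial).

        Real-space LJ+erfc runs over the grid search or the stored pair
        list; PME reciprocal, self energy and exclusion corrections are
        added when electrostatics are active.
        """
        top = self.topology
        params = self.params
        reuse = (self.policy is not None and self.policy.update_frequency > 1)
        refresh = (not reuse or self._pairlist is None
                   or (step_index - self._pairlist.creation_step)
                   >= self.policy.update_frequency)
        if refresh:
            spacing = _neighbor.grid_spacing(params.cutoff)
            grid = _neighbor.Grid(state.cell, state.positions, spacing)
            pattern = self.pattern_for(state.cell)
            energies, forces, virial, plist = _neighbor.fused_search_and_forces(
                state, top, grid, pattern, params,
                store_pairlist=reuse,
                pairlist_cutoff_value=self.search_cutoff,
                step_index=step_index)
            if reuse:
                self._pairlist = plist
            self._grid = grid
        else:
            energies, forces, virial = _neighbor.pairlist_reuse_step(
                state, top, self._pairlist, params, step_index,
                self.policy.update_frequency)

        e_corr, f_corr, v_corr = _forces.excluded_pair_corrections(
            top, state.positions, state.cell, params)
        energies.update(e_corr)
        forces = forces + f_corr
        virial += v_corr

        if params.use_pme and np.any(top.charges != 0.0):
            ew = self.ewald_for(state.cell)
            e_rec, f_rec = _pme.pme_reciprocal(
                state.positions, top.charges, state.cell, ew)
            energies["coulomb_recip"] = e_rec
            energies["coulomb_self"] = _pme.self_energy(top.charges, ew.beta)
            forces = forces + f_rec
        energies["nonbonded_total"] = float(sum(energies.values()))
        return energies, forces, virial

    def potential_energy(self, state, step_index: int = 0) -> dict:
        """All energy components at the current positions (diagnostics)."""
        e_b, _ = self.bonded(state)
        e_nb, _, _ = self.nonbonded(state, step_index)
        out = dict(e_nb)
        out["bonded"] = e_b
        out["potential"] = e_b + e_nb["nonbonded_total"]
        return out
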