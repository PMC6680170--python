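"""Bonded terms, nonbonded kernels, lookup tables, PME and the virial."""

from itertools import product

import numpy as np
import pytest
from scipy.special import erfc

from picomd.cell import TriclinicCell
from picomd.engine import ForceField
from picomd.fixtures import WaterModel, build_test_molecule, build_water_box
from picomd.forces import (NonbondedParams, VirialAccumulator, bonded_forces,
                           kinetic_energy, virial_pressure)
from picomd.pme import EwaldParams, pme_reciprocal, self_energy
from picomd.system import SystemState, Topology
from picomd.tables import build_force_tables, nonbonded_pair_force
from picomd.units import COULOMB, KB, KJ_PER_MOL_A3_TO_BAR


def finite_difference_forces(energy_fn, positions, h=1e-5):
    num = np.zeros_like(positions)
    for i in range(len(positions)):
        for ax in range(3):
            pp = positions.copy()
            pp[i, ax] += h
            pm = positions.copy()
            pm[i, ax] -= h
            num[i, ax] = -(energy_fn(pp) - energy_fn(pm)) / (2 * h)
    return num


def direct_ewald_energy(pos, q, cell, beta, kmax=14, images=2):
    """Independent oracle: explicit real-space image sum + reciprocal sum."""
    H = cell.matrix
    G = np.linalg.inv(H)
    e_real = 0.0
    n = len(q)
    for a in range(n):
        for b in range(n):
            for s in product(range(-images, images + 1), repeat=3):
                if a == b and s == (0, 0, 0):
                    continue
                r = np.linalg.norm(pos[a] - pos[b] + np.array(s, float) @ H)
                e_real += 0.5 * q[a] * q[b] * erfc(beta * r) / r
    e_rec = 0.0
    for m1 in range(-kmax, kmax + 1):
        for m2 in range(-kmax, kmax + 1):
            for m3 in range(-kmax, kmax + 1):
                if m1 == m2 == m3 == 0:
                    continue
                mv = np.array([m1, m2, m3], float) @ G.T
                m2a = mv @ mv
                s_m = np.sum(q * np.exp(2j * np.pi * (pos @ mv)))
                e_rec += (np.exp(-np.pi ** 2 * m2a / beta ** 2) / m2a
                          * abs(s_m) ** 2)
    e_rec /= 2 * np.pi * cell.volume
    e_self = -beta / np.sqrt(np.pi) * np.sum(q ** 2)
    return COULOMB * (e_real + e_rec + e_self)


class TestBondedForces:
    def test_zero_at_equilibrium(self, dipeptide):
        """Idealized fixture geometry *is* the equilibrium by construction."""
        top, state = dipeptide
        # drop the torsion terms: a 3-fold cosine has no zero-force
        # requirement at the embedded geometry
        top_nodih = _without_dihedrals(top)
        e, f = bonded_forces(state.positions, top_nodih)
        assert np.abs(f).max() < 1e-6

    def test_stretched_bond_closed_form(self):
        top = Topology(["C", "H"], [12.011, 1.008])
        top.set_bonds([(0, 1)], [1.09], [2800.0])
        pos = np.array([[0.0, 0, 0], [1.19, 0, 0]])
        e, f = bonded_forces(pos, top)
        assert e == pytest.approx(0.5 * 2800.0 * 0.1 ** 2, rel=1e-12)
        assert f[1, 0] == pytest.approx(-2800.0 * 0.1, rel=1e-10)
        assert f[0, 0] == pytest.approx(+2800.0 * 0.1, rel=1e-10)

    @pytest.mark.parametrize("name", ["ethanol", "capped_alanine_dipeptide"])
    def test_gradient_check(self, name):
        """Analytic bonded forces match central differences to 1e-6."""
        top, state = build_test_molecule(name)
        rng = np.random.default_rng(0)
        pos = state.positions + rng.normal(0, 0.05, state.positions.shape)
        e, f = bonded_forces(pos, top)
        num = finite_difference_forces(
            lambda p: bonded_forces(p, top)[0], pos)
        scale = max(1.0, np.abs(f).max())
        assert np.abs(f - num).max() / scale < 1e-6

    def test_newtons_third_law(self, dipeptide):
        top, state = dipeptide
        rng = np.random.default_rng(1)
        pos = state.positions + rng.normal(0, 0.1, state.positions.shape)
        _, f = bonded_forces(pos, top)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_constrained_terms_skipped(self, methane, methane_constraints):
        top, state = methane
        params = NonbondedParams(cutoff=5.0, use_pme=False)
        ff = ForceField(top, params, constraint_set=methane_constraints)
        assert ff.skip_bonds.all()          # all four C-H bonds constrained
        e, f = ff.bonded(SystemState(state.positions + 10.0,
                                     np.zeros_like(state.positions),
                                     state.cell))
        # angle terms frozen via H-H constraints contribute nothing either
        frozen = ff.skip_angles.sum()
        assert frozen >= 1


def _without_dihedrals(top):
    import copy

    t = copy.copy(top)
    t.dihedrals = np.zeros((0, 4), dtype=int)
    t.dihedral_k = np.zeros(0)
    t.dihedral_n = np.zeros(0, dtype=int)
    t.dihedral_phase = np.zeros(0)
    return t


class TestForceTables:
    model = WaterModel()

    def build(self, resolution=4096):
        ew = EwaldParams(beta=0.39, grid=(16, 16, 16), cutoff=8.0)
        return build_force_tables(ew, self.model, resolution=resolution)

    def test_damping_vanishes_at_large_distance(self):
        tables = self.build()
        assert tables.damping.interpolate(7.99) < 1e-4

    def test_damping_table_matches_explicit_over_full_range(self):
        """≤ 1e-5 relative over [0.5 Å, cutoff] (the damping factor is
        smooth and strictly positive)."""
        tables = self.build()
        rng = np.random.default_rng(1)
        r = rng.uniform(0.5, 8.0, 10_000)
        beta = tables.beta
        exact = (erfc(beta * r) / r + 2 * beta / np.sqrt(np.pi)
                 * np.exp(-(beta * r) ** 2)) / r ** 2
        approx = tables.damping.interpolate(r)
        assert np.max(np.abs(approx - exact) / exact) <= 1e-5

    def test_oo_table_matches_explicit_evaluation(self):
        """≤ 1e-5 relative over the physically sampled O–O range; the force
        changes sign near the LJ/Coulomb balance, so the error is measured
        against a floor that avoids dividing by the zero crossing."""
        tables = self.build()
        rng = np.random.default_rng(2)
        r = rng.uniform(2.4, 8.0, 10_000)
        sig, eps = self.model.lj_sigma_o, self.model.lj_epsilon_o
        qq = self.model.q_o ** 2
        beta = tables.beta
        sr6 = (sig / r) ** 6
        exact = (COULOMB * qq * (erfc(beta * r) / r
                                 + 2 * beta / np.sqrt(np.pi)
                                 * np.exp(-(beta * r) ** 2)) / r ** 2
                 + 24 * eps * (2 * sr6 ** 2 - sr6) / r ** 2)
        approx = tables.water["OO"].interpolate(r)
        floor = 1e-4 * np.abs(exact).max()
        rel = np.abs(approx - exact) / np.maximum(np.abs(exact), floor)
        assert rel.max() <= 1e-5

    def test_halving_resolution_quadruples_error(self):
        """Linear interpolation error scales with the square of the grid
        spacing."""
        rng = np.random.default_rng(3)
        r = rng.uniform(1.0, 7.9, 20_000)

        def max_err(res):
            t = self.build(resolution=res)
            beta = t.beta
            exact = (erfc(beta * r) / r + 2 * beta / np.sqrt(np.pi)
                     * np.exp(-(beta * r) ** 2)) / r ** 2
            return np.max(np.abs(t.damping.interpolate(r) - exact))

        ratio = max_err(256) / max_err(512)
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_pair_force_water_vs_explicit(self):
        tables = self.build()
        rvec = np.array([2.9, 0.4, -0.3])
        f, e = nonbonded_pair_force(rvec, "OO", tables, None)
        r = np.linalg.norm(rvec)
        beta = tables.beta
        qq = self.model.q_o ** 2
        sig, eps = self.model.lj_sigma_o, self.model.lj_epsilon_o
        sr6 = (sig / r) ** 6
        f_exact = (COULOMB * qq * (erfc(beta * r) / r
                                   + 2 * beta / np.sqrt(np.pi)
                                   * np.exp(-(beta * r) ** 2)) / r ** 2
                   + 24 * eps * (2 * sr6 ** 2 - sr6) / r ** 2) * rvec
        assert np.abs(f - f_exact).max() / np.abs(f_exact).max() < 1e-5

    def test_neutral_zero_epsilon_pair_is_zero(self):
        tables = self.build()
        f, e = nonbonded_pair_force(np.array([3.0, 0, 0]),
                                    (0.0, 3.0, 0.0), tables, None)
        assert np.all(f == 0.0) and e == 0.0

    def test_below_range_clamped_and_counted(self):
        tables = self.build()
        before = tables.clamp_warnings
        nonbonded_pair_force(np.array([0.05, 0, 0]), "HH", tables, None)
        assert tables.clamp_warnings == before + 1


class TestPME:
    pos = np.array([[1.0, 1.0, 1.0], [4.2, 5.5, 6.1], [8.0, 2.0, 9.0],
                    [3.3, 8.8, 2.2]])
    q = np.array([1.0, -1.0, 0.5, -0.5])

    def total_electrostatic(self, pos, cell, beta, grid):
        params = EwaldParams(beta=beta, grid=grid)
        e_rec, _ = pme_reciprocal(pos, self.q, cell, params)
        e_real = 0.0
        for a in range(len(self.q)):
            for b in range(a + 1, len(self.q)):
                for s in product(range(-2, 3), repeat=3):
                    sv = np.array(s, float) @ cell.matrix
                    if a == b and s == (0, 0, 0):
                        continue
                    r = np.linalg.norm(pos[a] - pos[b] + sv)
                    e_real += self.q[a] * self.q[b] * erfc(beta * r) / r
        # same-atom image interactions
        for a in range(len(self.q)):
            for s in product(range(-2, 3), repeat=3):
                if s == (0, 0, 0):
                    continue
                r = np.linalg.norm(np.array(s, float) @ cell.matrix)
                e_real += 0.5 * self.q[a] ** 2 * erfc(beta * r) / r
        return COULOMB * e_real + e_rec + self_energy(self.q, beta)

    def test_total_energy_matches_direct_ewald_cubic(self):
        cell = TriclinicCell.cubic(10.0)
        ours = self.total_electrostatic(self.pos, cell, 0.35, (24, 24, 24))
        oracle = direct_ewald_energy(self.pos, self.q, cell, 0.35)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_total_energy_matches_direct_ewald_triclinic(self):
        cell = TriclinicCell(np.array([[10.0, 0, 0], [1.5, 10.0, 0],
                                       [1.0, 0.8, 10.0]]))
        ours = self.total_electrostatic(self.pos, cell, 0.35, (24, 24, 24))
        oracle = direct_ewald_energy(self.pos, self.q, cell, 0.35)
        assert ours == pytest.approx(oracle, rel=1e-4)

    def test_reciprocal_forces_match_finite_differences(self):
        """The spline forces are the exact gradient of the mesh energy
        (checked without the cosmetic net-force removal)."""
        cell = TriclinicCell.cubic(10.0)
        params = EwaldParams(beta=0.35, grid=(24, 24, 24))
        _, f = pme_reciprocal(self.pos, self.q, cell, params,
                              remove_net_force=False)
        num = finite_difference_forces(
            lambda p: pme_reciprocal(p, self.q, cell, params)[0], self.pos)
        assert np.abs(f - num).max() / np.abs(f).max() < 1e-5

    def test_lattice_translation_invariance(self):
        cell = TriclinicCell.cubic(10.0)
        params = EwaldParams(beta=0.35, grid=(24, 24, 24))
        e1, _ = pme_reciprocal(self.pos, self.q, cell, params)
        e2, _ = pme_reciprocal(self.pos + cell.matrix[0], self.q, cell,
                               params)
        assert e1 == pytest.approx(e2, abs=1e-8)

    def test_reciprocal_forces_sum_to_zero(self):
        cell = TriclinicCell.cubic(10.0)
        params = EwaldParams(beta=0.35, grid=(24, 24, 24))
        _, f = pme_reciprocal(self.pos, self.q, cell, params)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_relabeling_invariance(self):
        cell = TriclinicCell.cubic(10.0)
        params = EwaldParams(beta=0.35, grid=(24, 24, 24))
        e1, _ = pme_reciprocal(self.pos, self.q, cell, params)
        perm = np.array([2, 0, 3, 1])
        e2, _ = pme_reciprocal(self.pos[perm], self.q[perm], cell, params)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_non_neutral_rejected_without_background(self):
        cell = TriclinicCell.cubic(10.0)
        params = EwaldParams(beta=0.35, grid=(16, 16, 16))
        with pytest.raises(ValueError, match="net charge"):
            pme_reciprocal(self.pos, np.abs(self.q), cell, params)


class TestEngineGradients:
    def test_full_nonbonded_gradient_water_box(self, small_water_box):
        """Real-space + PME + exclusion corrections are a consistent
        gradient of the total nonbonded energy (1e-5 relative)."""
        top, state = small_water_box
        params = NonbondedParams(cutoff=4.0)
        ff = ForceField(top, params)
        _, f, _ = ff.nonbonded(state)

        def energy(pos):
            st = SystemState(pos, np.zeros_like(pos), state.cell)
            e, _, _ = ff.nonbonded(st)
            return e["nonbonded_total"]

        # atoms with a pair sitting right at the cutoff see the truncation
        # discontinuity and cannot be differenced; skip them
        d = state.cell.minimum_image(
            state.positions[:, None, :] - state.positions[None, :, :])
        rr = np.linalg.norm(d, axis=2)
        near_edge = np.any(np.abs(rr - params.cutoff) < 1e-3, axis=1)

        rng = np.random.default_rng(0)
        atoms = [i for i in rng.permutation(top.n_atoms) if not near_edge[i]]
        checked = 0
        for i in atoms[:6]:
            for ax in range(3):
                pp = state.positions.copy()
                pp[i, ax] += 1e-5
                pm = state.positions.copy()
                pm[i, ax] -= 1e-5
                num = -(energy(pp) - energy(pm)) / 2e-5
                assert f[i, ax] == pytest.approx(
                    num, rel=1e-4, abs=1e-4 * max(1, np.abs(f).max()))
                checked += 1
        assert checked >= 9

    def test_total_force_sums_to_zero(self, small_water_box):
        top, state = small_water_box
        params = NonbondedParams(cutoff=4.0)
        ff = ForceField(top, params)
        _, f, _ = ff.nonbonded(state)
        assert np.abs(f.sum(axis=0)).max() < 1e-8 * top.n_atoms


class TestVirialPressure:
    def test_ideal_gas_law(self):
        """No forces: P = N·kB·T/V exactly."""
        n, t, vol = 100, 300.0, 8000.0
        ke = 1.5 * n * KB * t
        acc = VirialAccumulator(kinetic_energy=ke, rf_sum=0.0, volume=vol)
        expected = n * KB * t / vol * KJ_PER_MOL_A3_TO_BAR
        assert virial_pressure(acc) == pytest.approx(expected, rel=1e-12)

    def test_zero_everything(self):
        acc = VirialAccumulator(kinetic_energy=0.0, rf_sum=0.0, volume=1000.0)
        assert virial_pressure(acc) == 0.0

    def test_lj_dimer_closed_form(self):
        """Single pair at fixed r: P = (2·KE + r·f)/(3V)."""
        sigma, eps, r = 3.4, 0.3, 3.8
        sr6 = (sigma / r) ** 6
        f_scalar = 24 * eps * (2 * sr6 ** 2 - sr6) / r
        ke = 1.2345
        vol = 1000.0
        acc = VirialAccumulator(kinetic_energy=ke, rf_sum=f_scalar * r,
                                volume=vol)
        expected = (2 * ke / 3 + f_scalar * r / 3) / vol \
            * KJ_PER_MOL_A3_TO_BAR
        assert virial_pressure(acc) == pytest.approx(expected, rel=1e-12)

    def test_engine_virial_consistent_with_volume_derivative(self):
        """Σr·f from the pair pass equals −3·dU/dlnV (LJ only)."""
        cell = TriclinicCell.cubic(16.0)
        rng = np.random.default_rng(4)
        n = 60
        pos = rng.uniform(0, 16, (n, 3))
        top = Topology(["C"] * n, np.full(n, 12.0),
                       lj_sigma=np.full(n, 3.4), lj_epsilon=np.full(n, 0.3))
        params = NonbondedParams(cutoff=7.0, use_pme=False)
        ff = ForceField(top, params)

        def u(scale):
            st = SystemState(pos * scale, np.zeros_like(pos),
                             cell.scaled(scale))
            e, _, _ = ff.nonbonded(st)
            return e["nonbonded_total"]

        st = SystemState(pos, np.zeros_like(pos), cell)
        _, _, w = ff.nonbonded(st)
        eps = 1e-6
        du_dlns = (u(1 + eps) - u(1 - eps)) / (2 * eps)
        assert w == pytest.approx(-du_dlns, rel=2e-3)


class TestKineticEnergy:
    def test_temperature_arithmetic(self):
        """KE set to ½·dof·kB·T reads back as T."""
        from picomd.integrate import kinetic_energy_and_temperature

        masses = np.full(10, 18.0)
        v = np.zeros((10, 3))
        v[:, 0] = np.sqrt(2 * 0.5 * 27 * KB * 298.0 / (masses.sum() * 1e4)
                          * 10 / 10)
        state = SystemState(np.zeros((10, 3)), v, TriclinicCell.cubic(10))
        ke = kinetic_energy(v, masses)
        _, t = kinetic_energy_and_temperature(state, masses, 27)
        assert t == pytest.approx(2 * ke / (27 * KB), rel=1e-12)

    def test_velocity_doubling_quadruples_temperature(self):
        from picomd.integrate import kinetic_energy_and_temperature

        rng = np.random.default_rng(0)
        masses = rng.uniform(1, 20, 8)
        v = rng.normal(0, 1e-3, (8, 3))
        s1 = SystemState(np.zeros((8, 3)), v, TriclinicCell.cubic(10))
        s2 = SystemState(np.zeros((8, 3)), 2 * v, TriclinicCell.cubic(10))
        _, t1 = kinetic_energy_and_temperature(s1, masses, 21)
        _, t2 = kinetic_energy_and_temperature(s2, masses, 21)
        assert t2 == pytest.approx(4 * t1, rel=1e-12)

    def test_zero_velocities_zero_kelvin(self):
        from picomd.integrate import kinetic_energy_and_temperature

        s = SystemState(np.zeros((5, 3)), np.zeros((5, 3)),
                        TriclinicCell.cubic(10))
        _, t = kinetic_energy_and_temperature(s, np.ones(5), 12)
        assert t == 0.0
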