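"""Constraint machinery: selection, coupling spectra, LINCS and SETTLE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picomd.constraints import (ANGLE, BOND, Constraint, ConstraintGroup,
                                LincsConvergenceError, LincsParams,
                                WaterGeometry, angle_constraint_distance,
                                build_all_constraints, build_coupling_matrix,
                                lincs_apply, max_abs_eigenvalue, settle_apply,
                                _shake_triad)
from picomd.fixtures import build_test_molecule, build_water_box

TETRA_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                      dtype=float) / np.sqrt(3.0)
M_C, M_H = 12.011, 1.008


def ch3_tetrahedron_group(bond=1.09):
    """Central carbon with three hydrogens in ideal tetrahedral geometry:
    three bond constraints plus the three angle-derived H–H distances."""
    pos = np.vstack([[0.0, 0.0, 0.0]] + [d * bond for d in TETRA_DIRS[:3]])
    masses = np.array([M_C, M_H, M_H, M_H])
    d_hh = angle_constraint_distance(bond, bond, np.degrees(np.arccos(-1.0 / 3.0)))
    cons = ([Constraint(0, i, bond, BOND) for i in (1, 2, 3)]
            + [Constraint(1, 2, d_hh, ANGLE), Constraint(2, 3, d_hh, ANGLE),
               Constraint(3, 1, d_hh, ANGLE)])
    group = ConstraintGroup(cons, np.arange(4), is_tetrahedron_case=True)
    return group, masses, pos


def methane_group(bond=1.09):
    """Four bonds plus two angle constraints over disjoint hydrogen pairs."""
    pos = np.vstack([[0.0, 0.0, 0.0]] + [d * bond for d in TETRA_DIRS])
    masses = np.array([M_C, M_H, M_H, M_H, M_H])
    d_hh = angle_constraint_distance(bond, bond, np.degrees(np.arccos(-1.0 / 3.0)))
    cons = ([Constraint(0, i, bond, BOND) for i in (1, 2, 3, 4)]
            + [Constraint(1, 2, d_hh, ANGLE), Constraint(3, 4, d_hh, ANGLE)])
    group = ConstraintGroup(cons, np.arange(5))
    return group, masses, pos


class TestAngleConstraintDistance:
    @pytest.mark.parametrize("ab,bc,angle,expected", [
        (1.0, 1.0, 90.0, np.sqrt(2.0)),
        (0.9572, 0.9572, 104.52, 1.5139),
        (1.09, 1.09, 109.4712, 1.7799),
    ])
    def test_law_of_cosines(self, ab, bc, angle, expected):
        assert angle_constraint_distance(ab, bc, angle) == pytest.approx(
            expected, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            angle_constraint_distance(-1.0, 1.0, 90.0)
        with pytest.raises(ValueError):
            angle_constraint_distance(1.0, 1.0, 181.0)


class TestSelection:
    def test_methane_two_disjoint_pairs(self, methane, methane_constraints):
        top, _ = methane
        angles = [c for c in methane_constraints.constraints
                  if c.origin == ANGLE]
        assert len(angles) == 2
        covered = [c.atom_a for c in angles] + [c.atom_b for c in angles]
        assert len(set(covered)) == 4  # disjoint hydrogen pairs

    def test_methyl_triangle(self, ethane):
        top, _ = ethane
        cset = build_all_constraints(top)
        angles = [c for c in cset.constraints if c.origin == ANGLE]
        assert len(angles) == 6  # two CH3 triangles
        assert all(g.is_tetrahedron_case for g in cset.groups)

    def test_sp2_ch2_single_hh_constraint(self):
        top, _ = build_test_molecule("sp2_CH2")
        cset = build_all_constraints(top)
        angles = [c for c in cset.constraints if c.origin == ANGLE]
        assert len(angles) == 2  # one per =CH2 group
        for c in angles:
            assert top.is_hydrogen[c.atom_a] and top.is_hydrogen[c.atom_b]

    def test_hydroxyl_single_constraint(self):
        top, _ = build_test_molecule("ethanol")
        cset = build_all_constraints(top)
        oh_h = [i for i in range(top.n_atoms) if top.is_hydrogen[i]
                and any(top.elements[j] == "O" for j in top.adjacency[i])]
        assert len(oh_h) == 1
        angles = [c for c in cset.constraints if c.origin == ANGLE
                  and oh_h[0] in (c.atom_a, c.atom_b)]
        assert len(angles) == 1
        other = angles[0].atom_b if angles[0].atom_a == oh_h[0] \
            else angles[0].atom_a
        assert not top.is_hydrogen[other]

    def test_every_hydrogen_one_or_two_angle_constraints(self):
        """Beyond its bond, each hydrogen joins one or two constraints
        (hydroxyls next to methyls may legitimately get none)."""
        for name in ("methane", "ethane", "ammonium", "sp2_CH2",
                     "arginine_sidechain_analog", "capped_alanine_dipeptide"):
            top, _ = build_test_molecule(name)
            cset = build_all_constraints(top)
            count = {}
            for c in cset.constraints:
                if c.origin != ANGLE:
                    continue
                for a in (c.atom_a, c.atom_b):
                    if top.is_hydrogen[a]:
                        count[a] = count.get(a, 0) + 1
            for h in np.nonzero(top.is_hydrogen)[0]:
                assert 1 <= count.get(int(h), 0) <= 2, (name, h)

    def test_no_heavy_heavy_bond_constraint(self, ethane):
        top, _ = ethane
        cset = build_all_constraints(top)
        for c in cset.constraints:
            if c.origin == BOND:
                assert (top.is_hydrogen[c.atom_a]
                        or top.is_hydrogen[c.atom_b])

    def test_water_routed_to_settle(self, small_water_box):
        top, _ = small_water_box
        cset = build_all_constraints(top)
        assert len(cset.groups) == 0
        assert len(cset.settle_triads) == 27


class TestCouplingMatrix:
    def test_single_constraint_zero_matrix(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        g = ConstraintGroup([Constraint(0, 1, 1.0)], np.array([0, 1]))
        a = build_coupling_matrix(g, np.array([12.0, 1.0]), pos)
        assert a.shape == (1, 1) and a[0, 0] == 0.0

    def test_disjoint_constraints_zero_matrix(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0], [6.0, 0, 0]])
        g = ConstraintGroup([Constraint(0, 1, 1.0), Constraint(2, 3, 1.0)],
                            np.arange(4))
        a = build_coupling_matrix(g, np.ones(4), pos)
        assert np.all(a == 0.0)

    def test_shared_atom_pattern(self):
        """Water-like triangle: every constraint pair shares an atom."""
        geo = WaterGeometry()
        rc = geo.d_hh / 2
        h = np.sqrt(geo.d_oh ** 2 - rc ** 2)
        pos = np.array([[0.0, 0, 0], [-rc, -h, 0], [rc, -h, 0]])
        cons = [Constraint(0, 1, geo.d_oh), Constraint(0, 2, geo.d_oh),
                Constraint(1, 2, geo.d_hh)]
        g = ConstraintGroup(cons, np.arange(3))
        a = build_coupling_matrix(g, np.array([15.999, 1.008, 1.008]), pos)
        off = a[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) > 0.0)
        assert np.all(np.diag(a) == 0.0)

    def test_diagonal_exactly_zero(self):
        g, masses, pos = ch3_tetrahedron_group()
        a = build_coupling_matrix(g, masses, pos)
        assert np.all(np.diag(a) == 0.0)

    def test_degenerate_geometry_rejected(self):
        pos = np.zeros((2, 3))
        g = ConstraintGroup([Constraint(0, 1, 1.0)], np.array([0, 1]))
        with pytest.raises(ValueError, match="degenerate"):
            build_coupling_matrix(g, np.ones(2), pos)


class TestEigenvalues:
    def test_ch3_tetrahedron_gate_violated(self):
        g, masses, pos = ch3_tetrahedron_group()
        lam = max_abs_eigenvalue(build_coupling_matrix(g, masses, pos))
        assert lam == pytest.approx(1.35, abs=0.02)
        assert lam > 1.0

    def test_methane_scheme_inside_gate(self):
        g, masses, pos = methane_group()
        lam = max_abs_eigenvalue(build_coupling_matrix(g, masses, pos))
        assert lam == pytest.approx(0.82, abs=0.02)
        assert lam < 1.0

    def test_zero_matrix(self):
        assert max_abs_eigenvalue(np.zeros((3, 3))) == 0.0


class TestLincs:
    def test_satisfied_group_is_fixed_point(self):
        g, masses, pos = methane_group()
        steps = np.zeros_like(pos)
        out = lincs_apply(pos, steps, [g], masses)
        assert np.abs(out).max() < 1e-12

    def test_two_body_analytic_shake(self):
        """Stretched C–H: correction splits by inverse mass and restores the
        target length (closed-form two-body solution)."""
        pos = np.array([[0.0, 0, 0], [1.09, 0, 0]])
        masses = np.array([M_C, M_H])
        steps = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        g = ConstraintGroup([Constraint(0, 1, 1.09)], np.array([0, 1]))
        out = lincs_apply(pos, steps, [g], masses)
        new = pos + out
        assert np.linalg.norm(new[0] - new[1]) == pytest.approx(1.09,
                                                                abs=1e-9)
        w_c = (1 / M_C) / (1 / M_C + 1 / M_H)
        assert out[0, 0] == pytest.approx(0.1 * w_c, abs=1e-9)

    def test_tetrahedron_matches_dense_solver_oracle(self):
        """Exact 6×6 inversion path equals an independent dense solve of the
        same projection equations."""
        g, masses, pos = ch3_tetrahedron_group()
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 0.01, pos.shape)
        out = lincs_apply(pos, steps, [g], masses,
                          LincsParams(rotational_corrections=1))

        # oracle: one projection + one rotational correction via scipy solve
        import scipy.linalg

        pairs = np.array([(c.atom_a, c.atom_b) for c in g.constraints])
        d0 = np.array([c.target_distance for c in g.constraints])
        ia, ib = pairs[:, 0], pairs[:, 1]
        r_old = pos[ia] - pos[ib]
        l_old = np.linalg.norm(r_old, axis=1)
        u = r_old / l_old[:, None]
        invm = 1.0 / masses
        gram = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                v = 0.0
                for x, sx in ((ia[i], 1), (ib[i], -1)):
                    for y, sy in ((ia[j], 1), (ib[j], -1)):
                        if x == y:
                            v += sx * sy * invm[x] * (u[i] @ u[j])
                gram[i, j] = v
        ref = steps.copy()

        def project(target_proj):
            rhs = (np.einsum("ij,ij->i", u,
                             (pos[ia] + ref[ia]) - (pos[ib] + ref[ib]))
                   - target_proj)
            lam = scipy.linalg.solve(gram, rhs)
            for nn in range(6):
                ref[ia[nn]] -= invm[ia[nn]] * lam[nn] * u[nn]
                ref[ib[nn]] += invm[ib[nn]] * lam[nn] * u[nn]

        project(d0)
        l_new = np.linalg.norm((pos[ia] + ref[ia]) - (pos[ib] + ref[ib]),
                               axis=1)
        project(np.sqrt(np.maximum(2 * d0 ** 2 - l_new ** 2, 0.0)))
        assert np.abs(out - ref).max() < 1e-10

    def test_tolerance_after_corrections(self):
        """MD-step-scale violations reach the 1e-6 relative tolerance with
        the default order-8 series and three rotational corrections."""
        g, masses, pos = methane_group()
        rng = np.random.default_rng(5)
        steps = rng.normal(0, 1e-3, pos.shape)
        params = LincsParams()
        out = lincs_apply(pos, steps, [g], masses, params)
        new = pos + out
        for c in g.constraints:
            d = np.linalg.norm(new[c.atom_a] - new[c.atom_b])
            assert abs(d - c.target_distance) / c.target_distance \
                <= params.tolerance

    def test_gate_violation_raises(self):
        g, masses, pos = ch3_tetrahedron_group()
        g.is_tetrahedron_case = False
        with pytest.raises(LincsConvergenceError):
            lincs_apply(pos, np.zeros_like(pos) + 0.01, [g], masses)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_momentum_conserved_property(self, seed):
        """Mass-weighted correction displacements sum to zero per group."""
        g, masses, pos = methane_group()
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 0.02, pos.shape)
        out = lincs_apply(pos, steps, [g], masses)
        dp = (masses[:, None] * (out - steps)).sum(axis=0)
        assert np.abs(dp).max() < 1e-10

    def test_single_precision_emulation_distances_bounded(self):
        """Repeated float32-rounded applications do not walk away from the
        targets (the delta formulation keeps round-off from accumulating)."""
        g, masses, pos = methane_group()
        pos = pos + 100.0  # far from the origin, where float32 is coarse
        rng = np.random.default_rng(0)
        p = pos.astype(np.float32).astype(float)
        worst = 0.0
        for _ in range(10_000):
            steps = rng.normal(0, 1e-3, p.shape)
            steps = lincs_apply(p, steps.astype(np.float32).astype(float),
                                [g], masses)
            p = (p + steps).astype(np.float32).astype(float)
            for c in g.constraints:
                d = np.linalg.norm(p[c.atom_a] - p[c.atom_b])
                worst = max(worst,
                            abs(d - c.target_distance) / c.target_distance)
        assert worst < 1e-3


class TestSettle:
    geo = WaterGeometry()
    masses = np.array([15.999, 1.008, 1.008])

    def canonical(self):
        rc = self.geo.d_hh / 2
        h = np.sqrt(self.geo.d_oh ** 2 - rc ** 2)
        return np.array([[0.0, 0, 0], [-rc, -h, 0], [rc, -h, 0]])

    def dists(self, p):
        return (np.linalg.norm(p[0] - p[1]), np.linalg.norm(p[0] - p[2]),
                np.linalg.norm(p[1] - p[2]))

    def test_distances_exact_after_random_step(self):
        pos = self.canonical()
        rng = np.random.default_rng(1)
        steps = rng.normal(0, 0.05, (3, 3))
        out = settle_apply(pos, steps, [[0, 1, 2]], self.masses, self.geo)
        d = self.dists(pos + out)
        assert d[0] == pytest.approx(self.geo.d_oh, rel=1e-9)
        assert d[1] == pytest.approx(self.geo.d_oh, rel=1e-9)
        assert d[2] == pytest.approx(self.geo.d_hh, rel=1e-9)

    def test_rigid_body_motion_preserves_distances(self):
        """A small rigid rotation+translation already satisfies the
        constraints and passes through unchanged."""
        from scipy.spatial.transform import Rotation

        pos = self.canonical() + 5.0
        rot = Rotation.from_rotvec(np.radians(3.0) * np.array(
            [0.6, 0.0, 0.8])).as_matrix()
        com = (self.masses[:, None] * pos).sum(0) / self.masses.sum()
        steps = (pos - com) @ rot.T + com + 0.05 - pos
        out = settle_apply(pos, steps, [[0, 1, 2]], self.masses, self.geo)
        assert np.abs(out - steps).max() < 1e-12

    def test_matches_iterative_oracle_for_small_steps(self):
        """MD-step-sized perturbations: analytic result equals the
        tightly converged iterative solution to 1e-6 Å."""
        pos = self.canonical()
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 2e-4, (3, 3))
        out = settle_apply(pos, steps, [[0, 1, 2]], self.masses, self.geo)
        ref = steps.copy()
        _shake_triad(pos, ref, [0, 1, 2], self.masses, self.geo,
                     iters=200_000, tol=1e-15)
        assert np.abs(out - ref).max() < 1e-6

    def test_momentum_conserved(self):
        pos = self.canonical()
        rng = np.random.default_rng(7)
        steps = rng.normal(0, 0.05, (3, 3))
        out = settle_apply(pos, steps, [[0, 1, 2]], self.masses, self.geo)
        dp = (self.masses[:, None] * (out - steps)).sum(axis=0)
        assert np.abs(dp).max() < 1e-10

    def test_vectorized_over_many_waters(self):
        top, state = build_water_box(3, seed=9)
        cset = build_all_constraints(top)
        rng = np.random.default_rng(2)
        steps = rng.normal(0, 0.01, state.positions.shape)
        out = settle_apply(state.positions, steps, cset.settle_triads,
                           top.masses, cset.water_geometry)
        new = state.positions + out
        geo = cset.water_geometry
        for o, h1, h2 in cset.settle_triads:
            assert np.linalg.norm(new[o] - new[h1]) == pytest.approx(
                geo.d_oh, rel=1e-9)
            assert np.linalg.norm(new[h1] - new[h2]) == pytest.approx(
                geo.d_hh, rel=1e-9)
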