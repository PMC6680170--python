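"""Holonomic distance constraints: selection, coupling analysis, LINCS, SETTLE.

Bonds involving hydrogens are always constrained; bonds between heavy atoms
are deliberately left flexible (they are integrated with the small bonded
time step and are uncritical there), which keeps the constraint coupling
matrix sparse.  Selected hydrogen *angles* are additionally constrained as
distances via the law of cosines, chosen by a recursive heuristic such that
every coupled-constraint group can still be solved with the truncated LINCS
power series — all absolute eigenvalues of the zero-diagonal simplified
coupling matrix stay below 1.  The one systematic exception is a heavy atom
carrying three hydrogens (–CH3, –NH3+): its six constraints form a
tetrahedron whose largest eigenvalue exceeds 1, so that group is flagged and
solved by inverting the 6x6 matrix exactly.  Rigid three-site waters are
routed to the analytic SETTLE solver instead.

LINCS here operates on *steps* (displacements to the new positions) rather
than absolute new coordinates: only the steps are corrected and the addition
to the old positions happens once at the end, which preserves precision when
coordinates are stored in single precision far from the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BOND = "BOND"
ANGLE = "ANGLE"


class LincsConvergenceError(RuntimeError):
    """A non-tetrahedron group has a coupling eigenvalue >= 1."""


@dataclass(frozen=True)
class Constraint:
    atom_a: int
    atom_b: int
    target_distance: float
    origin: str = BOND  # BOND or ANGLE

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError("constraint endpoints must differ")
        if self.target_distance <= 0:
            raise ValueError("constraint target distance must be positive")


@dataclass
class ConstraintGroup:
    """Connected component of the constraint-sharing graph."""

    constraints: list[Constraint]
    atom_ids: np.ndarray
    is_tetrahedron_case: bool = False


@dataclass
class LincsParams:
    expansion_order: int = 8
    rotational_corrections: int = 3
    tolerance: float = 1e-6

    def __post_init__(self):
        if self.expansion_order < 1 or self.rotational_corrections < 1:
            raise ValueError("expansion order and corrections must be >= 1")


@dataclass
class WaterGeometry:
    """Rigid 3-site water targets (Å)."""

    d_oh: float = 0.9572
    d_hh: float = 1.5139006585152397  # law of cosines at 104.52 deg

    @classmethod
    def from_bond_angle(cls, d_oh: float, angle_deg: float) -> "WaterGeometry":
        return cls(d_oh=d_oh, d_hh=angle_constraint_distance(d_oh, d_oh, angle_deg))


@dataclass
class ConstraintSet:
    """All constraints of a system: LINCS groups plus SETTLE water triads."""

    constraints: list[Constraint] = field(default_factory=list)
    groups: list[ConstraintGroup] = field(default_factory=list)
    settle_triads: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=int))
    water_geometry: WaterGeometry = field(default_factory=WaterGeometry)

    @property
    def n_constraints_total(self) -> int:
        return len(self.constraints) + 3 * len(self.settle_triads)

    def constraints_per_molecule(self, topology) -> dict[int, int]:
        labels = topology.molecule_id
        counts: dict[int, int] = {}
        for c in self.constraints:
            lab = int(labels[c.atom_a])
            counts[lab] = counts.get(lab, 0) + 1
        for triad in self.settle_triads:
            lab = int(labels[triad[0]])
            counts[lab] = counts.get(lab, 0) + 3
        return counts

    def all_pairs(self) -> np.ndarray:
        """(n, 2) array of every constrained atom pair (LINCS + SETTLE)."""
        pairs = [(c.atom_a, c.atom_b) for c in self.constraints]
        for o, h1, h2 in self.settle_triads:
            pairs += [(o, h1), (o, h2), (h1, h2)]
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def all_targets(self) -> np.ndarray:
        t = [c.target_distance for c in self.constraints]
        g = self.water_geometry
        for _ in range(len(self.settle_triads)):
            t += [g.d_oh, g.d_oh, g.d_hh]
        return np.array(t)


# ---------------------------------------------------------------------------
# constraint targets and selection
# ---------------------------------------------------------------------------

def angle_constraint_distance(ab: float, bc: float, angle_abc_deg: float) -> float:
    """A–C distance that freezes the angle A–B–C (law of cosines).

    ``ab`` and ``bc`` are the equilibrium bond lengths, ``angle_abc_deg`` the
    equilibrium angle in degrees.
    """
    if ab <= 0 or bc <= 0:
        raise ValueError("bond lengths must be positive")
    if not 0.0 < angle_abc_deg < 180.0:
        raise ValueError("angle must be in (0, 180) degrees")
    ang = np.radians(angle_abc_deg)
    return float(np.sqrt(ab * ab + bc * bc - 2.0 * ab * bc * np.cos(ang)))


class _AngleSelector:
    """Recursive hydrogen-angle selection.

    Ports the published heuristic: atoms are analyzed once (``done`` table);
    the traversal starts at methyl-like groups, then hydroxyls, then walks
    along CH2 chains, so that every hydrogen ends up with one or two angle
    constraints while coupled groups stay small and series-solvable.
    Tie-breaks among equally scored candidate partners go to the lowest
    atom id.
    """

    def __init__(self, topology, skip_atoms=frozenset()):
        self.top = topology
        self.adj = topology.adjacency
        self.skip = skip_atoms
        self.done = np.zeros(topology.n_atoms, dtype=bool)
        self.done[list(skip_atoms)] = True
        self.constraints: list[Constraint] = []
        self._by_center: dict[int, list[tuple[int, int]]] = {}
        self._endpoint_count: dict[int, int] = {}
        self._bond_r0 = {}
        for (a, b), r0 in zip(topology.bonds, topology.bond_r0):
            self._bond_r0[(int(a), int(b))] = float(r0)
            self._bond_r0[(int(b), int(a))] = float(r0)
        self._angle_theta0 = {}
        for (a, b, c), t0 in zip(topology.angles, topology.angle_theta0):
            self._angle_theta0[(int(a), int(b), int(c))] = float(t0)
            self._angle_theta0[(int(c), int(b), int(a))] = float(t0)

    # -- helpers -----------------------------------------------------------

    def hydrogens_of(self, atm: int) -> list[int]:
        return [n for n in self.adj[atm] if self.top.is_hydrogen[n]]

    def n_hydrogens(self, atm: int) -> int:
        return len(self.hydrogens_of(atm))

    def n_bonds(self, atm: int) -> int:
        return len(self.adj[atm])

    def heavy_neighbors(self, atm: int) -> list[int]:
        return [n for n in self.adj[atm] if not self.top.is_hydrogen[n]]

    def has_centered_constraint(self, endpoint: int, center: int) -> bool:
        return any(endpoint in pair for pair in self._by_center.get(center, []))

    def fix_angle(self, a: int, b: int, c: int) -> None:
        """Constrain the angle a–b–c by fixing the a–c distance."""
        r_ab = self._bond_r0.get((a, b))
        r_bc = self._bond_r0.get((b, c))
        theta = self._angle_theta0.get((a, b, c))
        if r_ab is None or r_bc is None:
            raise KeyError(f"missing equilibrium bond length for angle "
                           f"{a}-{b}-{c}")
        if theta is None:
            raise KeyError(f"missing equilibrium angle for term {a}-{b}-{c}")
        d = angle_constraint_distance(r_ab, r_bc, theta)
        self.constraints.append(Constraint(a, c, d, origin=ANGLE))
        self._by_center.setdefault(b, []).append((a, c))
        self._endpoint_count[a] = self._endpoint_count.get(a, 0) + 1
        self._endpoint_count[c] = self._endpoint_count.get(c, 0) + 1

    @staticmethod
    def _best(candidates: list[tuple[float, int]]):
        """Highest score, ties broken by lowest atom id."""
        if not candidates:
            return None
        return min(candidates, key=lambda t: (-t[0], t[1]))[1]

    # -- the recursive core ------------------------------------------------

    def analyze(self, atm: int, lastatm: int | None = None) -> None:
        if self.done[atm]:
            return
        self.done[atm] = True
        nextatm: int | None = None
        hyd = self.hydrogens_of(atm)
        n_h = len(hyd)

        if n_h == 4:
            # methane-like: two constraints over disjoint hydrogen pairs
            self.fix_angle(hyd[0], atm, hyd[1])
            self.fix_angle(hyd[2], atm, hyd[3])

        if n_h == 3:
            # CH3/NH3-like: triangle of three constraints (tetrahedron group)
            self.fix_angle(hyd[0], atm, hyd[1])
            self.fix_angle(hyd[1], atm, hyd[2])
            self.fix_angle(hyd[2], atm, hyd[0])
            heavies = self.heavy_neighbors(atm)
            nextatm = min(heavies) if heavies else None
            if (nextatm is not None and self.n_hydrogens(nextatm) <= 1
                    and self.n_bonds(nextatm) > 3):
                nextatm = None

        if n_h == 2:
            if self.n_bonds(atm) > 3:
                # sp3 CH2: constrain both hydrogens to the best next heavy atom
                cands = []
                for nb in self.heavy_neighbors(atm):
                    if nb == lastatm or self.n_hydrogens(nb) >= 3:
                        continue
                    if self.has_centered_constraint(atm, nb):
                        continue
                    nbh = self.n_hydrogens(nb)
                    if nbh == 2:
                        score = 3
                    elif nbh == 0:
                        score = 2
                    elif nbh == 1 and self.n_bonds(nb) == 3:
                        score = 1
                    else:
                        score = 0
                    cands.append((float(score), nb))
                nextatm = self._best(cands)
            if nextatm is not None:
                self.fix_angle(hyd[0], atm, nextatm)
                self.fix_angle(hyd[1], atm, nextatm)
                if (self.n_hydrogens(nextatm) <= 1
                        and self.n_bonds(nextatm) > 3):
                    nextatm = None
            else:
                # sp2 =CH2 (or nothing suitable found): couple the two H
                self.fix_angle(hyd[0], atm, hyd[1])

        if n_h == 1:
            cands = []
            for nb in self.heavy_neighbors(atm):
                if self.n_hydrogens(nb) >= 3:
                    continue
                score = -(self.n_hydrogens(nb)
                          + self._endpoint_count.get(nb, 0)) * 4.0
                if nb == lastatm or self.has_centered_constraint(atm, nb):
                    score -= 20.0
                if self.top.residue_ids[nb] != self.top.residue_ids[atm]:
                    score -= 10.0
                cands.append((score, nb))
            nextatm = self._best(cands)
            if nextatm is not None:
                self.fix_angle(hyd[0], atm, nextatm)

        if nextatm is not None:
            self.analyze(nextatm, atm)


def select_angle_constraints(topology, skip_atoms=frozenset()) -> list[Constraint]:
    """Choose which hydrogen angles to constrain.

    The driver calls the recursive analysis in six phases: first methyl-like
    atoms (three bound hydrogens), then hydroxyl/thiol-like atoms (one
    hydrogen, two bonds), then CH2 atoms adjacent to single-hydrogen atoms,
    then the remaining CH2 chains, then CH atoms in chains/rings, and finally
    everything else.  Within a phase, atoms are visited in ascending id.
    """
    sel = _AngleSelector(topology, skip_atoms=skip_atoms)

    def n_h(a):
        return sel.n_hydrogens(a)

    def neighbor_h_counts(a):
        return [n_h(nb) for nb in sel.heavy_neighbors(a)]

    atoms = [a for a in range(topology.n_atoms)
             if not topology.is_hydrogen[a] and a not in skip_atoms]
    phases = [
        lambda a: n_h(a) == 3,
        lambda a: n_h(a) == 1 and sel.n_bonds(a) == 2,
        lambda a: (n_h(a) == 2
                   and sum(1 for c in neighbor_h_counts(a) if c == 1) >= 1
                   and sum(1 for c in neighbor_h_counts(a) if c == 2) <= 1),
        lambda a: (n_h(a) == 2
                   and sum(1 for c in neighbor_h_counts(a) if c == 2) <= 1),
        lambda a: (n_h(a) == 1
                   and sum(1 for c in neighbor_h_counts(a) if c == 1) <= 1),
        lambda a: True,
    ]
    for phase in phases:
        for a in atoms:
            if not sel.done[a] and phase(a):
                sel.analyze(a, None)
    return sel.constraints


def build_all_constraints(topology,
                          water_geometry: WaterGeometry | None = None
                          ) -> ConstraintSet:
    """Constrain all X–H bonds plus selected hydrogen angles.

    Heavy-atom–heavy-atom bonds are never constrained.  Rigid 3-site waters
    are routed to SETTLE and excluded from the LINCS groups.  The returned
    groups are the connected components of the constraint-sharing graph.
    """
    is_h = topology.is_hydrogen
    water_atoms: set[int] = set()
    triads = []
    for mol in topology.molecules:
        if len(mol) == 3 and topology.is_water[mol].all():
            heavy = [int(a) for a in mol if not is_h[a]]
            hyds = [int(a) for a in mol if is_h[a]]
            if len(heavy) == 1 and len(hyds) == 2:
                triads.append((heavy[0], hyds[0], hyds[1]))
                water_atoms.update(int(a) for a in mol)
    constraints: list[Constraint] = []
    for (a, b), r0 in zip(topology.bonds, topology.bond_r0):
        a, b = int(a), int(b)
        if a in water_atoms:
            continue
        if is_h[a] or is_h[b]:
            if not np.isfinite(r0) or r0 <= 0:
                raise ValueError(f"missing equilibrium length for bond {a}-{b}")
            constraints.append(Constraint(min(a, b), max(a, b), float(r0),
                                          origin=BOND))
    constraints.extend(
        select_angle_constraints(topology, skip_atoms=frozenset(water_atoms)))

    groups = _group_constraints(constraints, is_h)
    if water_geometry is None:
        water_geometry = _water_geometry_from_topology(topology, triads)
    return ConstraintSet(constraints=constraints, groups=groups,
                         settle_triads=np.array(triads, dtype=int).reshape(-1, 3),
                         water_geometry=water_geometry)


def _water_geometry_from_topology(topology, triads) -> WaterGeometry:
    if not triads:
        return WaterGeometry()
    o, h1, _ = triads[0]
    r0 = {}
    for (a, b), r in zip(topology.bonds, topology.bond_r0):
        r0[(int(a), int(b))] = float(r)
        r0[(int(b), int(a))] = float(r)
    d_oh = r0.get((o, h1), 0.9572)
    theta = None
    for (a, b, c), t in zip(topology.angles, topology.angle_theta0):
        if int(b) == o:
            theta = float(t)
            break
    return WaterGeometry.from_bond_angle(d_oh, theta if theta else 104.52)


def _group_constraints(constraints: list[Constraint], is_h) -> list[ConstraintGroup]:
    parent: dict[int, int] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for c in constraints:
        union(c.atom_a, c.atom_b)
    buckets: dict[int, list[Constraint]] = {}
    for c in constraints:
        buckets.setdefault(find(c.atom_a), []).append(c)
    groups = []
    for root in sorted(buckets, key=lambda r: min(min(c.atom_a, c.atom_b)
                                                  for c in buckets[r])):
        cons = buckets[root]
        atoms = np.array(sorted({a for c in cons for a in (c.atom_a, c.atom_b)}))
        groups.append(ConstraintGroup(
            constraints=cons, atom_ids=atoms,
            is_tetrahedron_case=_is_tetrahedron(cons, atoms, is_h)))
    return groups


def _is_tetrahedron(cons: list[Constraint], atoms: np.ndarray, is_h) -> bool:
    """Central heavy atom with three bound hydrogens: 3 bonds + 3 angles."""
    if len(cons) != 6 or len(atoms) != 4:
        return False
    heavy = [a for a in atoms if not is_h[a]]
    hyds = [a for a in atoms if is_h[a]]
    if len(heavy) != 1 or len(hyds) != 3:
        return False
    n_bond = sum(1 for c in cons if c.origin == BOND)
    return n_bond == 3


# ---------------------------------------------------------------------------
# coupling matrix analysis
# ---------------------------------------------------------------------------

def build_coupling_matrix(group: ConstraintGroup, masses: np.ndarray,
                          positions: np.ndarray) -> np.ndarray:
    """Zero-diagonal simplified LINCS coupling matrix A.

    With the constraint gradient matrix B (rows are ± unit direction vectors
    placed at the two constrained atoms) and S = diag(1/sqrt(1/m_a + 1/m_b)),
    A = I − S B M⁻¹ Bᵀ S.  Element (n, m) is nonzero iff constraints n and m
    share an atom; the diagonal is exactly zero.  Directions are taken from
    ``positions`` (conventionally the equilibrium geometry: the spectrum used
    to gate solvability is treated as a topology property).
    """
    cons = group.constraints
    n = len(cons)
    pairs = np.array([(c.atom_a, c.atom_b) for c in cons])
    d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    lengths = np.linalg.norm(d, axis=1)
    if np.any(lengths < 1e-10):
        raise ValueError("degenerate geometry: zero-length constraint direction")
    u = d / lengths[:, None]
    invm = 1.0 / masses
    gram = np.zeros((n, n))
    for i in range(n):
        ai, bi = pairs[i]
        for j in range(i, n):
            aj, bj = pairs[j]
            v = 0.0
            for atom, si in ((ai, 1.0), (bi, -1.0)):
                for atom2, sj in ((aj, 1.0), (bj, -1.0)):
                    if atom == atom2:
                        v += si * sj * invm[atom] * float(u[i] @ u[j])
            gram[i, j] = gram[j, i] = v
    s = 1.0 / np.sqrt(np.diag(gram))
    a = np.eye(n) - (s[:, None] * gram * s[None, :])
    np.fill_diagonal(a, 0.0)
    return a


def max_abs_eigenvalue(matrix: np.ndarray) -> float:
    """Largest absolute eigenvalue; gates the series-inversion path."""
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


# ---------------------------------------------------------------------------
# LINCS solver (step formulation)
# ---------------------------------------------------------------------------

def lincs_apply(old_positions: np.ndarray, steps: np.ndarray,
                groups: list[ConstraintGroup], masses: np.ndarray,
                params: LincsParams | None = None) -> np.ndarray:
    """Correct integration steps so all constraints are satisfied.

    For ordinary groups the coupling matrix is inverted with the truncated
    power series (1−A)⁻¹ ≈ 1+A+…+A^order, valid only while max|λ| < 1;
    tetrahedron groups invert the 6x6 matrix exactly, and the same inverse is
    reused for the initial projection and every rotational-lengthening
    correction.  Only ``steps`` is modified; the caller adds the result to
    ``old_positions`` once at the end.
    """
    if params is None:
        params = LincsParams()
    steps = np.array(steps, dtype=float, copy=True)
    for group in groups:
        _lincs_group(old_positions, steps, group, masses, params)
    return steps


def _lincs_group(old_pos, steps, group, masses, params):
    cons = group.constraints
    n = len(cons)
    pairs = np.array([(c.atom_a, c.atom_b) for c in cons])
    d0 = np.array([c.target_distance for c in cons])
    ia, ib = pairs[:, 0], pairs[:, 1]
    r_old = old_pos[ia] - old_pos[ib]
    l_old = np.linalg.norm(r_old, axis=1)
    u = r_old / l_old[:, None]
    invm = 1.0 / masses
    s = 1.0 / np.sqrt(invm[ia] + invm[ib])
    a = build_coupling_matrix(group, masses, old_pos)

    if group.is_tetrahedron_case:
        inv = np.linalg.inv(np.eye(n) - a)

        def solve(rhs):
            return inv @ rhs
    else:
        lam = max_abs_eigenvalue(a)
        if lam >= 1.0:
            raise LincsConvergenceError(
                f"constraint group with max|eigenvalue| = {lam:.3f} >= 1 is "
                "not series-solvable and is not a flagged tetrahedron case; "
                "this indicates a constraint-selection bug upstream")

        def solve(rhs):
            y = rhs.copy()
            t = rhs
            for _ in range(params.expansion_order):
                t = a @ t
                y = y + t
            return y

    def apply_correction(lagrange):
        f = (s * lagrange)[:, None] * u
        np.add.at(steps, ia, -invm[ia, None] * f)
        np.add.at(steps, ib, invm[ib, None] * f)

    # initial projection: enforce u·(r_old + Δstep) = d0
    g = np.einsum("ij,ij->i", u, steps[ia] - steps[ib]) + l_old - d0
    apply_correction(solve(s * g))

    # rotational lengthening corrections: project to the target length along
    # the old direction, accounting for the perpendicular component picked up
    # by the rotation.  With proj = u·r this generalizes the classic
    # sqrt(2·d0² − l²) target (identical to leading order when proj ≈ d0)
    # and converges monotonically under repetition.
    for _ in range(params.rotational_corrections):
        r_new = (old_pos[ia] + steps[ia]) - (old_pos[ib] + steps[ib])
        l_new = np.linalg.norm(r_new, axis=1)
        proj = np.einsum("ij,ij->i", u, r_new)
        perp2 = np.maximum(l_new * l_new - proj * proj, 0.0)
        p = np.sqrt(np.maximum(d0 * d0 - perp2, 0.0))
        apply_correction(solve(s * (proj - p)))


# ---------------------------------------------------------------------------
# SETTLE (analytic rigid three-site water)
# ---------------------------------------------------------------------------

def settle_apply(old_positions: np.ndarray, steps: np.ndarray,
                 triads: np.ndarray, masses: np.ndarray,
                 geometry: WaterGeometry | None = None) -> np.ndarray:
    """Analytic constraint of rigid 3-site waters; returns corrected steps.

    ``triads`` is (n_waters, 3) with the oxygen first.  The old positions
    must satisfy the geometry; the corrected new positions satisfy all three
    distances exactly (non-iterative).  Degenerate (collinear) inputs fall
    back to an iterative solve and are logged.
    """
    if geometry is None:
        geometry = WaterGeometry()
    triads = np.asarray(triads, dtype=int).reshape(-1, 3)
    steps = np.array(steps, dtype=float, copy=True)
    if len(triads) == 0:
        return steps
    io, ih1, ih2 = triads[:, 0], triads[:, 1], triads[:, 2]
    m_o = masses[io][:, None]
    m_h = masses[ih1][:, None]
    m_tot = m_o + 2.0 * m_h

    rc = geometry.d_hh / 2.0
    height = np.sqrt(geometry.d_oh ** 2 - rc ** 2)
    # distances of O and H from the center of mass along the triangle height
    ra = 2.0 * masses[ih1][:, None] * height / (m_o + 2.0 * m_h)
    rb = height - ra

    a0, b0, c0 = old_positions[io], old_positions[ih1], old_positions[ih2]
    a1 = a0 + steps[io]
    b1 = b0 + steps[ih1]
    c1 = c0 + steps[ih2]

    com = (m_o * a1 + m_h * b1 + m_h * c1) / m_tot
    a1r, b1r, c1r = a1 - com, b1 - com, c1 - com
    b0r, c0r = b0 - a0, c0 - a0

    n0 = np.cross(b0r, c0r)
    n0n = np.linalg.norm(n0, axis=1, keepdims=True)
    n1 = np.cross(a1r, n0)
    n1n = np.linalg.norm(n1, axis=1, keepdims=True)
    degenerate = (n0n[:, 0] < 1e-10) | (n1n[:, 0] < 1e-10)
    n0 = n0 / np.where(n0n > 0, n0n, 1.0)
    n1 = n1 / np.where(n1n > 0, n1n, 1.0)
    n2 = np.cross(n0, n1)

    def to_prime(v):
        return np.stack([np.einsum("ij,ij->i", n1, v),
                         np.einsum("ij,ij->i", n2, v),
                         np.einsum("ij,ij->i", n0, v)], axis=1)

    a1p, b1p, c1p = to_prime(a1r), to_prime(b1r), to_prime(c1r)
    b0p, c0p = to_prime(b0r), to_prime(c0r)

    sinphi = np.clip(a1p[:, 2:3] / ra, -1.0, 1.0)
    cosphi = np.sqrt(1.0 - sinphi ** 2)
    sinpsi = np.clip((b1p[:, 2:3] - c1p[:, 2:3]) / (2.0 * rc * np.maximum(cosphi, 1e-12)),
                     -1.0, 1.0)
    cospsi = np.sqrt(1.0 - sinpsi ** 2)

    ya2 = ra * cosphi
    xb2 = -rc * cospsi
    t1 = -rb * cosphi
    yb2 = t1 - rc * sinpsi * sinphi
    yc2 = t1 + rc * sinpsi * sinphi

    alpha = (xb2[:, 0] * (b0p[:, 0] - c0p[:, 0])
             + b0p[:, 1] * yb2[:, 0] + c0p[:, 1] * yc2[:, 0])
    beta = (xb2[:, 0] * (c0p[:, 1] - b0p[:, 1])
            + b0p[:, 0] * yb2[:, 0] + c0p[:, 0] * yc2[:, 0])
    gamma = (b0p[:, 0] * b1p[:, 1] - b1p[:, 0] * b0p[:, 1]
             + c0p[:, 0] * c1p[:, 1] - c1p[:, 0] * c0p[:, 1])
    al2be2 = alpha ** 2 + beta ** 2
    under = np.maximum(al2be2 - gamma ** 2, 0.0)
    sinthe = np.clip((alpha * gamma - beta * np.sqrt(under)) / al2be2, -1.0, 1.0)
    costhe = np.sqrt(1.0 - sinthe ** 2)
    sinthe = sinthe[:, None]
    costhe = costhe[:, None]

    a3 = np.concatenate([-ya2 * sinthe, ya2 * costhe, a1p[:, 2:3]], axis=1)
    b3 = np.concatenate([xb2 * costhe - yb2 * sinthe,
                         xb2 * sinthe + yb2 * costhe, b1p[:, 2:3]], axis=1)
    c3 = np.concatenate([-xb2 * costhe - yc2 * sinthe,
                         -xb2 * sinthe + yc2 * costhe, c1p[:, 2:3]], axis=1)

    def from_prime(v):
        return (v[:, 0:1] * n1 + v[:, 1:2] * n2 + v[:, 2:3] * n0)

    new_a = com + from_prime(a3)
    new_b = com + from_prime(b3)
    new_c = com + from_prime(c3)

    steps[io] = new_a - a0
    steps[ih1] = new_b - b0
    steps[ih2] = new_c - c0

    if np.any(degenerate):
        logger.warning("SETTLE: %d degenerate waters, falling back to "
                       "iterative solve", int(np.sum(degenerate)))
        for w in np.nonzero(degenerate)[0]:
            _shake_triad(old_positions, steps, triads[w], masses, geometry)
    return steps


def _shake_triad(old_pos, steps, triad, masses, geometry, iters=500, tol=1e-10):
    """Iterative two-atom-at-a-time fallback for degenerate SETTLE input."""
    o, h1, h2 = (int(x) for x in triad)
    pairs = [(o, h1, geometry.d_oh), (o, h2, geometry.d_oh),
             (h1, h2, geometry.d_hh)]
    for _ in range(iters):
        worst = 0.0
        for a, b, d0 in pairs:
            r = (old_pos[a] + steps[a]) - (old_pos[b] + steps[b])
            l = np.linalg.norm(r)
            diff = (l - d0) / d0
            worst = max(worst, abs(diff))
            g = (l * l - d0 * d0) / (2.0 * l * l)
            w = 1.0 / masses[a] + 1.0 / masses[b]
            corr = g * r / w
            steps[a] -= corr / masses[a]
            steps[b] += corr / masses[b]
        if worst < tol:
            break


def remove_constraint_velocities(velocities: np.ndarray, positions: np.ndarray,
                                 pairs: np.ndarray, masses: np.ndarray,
                                 iters: int = 50) -> np.ndarray:
    """Project out velocity components along constrained directions (RATTLE-
    style iteration); used to clean up freshly drawn random velocities."""
    v = np.array(velocities, dtype=float, copy=True)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if len(pairs) == 0:
        return v
    ia, ib = pairs[:, 0], pairs[:, 1]
    invm = 1.0 / masses
    r = positions[ia] - positions[ib]
    u = r / np.linalg.norm(r, axis=1)[:, None]
    w = invm[ia] + invm[ib]
    for _ in range(iters):
        rel = np.einsum("ij,ij->i", u, v[ia] - v[ib])
        lam = rel / w
        np.add.at(v, ia, -(lam * invm[ia])[:, None] * u)
        np.add.at(v, ib, (lam * invm[ib])[:, None] * u)
    return v


def constraint_report(constraint_set: ConstraintSet, masses: np.ndarray,
                      positions: np.ndarray):
    """Per-group TSV-ready report: atoms, targets, max|λ|, solver path."""
    import pandas as pd

    rows = []
    for gi, g in enumerate(constraint_set.groups):
        lam = max_abs_eigenvalue(build_coupling_matrix(g, masses, positions))
        path = "exact-6x6" if g.is_tetrahedron_case else "series"
        rows.append({
            "group": gi,
            "n_constraints": len(g.constraints),
            "atoms": ",".join(str(a) for a in g.atom_ids),
            "targets": ",".join(f"{c.target_distance:.4f}"
                                for c in g.constraints),
            "max_abs_eigenvalue": round(lam, 4),
            "solver": path,
        })
    for triad in constraint_set.settle_triads:
        rows.append({
            "group": "water",
            "n_constraints": 3,
            "atoms": ",".join(str(a) for a in triad),
            "targets": (f"{constraint_set.water_geometry.d_oh:.4f},"
                        f"{constraint_set.water_geometry.d_oh:.4f},"
                        f"{constraint_set.water_geometry.d_hh:.4f}"),
            "max_abs_eigenvalue": float("nan"),
            "solver": "settle",
        })
    return pd.DataFrame(rows)
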