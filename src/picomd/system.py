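"""Topology and dynamic state of a molecular system.

A :class:`Topology` holds the static description — atoms, bonded terms,
exclusions and the partition of atoms into molecules (connected components of
the bond graph).  A :class:`SystemState` holds positions, velocities, the
periodic cell and the current time.  Molecules are classified for the mixed
integrator into those that are fully rigid after constraining (propagated
with one large step) and those that retain internal flexibility (propagated
with the small-step impulse scheme).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .cell import TriclinicCell


class IntegrationClass(enum.Enum):
    SINGLE_STEP = "single_step"
    MULTI_STEP = "multi_step"


@dataclass
class Atom:
    """Single-atom view into a topology."""

    id: int
    element: str
    mass: float
    charge: float
    lj_sigma: float
    lj_epsilon: float
    molecule_id: int
    is_water: bool
    is_hydrogen: bool
    name: str = ""
    residue_id: int = 0
    residue_name: str = ""


class Topology:
    """Static molecular description with array-backed storage.

    Bonded terms use the conventional force-field forms: harmonic bonds
    ``0.5*k*(r-r0)²`` (k in kJ/mol/Å²), harmonic angles ``0.5*k*(θ-θ0)²``
    (θ0 in degrees, k in kJ/mol/rad²) and periodic cosine dihedrals
    ``k*(1+cos(n·φ-γ))``.
    """

    def __init__(self, elements, masses, charges=None, lj_sigma=None,
                 lj_epsilon=None, names=None, residue_ids=None,
                 residue_names=None, is_water=None):
        n = len(elements)
        self.elements = [str(e).capitalize() if len(str(e)) > 1 else str(e).upper()
                         for e in elements]
        self.masses = np.asarray(masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive "
                             "(no massless/virtual sites)")
        self.charges = np.zeros(n) if charges is None else np.asarray(charges, float)
        self.lj_sigma = np.ones(n) if lj_sigma is None else np.asarray(lj_sigma, float)
        self.lj_epsilon = (np.zeros(n) if lj_epsilon is None
                           else np.asarray(lj_epsilon, float))
        self.names = list(names) if names is not None else list(self.elements)
        self.residue_ids = (np.zeros(n, dtype=int) if residue_ids is None
                            else np.asarray(residue_ids, dtype=int))
        self.residue_names = (list(residue_names) if residue_names is not None
                              else ["UNK"] * n)
        self.is_water = (np.zeros(n, dtype=bool) if is_water is None
                         else np.asarray(is_water, dtype=bool))
        self.is_hydrogen = np.array([e.upper() == "H" for e in self.elements])

        self.bonds = np.zeros((0, 2), dtype=int)
        self.bond_r0 = np.zeros(0)
        self.bond_k = np.zeros(0)
        self.angles = np.zeros((0, 3), dtype=int)
        self.angle_theta0 = np.zeros(0)
        self.angle_k = np.zeros(0)
        self.dihedrals = np.zeros((0, 4), dtype=int)
        self.dihedral_k = np.zeros(0)
        self.dihedral_n = np.zeros(0, dtype=int)
        self.dihedral_phase = np.zeros(0)
        self.metadata: dict = {}
        self._invalidate()

    # -- construction ------------------------------------------------------

    def set_bonds(self, bonds, r0, k):
        bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
        self._check_ids(bonds)
        self.bonds = np.sort(bonds, axis=1)
        self.bond_r0 = np.asarray(r0, dtype=float)
        self.bond_k = np.asarray(k, dtype=float)
        self._invalidate()

    def set_angles(self, angles, theta0_deg, k):
        angles = np.asarray(angles, dtype=int).reshape(-1, 3)
        self._check_ids(angles)
        self.angles = angles
        self.angle_theta0 = np.asarray(theta0_deg, dtype=float)
        self.angle_k = np.asarray(k, dtype=float)
        self._invalidate()

    def set_dihedrals(self, dihedrals, k, n, phase_deg):
        dihedrals = np.asarray(dihedrals, dtype=int).reshape(-1, 4)
        self._check_ids(dihedrals)
        self.dihedrals = dihedrals
        self.dihedral_k = np.asarray(k, dtype=float)
        self.dihedral_n = np.asarray(n, dtype=int)
        self.dihedral_phase = np.asarray(phase_deg, dtype=float)
        self._invalidate()

    def _check_ids(self, idx):
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise ValueError("bonded term references invalid atom id")

    def _invalidate(self):
        self._molecule_id = None
        self._adjacency = None
        self._exclusions = None
        self._pairs14 = None

    # -- derived structure -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def molecule_id(self) -> np.ndarray:
        """Connected component label of the bond graph, per atom."""
        if self._molecule_id is None:
            n = self.n_atoms
            if len(self.bonds):
                i, j = self.bonds[:, 0], self.bonds[:, 1]
                g = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
                _, labels = connected_components(g, directed=False)
            else:
                labels = np.arange(n)
            self._molecule_id = labels
        return self._molecule_id

    @property
    def molecules(self) -> list[np.ndarray]:
        """Atom index arrays, one per molecule, ordered by lowest atom id."""
        labels = self.molecule_id
        order = np.argsort(labels, kind="stable")
        groups = np.split(order, np.cumsum(np.bincount(labels))[:-1])
        return [np.sort(g) for g in groups]

    @property
    def adjacency(self) -> list[list[int]]:
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
            for a, b in self.bonds:
                adj[a].append(int(b))
                adj[b].append(int(a))
            self._adjacency = [sorted(x) for x in adj]
        return self._adjacency

    def _build_excl(self):
        """1-2 and 1-3 pairs are excluded from nonbonded interactions;
        1-4 pairs are scaled."""
        adj = self.adjacency
        excl = set()
        for a, b in self.bonds:
            excl.add((min(a, b), max(a, b)))
        for a, b, c in self.angles:
            excl.add((min(a, c), max(a, c)))
        # also via graph in case angle terms are incomplete
        for a in range(self.n_atoms):
            for b in adj[a]:
                for c in adj[b]:
                    if c != a:
                        excl.add((min(a, c), max(a, c)))
        p14 = set()
        for a in range(self.n_atoms):
            for b in adj[a]:
                for c in adj[b]:
                    if c == a:
                        continue
                    for d in adj[c]:
                        if d in (a, b):
                            continue
                        pair = (min(a, d), max(a, d))
                        if pair not in excl and a != d:
                            p14.add(pair)
        self._exclusions = np.array(sorted(excl), dtype=int).reshape(-1, 2)
        self._pairs14 = np.array(sorted(p14), dtype=int).reshape(-1, 2)

    @property
    def exclusions(self) -> np.ndarray:
        if self._exclusions is None:
            self._build_excl()
        return self._exclusions

    @property
    def pairs14(self) -> np.ndarray:
        if self._pairs14 is None:
            self._build_excl()
        return self._pairs14

    def atom(self, i: int) -> Atom:
        return Atom(
            id=i, element=self.elements[i], mass=float(self.masses[i]),
            charge=float(self.charges[i]), lj_sigma=float(self.lj_sigma[i]),
            lj_epsilon=float(self.lj_epsilon[i]),
            molecule_id=int(self.molecule_id[i]),
            is_water=bool(self.is_water[i]),
            is_hydrogen=bool(self.is_hydrogen[i]),
            name=self.names[i], residue_id=int(self.residue_ids[i]),
            residue_name=self.residue_names[i],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Topology({self.n_atoms} atoms, {len(self.bonds)} bonds, "
                f"{len(set(self.molecule_id.tolist()))} molecules)")


@dataclass
class SystemState:
    """Dynamic state: positions/velocities in Å and Å/fs, time in fs."""

    positions: np.ndarray
    velocities: np.ndarray
    cell: TriclinicCell
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have equal shape")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           TriclinicCell(self.cell.matrix.copy()), self.time)


def classify_molecules(topology: Topology, constraint_set) -> list[IntegrationClass]:
    """Assign each molecule to the single-step or multiple-time-step class.

    A molecule is SINGLE_STEP iff constraints remove all of its internal
    degrees of freedom: ``3·n_atoms − n_constraints − 6 ≤ 0`` (with 5 external
    degrees of freedom for diatomics and 3 for single atoms).  Such molecules
    are internally frozen, so their bonded forces vanish identically and only
    nonbonded interactions need to be evaluated, once per large step.
    """
    per_mol = constraint_set.constraints_per_molecule(topology)
    classes = []
    for mol in topology.molecules:
        n = len(mol)
        external = 3 if n == 1 else (5 if n == 2 else 6)
        internal = 3 * n - per_mol.get(int(topology.molecule_id[mol[0]]), 0) - external
        classes.append(IntegrationClass.SINGLE_STEP if internal <= 0
                       else IntegrationClass.MULTI_STEP)
    return classes


def count_degrees_of_freedom(topology: Topology, constraint_set) -> int:
    """3N − n_constraints − 3; the 3 removes total linear momentum."""
    n_con = constraint_set.n_constraints_total
    dof = 3 * topology.n_atoms - n_con - 3
    if dof < 0:
        raise ValueError(f"over-constrained system: 3N={3*topology.n_atoms}, "
                         f"constraints={n_con}")
    return dof
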