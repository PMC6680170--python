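"""Deterministic synthetic systems: water boxes and small test molecules.

The water box emulates bulk solvent: rigid 3-site waters (TIP3P-like by
default) on a cubic lattice with random orientations and Maxwell–Boltzmann
velocities, with the box edge chosen to hit a requested mass density.  The
small molecules cover the hydrogen configurations that matter for the
constraint-selection heuristic (methyl, methylene, hydroxyl, sp2 =CH2,
ammonium, a guanidinium side-chain analog and a capped dipeptide with two
backbone torsions).  Their idealized geometries come from a deterministic
distance-geometry embedding followed by an MMFF relaxation; the force-field
equilibrium values of every bond and angle are then defined as the values
measured in that relaxed geometry, so "all terms at equilibrium" holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import TriclinicCell
from .system import SystemState, Topology
from .units import ATOMIC_MASSES, KB, KE_FACTOR

# generic stiffnesses (kJ/mol/Å² and kJ/mol/rad² in the 0.5·k·x² convention)
BOND_K = 2800.0
ANGLE_K = 420.0
DIHEDRAL_K = 4.0

# element-based 12-6 parameters (σ Å, ε kJ/mol), conventional magnitudes
LJ_BY_ELEMENT = {
    "H": (2.50, 0.066), "C": (3.40, 0.36), "N": (3.25, 0.71),
    "O": (2.96, 0.88), "S": (3.56, 1.05), "NA": (2.43, 0.366),
    "CL": (4.45, 0.42), "K": (3.14, 0.364), "MG": (1.41, 3.66),
    "CA": (2.41, 1.88), "ZN": (1.96, 0.052),
}


@dataclass
class WaterModel:
    """Rigid 3-site water parameters (TIP3P-like defaults)."""

    d_oh: float = 0.9572
    angle_deg: float = 104.52
    q_o: float = -0.834
    q_h: float = 0.417
    lj_sigma_o: float = 3.15061
    lj_epsilon_o: float = 0.6364


TEST_MOLECULES = {
    "methane": "C",
    "methanol": "CO",
    "ethane": "CC",
    "ethanol": "CCO",
    "ammonium": "[NH4+]",
    "sp2_CH2": "C=C",
    "arginine_sidechain_analog": "CCCNC(N)=[NH2+]",
    "capped_alanine_dipeptide": "CC(=O)N[C@@H](C)C(=O)NC",
}

# three-letter residue codes that do not collide with amino-acid names
_RESIDUE_CODES = {
    "methane": "MTN", "methanol": "MOH", "ethane": "ETA", "ethanol": "EOH",
    "ammonium": "NH4", "sp2_CH2": "ETE", "arginine_sidechain_analog": "GAI",
}

# capped amino acids: ACE-X-NME; heavy-atom SMILES order is
# [ACE: CH3, C, O] [residue: N, CA, side chain..., C, O] [NME: N, CH3]
CAPPED_AMINO_ACIDS = {
    "ALA": "CC(=O)N[C@@H](C)C(=O)NC",
    "ARG": "CC(=O)N[C@@H](CCCNC(N)=[NH2+])C(=O)NC",
    "ASN": "CC(=O)N[C@@H](CC(N)=O)C(=O)NC",
    "ASP": "CC(=O)N[C@@H](CC([O-])=O)C(=O)NC",
    "CYS": "CC(=O)N[C@@H](CS)C(=O)NC",
    "GLN": "CC(=O)N[C@@H](CCC(N)=O)C(=O)NC",
    "GLU": "CC(=O)N[C@@H](CCC([O-])=O)C(=O)NC",
    "GLY": "CC(=O)NCC(=O)NC",
    "HIS": "CC(=O)N[C@@H](Cc1c[nH]cn1)C(=O)NC",
    "ILE": "CC(=O)N[C@@H]([C@@H](C)CC)C(=O)NC",
    "LEU": "CC(=O)N[C@@H](CC(C)C)C(=O)NC",
    "LYS": "CC(=O)N[C@@H](CCCC[NH3+])C(=O)NC",
    "MET": "CC(=O)N[C@@H](CCSC)C(=O)NC",
    "PHE": "CC(=O)N[C@@H](Cc1ccccc1)C(=O)NC",
    "PRO": "CC(=O)N1CCC[C@H]1C(=O)NC",
    "SER": "CC(=O)N[C@@H](CO)C(=O)NC",
    "THR": "CC(=O)N[C@@H]([C@H](O)C)C(=O)NC",
    "TRP": "CC(=O)N[C@@H](Cc1c[nH]c2ccccc12)C(=O)NC",
    "TYR": "CC(=O)N[C@@H](Cc1ccc(O)cc1)C(=O)NC",
    "VAL": "CC(=O)N[C@@H](C(C)C)C(=O)NC",
}

_EMBED_SEED = 2025


# ---------------------------------------------------------------------------
# water box
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(masses, temperature, rng):
    """Å/fs velocities at the requested temperature, COM motion removed."""
    sigma = np.sqrt(KB * temperature / (masses * KE_FACTOR))
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v -= np.sum(masses[:, None] * v, axis=0) / np.sum(masses)
    return v


def build_water_box(n_per_edge: int, density_g_ml: float = 0.997,
                    seed: int = 0, temperature: float = 298.0,
                    model: WaterModel | None = None):
    """Cubic lattice of rigid 3-site waters at the requested density.

    Returns (topology, state).  Bit-reproducible for a fixed seed.
    """
    from .units import DALTON_PER_A3_TO_G_ML

    if n_per_edge < 2:
        raise ValueError("n_per_edge must be >= 2")
    if model is None:
        model = WaterModel()
    rng = np.random.default_rng(seed)
    n_w = n_per_edge ** 3
    m_o = ATOMIC_MASSES["O"]
    m_h = ATOMIC_MASSES["H"]
    mass_total = n_w * (m_o + 2 * m_h)
    volume = mass_total * DALTON_PER_A3_TO_G_ML / density_g_ml
    edge = volume ** (1.0 / 3.0)
    cell = TriclinicCell.cubic(edge)

    # canonical water with COM at origin, apex O
    ang = np.radians(model.angle_deg)
    rc = model.d_oh * np.sin(ang / 2.0)
    h = model.d_oh * np.cos(ang / 2.0)
    m_tot = m_o + 2 * m_h
    y_o = 2 * m_h * h / m_tot
    template = np.array([[0.0, y_o, 0.0],
                         [-rc, y_o - h, 0.0],
                         [rc, y_o - h, 0.0]])

    spacing = edge / n_per_edge
    positions = np.empty((3 * n_w, 3))
    w = 0
    for i in range(n_per_edge):
        for j in range(n_per_edge):
            for k in range(n_per_edge):
                site = (np.array([i, j, k]) + 0.5) * spacing
                rot = _random_rotation(rng)
                positions[3 * w:3 * w + 3] = site + template @ rot.T
                w += 1

    elements = ["O", "H", "H"] * n_w
    masses = np.tile([m_o, m_h, m_h], n_w)
    charges = np.tile([model.q_o, model.q_h, model.q_h], n_w)
    lj_s = np.tile([model.lj_sigma_o, 1.0, 1.0], n_w)
    lj_e = np.tile([model.lj_epsilon_o, 0.0, 0.0], n_w)
    names = ["O", "H1", "H2"] * n_w
    res_ids = np.repeat(np.arange(1, n_w + 1), 3)
    top = Topology(elements, masses, charges, lj_s, lj_e, names=names,
                   residue_ids=res_ids, residue_names=["HOH"] * (3 * n_w),
                   is_water=np.ones(3 * n_w, dtype=bool))
    bonds = []
    angles = []
    for wi in range(n_w):
        o, h1, h2 = 3 * wi, 3 * wi + 1, 3 * wi + 2
        bonds += [(o, h1), (o, h2)]
        angles.append((h1, o, h2))
    top.set_bonds(bonds, [model.d_oh] * len(bonds), [BOND_K] * len(bonds))
    top.set_angles(angles, [model.angle_deg] * len(angles),
                   [ANGLE_K] * len(angles))

    velocities = maxwell_boltzmann_velocities(masses, temperature, rng)
    state = SystemState(positions, velocities, cell)
    return top, state


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# molecules from SMILES (idealized geometry)
# ---------------------------------------------------------------------------

def topology_from_smiles(smiles: str, cell_edge: float = 50.0,
                         residue_splits=None, residue_names=None,
                         name: str = "LIG"):
    """Embed a molecule and derive a topology with equilibrium bonded terms.

    ``residue_splits`` optionally partitions the *heavy-atom SMILES order*
    into residues: a list of (start, end) index pairs matched with
    ``residue_names``; hydrogens inherit the residue of their heavy atom.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles}")
    n_heavy = mol.GetNumAtoms()
    mol = Chem.AddHs(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, ps) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    pos = np.array(conf.GetPositions())

    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    masses = np.array([ATOMIC_MASSES[e.upper()] for e in elements])
    lj = np.array([LJ_BY_ELEMENT.get(e.upper(), (3.4, 0.3)) for e in elements])

    res_ids = np.zeros(mol.GetNumAtoms(), dtype=int)
    res_names = [name] * mol.GetNumAtoms()
    if residue_splits is not None:
        for ridx, ((a, b), rname) in enumerate(zip(residue_splits,
                                                   residue_names)):
            for i in range(a, b):
                res_ids[i] = ridx
                res_names[i] = rname
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 1:
                heavy = atom.GetNeighbors()[0].GetIdx()
                res_ids[atom.GetIdx()] = res_ids[heavy]
                res_names[atom.GetIdx()] = res_names[heavy]

    top = Topology(elements, masses, charges=np.zeros(len(elements)),
                   lj_sigma=lj[:, 0], lj_epsilon=lj[:, 1],
                   names=[f"{e}{i}" for i, e in enumerate(elements)],
                   residue_ids=res_ids, residue_names=res_names)

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    r0 = [float(np.linalg.norm(pos[a] - pos[b])) for a, b in bonds]
    top.set_bonds(bonds, r0, [BOND_K] * len(bonds))

    adj = [[] for _ in range(mol.GetNumAtoms())]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    angles, theta0 = [], []
    for j in range(mol.GetNumAtoms()):
        nbrs = sorted(adj[j])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                u = pos[i] - pos[j]
                v = pos[k] - pos[j]
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                angles.append((i, j, k))
                theta0.append(float(np.degrees(np.arccos(np.clip(c, -1, 1)))))
    top.set_angles(angles, theta0, [ANGLE_K] * len(angles))

    # one generic 3-fold torsion per rotatable central bond
    dihedrals = []
    for a, b in bonds:
        na = [x for x in adj[a] if x != b]
        nb = [x for x in adj[b] if x != a]
        if na and nb:
            dihedrals.append((min(na), a, b, min(nb)))
    if dihedrals:
        top.set_dihedrals(dihedrals, [DIHEDRAL_K] * len(dihedrals),
                          [3] * len(dihedrals), [0.0] * len(dihedrals))

    _annotate_backbone_torsions(mol, top)

    center = pos.mean(axis=0)
    pos = pos - center + cell_edge / 2.0
    state = SystemState(pos, np.zeros_like(pos), TriclinicCell.cubic(cell_edge))
    return top, state


def _annotate_backbone_torsions(mol, top):
    """Record φ/ψ-defining quadruples (C−N−CA−C and N−CA−C−N) in metadata."""
    from rdkit import Chem

    phi = Chem.MolFromSmarts("[CX3](=O)[NX3][CX4][CX3](=O)")
    psi = Chem.MolFromSmarts("[NX3][CX4][CX3](=O)[NX3]")
    phis = [(m[0], m[2], m[3], m[4]) for m in mol.GetSubstructMatches(phi)]
    psis = [(m[0], m[1], m[2], m[4]) for m in mol.GetSubstructMatches(psi)]
    if phis:
        top.metadata["phi"] = phis
    if psis:
        top.metadata["psi"] = psis


def build_test_molecule(name: str, cell_edge: float = 50.0):
    """Idealized small molecules exercising the hydrogen configurations."""
    if name not in TEST_MOLECULES:
        raise ValueError(f"unknown test molecule {name!r}; choose from "
                         f"{sorted(TEST_MOLECULES)}")
    smiles = TEST_MOLECULES[name]
    if name == "capped_alanine_dipeptide":
        # heavy atoms: 0-2 acetyl cap, 3-7 alanine, 8-9 N-methyl cap
        return topology_from_smiles(
            smiles, cell_edge, residue_splits=[(0, 3), (3, 8), (8, 10)],
            residue_names=["ACE", "ALA", "NME"], name="ALA")
    return topology_from_smiles(smiles, cell_edge,
                                name=_RESIDUE_CODES[name])


def build_capped_amino_acid(code: str, cell_edge: float = 50.0):
    """ACE-X-NME capped amino acid with per-residue atom assignment."""
    code = code.upper()
    if code not in CAPPED_AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {code!r}")
    smiles = CAPPED_AMINO_ACIDS[code]
    from rdkit import Chem

    n_heavy = Chem.MolFromSmiles(smiles).GetNumAtoms()
    splits = [(0, 3), (3, n_heavy - 2), (n_heavy - 2, n_heavy)]
    return topology_from_smiles(smiles, cell_edge, residue_splits=splits,
                                residue_names=["ACE", code, "NME"], name=code)


def build_ion(element: str = "NA", charge: float = 1.0,
              cell_edge: float = 50.0):
    """Single monoatomic ion (SINGLE_STEP trivially)."""
    el = element.upper()
    lj = LJ_BY_ELEMENT.get(el, (3.0, 0.3))
    top = Topology([el], [ATOMIC_MASSES[el]], charges=[charge],
                   lj_sigma=[lj[0]], lj_epsilon=[lj[1]], names=[el],
                   residue_names=[el])
    pos = np.full((1, 3), cell_edge / 2.0)
    return top, SystemState(pos, np.zeros((1, 3)), TriclinicCell.cubic(cell_edge))


def merge_systems(parts):
    """Concatenate (topology, state) pairs into one system (first cell wins)."""
    tops = [p[0] for p in parts]
    states = [p[1] for p in parts]
    offsets = np.cumsum([0] + [t.n_atoms for t in tops[:-1]])
    elements, names, res_names = [], [], []
    arrays = {k: [] for k in ("masses", "charges", "lj_sigma", "lj_epsilon",
                              "residue_ids", "is_water")}
    bonds, r0, bk = [], [], []
    angles, t0, ak = [], [], []
    dih, dk, dn, dp = [], [], [], []
    res_offset = 0
    for off, t in zip(offsets, tops):
        elements += t.elements
        names += t.names
        res_names += t.residue_names
        arrays["masses"].append(t.masses)
        arrays["charges"].append(t.charges)
        arrays["lj_sigma"].append(t.lj_sigma)
        arrays["lj_epsilon"].append(t.lj_epsilon)
        arrays["residue_ids"].append(t.residue_ids + res_offset)
        arrays["is_water"].append(t.is_water)
        res_offset += int(t.residue_ids.max()) + 1 if t.n_atoms else 0
        bonds += [(a + off, b + off) for a, b in t.bonds]
        r0 += list(t.bond_r0)
        bk += list(t.bond_k)
        angles += [(a + off, b + off, c + off) for a, b, c in t.angles]
        t0 += list(t.angle_theta0)
        ak += list(t.angle_k)
        dih += [(a + off, b + off, c + off, d + off)
                for a, b, c, d in t.dihedrals]
        dk += list(t.dihedral_k)
        dn += list(t.dihedral_n)
        dp += list(t.dihedral_phase)
    top = Topology(elements, np.concatenate(arrays["masses"]),
                   np.concatenate(arrays["charges"]),
                   np.concatenate(arrays["lj_sigma"]),
                   np.concatenate(arrays["lj_epsilon"]), names=names,
                   residue_ids=np.concatenate(arrays["residue_ids"]),
                   residue_names=res_names,
                   is_water=np.concatenate(arrays["is_water"]))
    if bonds:
        top.set_bonds(bonds, r0, bk)
    if angles:
        top.set_angles(angles, t0, ak)
    if dih:
        top.set_dihedrals(dih, dk, dn, dp)
    pos = np.concatenate([s.positions for s in states])
    vel = np.concatenate([s.velocities for s in states])
    return top, SystemState(pos, vel, states[0].cell)
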