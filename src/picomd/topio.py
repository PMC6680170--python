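"""Topology + force-field parameter files: a small, versioned YAML dialect.

The format stores exactly what :class:`picomd.system.Topology` holds — an
atom table and bonded-term tables with their equilibrium values and
stiffnesses — so a system built from any source can be saved and reloaded
without a PDB round trip.  Layout::

    picomd_topology: 1          # format version
    atoms:                      # one row per atom
      - [element, name, mass, charge, lj_sigma, lj_epsilon,
         residue_id, residue_name, is_water]
    bonds:                      # i, j, r0 (Å), k (kJ/mol/Å²)
      - [0, 1, 0.9572, 2800.0]
    angles:                     # i, j, k, theta0 (deg), k (kJ/mol/rad²)
      - [1, 0, 2, 104.52, 420.0]
    dihedrals:                  # i, j, k, l, k (kJ/mol), n, phase (deg)
      - [0, 1, 2, 3, 4.0, 3, 0.0]

All energies follow the 0.5·k·x² convention for harmonic terms.
"""

from __future__ import annotations

import numpy as np
import yaml

from .system import Topology

FORMAT_VERSION = 1


def save_topology(path, topology: Topology) -> None:
    doc = {
        "picomd_topology": FORMAT_VERSION,
        "atoms": [
            [topology.elements[i], topology.names[i],
             float(topology.masses[i]), float(topology.charges[i]),
             float(topology.lj_sigma[i]), float(topology.lj_epsilon[i]),
             int(topology.residue_ids[i]), topology.residue_names[i],
             bool(topology.is_water[i])]
            for i in range(topology.n_atoms)
        ],
        "bonds": [[int(a), int(b), float(r0), float(k)]
                  for (a, b), r0, k in zip(topology.bonds, topology.bond_r0,
                                           topology.bond_k)],
        "angles": [[int(a), int(b), int(c), float(t0), float(k)]
                   for (a, b, c), t0, k in zip(topology.angles,
                                               topology.angle_theta0,
                                               topology.angle_k)],
        "dihedrals": [[int(a), int(b), int(c), int(d), float(k), int(n),
                       float(p)]
                      for (a, b, c, d), k, n, p in zip(
                          topology.dihedrals, topology.dihedral_k,
                          topology.dihedral_n, topology.dihedral_phase)],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_topology(path) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    version = doc.get("picomd_topology")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported topology format version {version!r} "
                         f"(expected {FORMAT_VERSION})")
    rows = doc["atoms"]
    top = Topology(
        elements=[r[0] for r in rows],
        masses=[r[2] for r in rows],
        charges=[r[3] for r in rows],
        lj_sigma=[r[4] for r in rows],
        lj_epsilon=[r[5] for r in rows],
        names=[r[1] for r in rows],
        residue_ids=[r[6] for r in rows],
        residue_names=[r[7] for r in rows],
        is_water=[r[8] for r in rows],
    )
    bonds = doc.get("bonds") or []
    if bonds:
        arr = np.array(bonds, dtype=float)
        top.set_bonds(arr[:, :2].astype(int), arr[:, 2], arr[:, 3])
    angles = doc.get("angles") or []
    if angles:
        arr = np.array(angles, dtype=float)
        top.set_angles(arr[:, :3].astype(int), arr[:, 3], arr[:, 4])
    dih = doc.get("dihedrals") or []
    if dih:
        arr = np.array(dih, dtype=float)
        top.set_dihedrals(arr[:, :4].astype(int), arr[:, 4],
                          arr[:, 5].astype(int), arr[:, 6])
    return top
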