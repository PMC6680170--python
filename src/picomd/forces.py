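"""Force-field kernels: bonded terms, LJ + damped real-space Coulomb, virial.

Functional forms are the conventional ones: harmonic bonds and angles,
periodic cosine dihedrals, 12-6 Lennard-Jones with Lorentz–Berthelot
combination and 1-4 scaling (electrostatics / 1.2, LJ / 2.0), and erfc-damped
real-space Coulomb paired with the reciprocal-space treatment in
:mod:`picomd.pme`.  Nonbonded truncation is plain (pair selection at the
cutoff, no switching).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, erfc, erfcinv

from .units import COULOMB, KE_FACTOR, KJ_PER_MOL_A3_TO_BAR


@dataclass
class NonbondedParams:
    """Nonbonded interaction settings.

    ``beta`` is the Ewald real-space damping in 1/Å; by default it is chosen
    so that erfc(beta·cutoff) = 1e-5, making the truncated real-space tail
    negligible relative to a typical pair energy.
    """

    cutoff: float = 8.0
    beta: float | None = None
    use_pme: bool = True
    pme_spacing: float = 0.9   # Å; grid spacing kept < 1 Å
    spline_order: int = 4
    scee: float = 1.2
    scnb: float = 2.0

    def __post_init__(self):
        if self.beta is None:
            self.beta = float(erfcinv(1e-5)) / self.cutoff

    def resolved_beta(self) -> float:
        return float(self.beta)


# ---------------------------------------------------------------------------
# pair kernels
# ---------------------------------------------------------------------------

def lj_kernel(r, sigma, epsilon):
    """12-6 Lennard-Jones energy and force/r."""
    sr6 = (sigma / r) ** 6
    sr12 = sr6 * sr6
    energy = 4.0 * epsilon * (sr12 - sr6)
    f_by_r = 24.0 * epsilon * (2.0 * sr12 - sr6) / (r * r)
    return energy, f_by_r

def coulomb_erfc_kernel(r, qq, beta):
    """Real-space Ewald (erfc-damped) Coulomb energy and force/r."""
    br = beta * r
    e = COULOMB * qq * erfc(br) / r
    f_by_r = (COULOMB * qq
              * (erfc(br) / r + 2.0 * beta / np.sqrt(np.pi) * np.exp(-br * br))
              / (r * r))
    return e, f_by_r

def coulomb_plain_kernel(r, qq):
    e = COULOMB * qq / r
    return e, e / (r * r)

def erf_excluded_kernel(r, qq, beta):
    """Correction removing the reciprocal-space interaction of excluded pairs.

    Energy −ke·qq·erf(βr)/r and the matching force/r.
    """
    br = beta * r
    e = -COULOMB * qq * erf(br) / r
    f_by_r = -COULOMB * qq * (erf(br) / r
                              - 2.0 * beta / np.sqrt(np.pi) * np.exp(-br * br)
                              ) / (r * r)
    return e, f_by_r


def accumulate_pair_forces(topology, ii, jj, dvec, r, params: NonbondedParams):
    """LJ + damped-Coulomb accumulation over an enumerated pair set.

    Returns (energies dict, per-atom forces, scalar virial Σ r·f).
    dvec points from j to i; the force on i is +f_by_r · dvec.
    """
    n = topology.n_atoms
    forces = np.zeros((n, 3))
    energies = {"lj": 0.0, "coulomb_real": 0.0}
    if len(ii) == 0:
        return energies, forces, 0.0
    sigma = 0.5 * (topology.lj_sigma[ii] + topology.lj_sigma[jj])
    epsilon = np.sqrt(topology.lj_epsilon[ii] * topology.lj_epsilon[jj])
    e_lj, f_lj = lj_kernel(r, sigma, epsilon)
    qq = topology.charges[ii] * topology.charges[jj]
    beta = params.resolved_beta()
    if params.use_pme:
        e_c, f_c = coulomb_erfc_kernel(r, qq, beta)
    else:
        e_c, f_c = coulomb_plain_kernel(r, qq)
    f_by_r = f_lj + f_c
    fvec = f_by_r[:, None] * dvec
    for ax in range(3):
        forces[:, ax] = (np.bincount(ii, weights=fvec[:, ax], minlength=n)
                         - np.bincount(jj, weights=fvec[:, ax], minlength=n))
    energies["lj"] = float(np.sum(e_lj))
    energies["coulomb_real"] = float(np.sum(e_c))
    virial = float(np.sum(f_by_r * r * r))
    return energies, forces, virial


def excluded_pair_corrections(topology, positions, cell, params: NonbondedParams):
    """Reciprocal-space corrections for excluded and 1-4 pairs.

    Excluded (1-2/1-3) pairs get the −erf(βr)/r removal; 1-4 pairs get the
    removal plus their scaled explicit LJ and plain-Coulomb interaction.
    Only meaningful when PME is active; without PME only the scaled 1-4
    terms apply.
    """
    n = topology.n_atoms
    forces = np.zeros((n, 3))
    energies = {"coulomb_corr": 0.0, "lj_14": 0.0, "coulomb_14": 0.0}
    virial = 0.0
    beta = params.resolved_beta()

    def add_pairs(pairs, e_key, kernel):
        nonlocal virial
        if len(pairs) == 0:
            return
        ia, ib = pairs[:, 0], pairs[:, 1]
        d = cell.minimum_image(positions[ia] - positions[ib])
        r = np.linalg.norm(d, axis=1)
        qq = topology.charges[ia] * topology.charges[ib]
        e, f_by_r = kernel(r, qq, ia, ib)
        fvec = f_by_r[:, None] * d
        np.add.at(forces, ia, fvec)
        np.add.at(forces, ib, -fvec)
        energies[e_key] += float(np.sum(e))
        virial += float(np.sum(f_by_r * r * r))

    if params.use_pme:
        add_pairs(topology.exclusions, "coulomb_corr",
                  lambda r, qq, ia, ib: erf_excluded_kernel(r, qq, beta))
        add_pairs(topology.pairs14, "coulomb_corr",
                  lambda r, qq, ia, ib: erf_excluded_kernel(r, qq, beta))

    def kernel_14(r, qq, ia, ib):
        sigma = 0.5 * (topology.lj_sigma[ia] + topology.lj_sigma[ib])
        epsilon = np.sqrt(topology.lj_epsilon[ia] * topology.lj_epsilon[ib])
        e_lj, f_lj = lj_kernel(r, sigma, epsilon)
        e_c, f_c = coulomb_plain_kernel(r, qq)
        energies["lj_14"] += float(np.sum(e_lj)) / params.scnb
        return (e_c / params.scee,
                f_lj / params.scnb + f_c / params.scee)

    add_pairs(topology.pairs14, "coulomb_14", kernel_14)
    return energies, forces, virial


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def bonded_forces(positions, topology, cell=None, skip_bonds=None,
                  skip_angles=None):
    """Harmonic bonds/angles and cosine dihedrals: energy and forces.

    Terms whose degrees of freedom are removed by constraints are skipped via
    the boolean masks — a constrained bond or angle sits at its equilibrium
    value by construction, so its force is identically zero and is not
    computed.
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    energy = 0.0

    def mi(d):
        return cell.minimum_image(d) if cell is not None else d

    bonds, r0s, ks = topology.bonds, topology.bond_r0, topology.bond_k
    if skip_bonds is not None and len(bonds):
        keep = ~skip_bonds
        bonds, r0s, ks = bonds[keep], r0s[keep], ks[keep]
    if len(bonds):
        d = mi(positions[bonds[:, 0]] - positions[bonds[:, 1]])
        r = np.linalg.norm(d, axis=1)
        dr = r - r0s
        energy += float(np.sum(0.5 * ks * dr * dr))
        f = (-ks * dr / r)[:, None] * d
        np.add.at(forces, bonds[:, 0], f)
        np.add.at(forces, bonds[:, 1], -f)

    angles, t0s, aks = topology.angles, topology.angle_theta0, topology.angle_k
    if skip_angles is not None and len(angles):
        keep = ~skip_angles
        angles, t0s, aks = angles[keep], t0s[keep], aks[keep]
    if len(angles):
        i, j, k = angles[:, 0], angles[:, 1], angles[:, 2]
        u = mi(positions[i] - positions[j])
        v = mi(positions[k] - positions[j])
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
        theta = np.arccos(c)
        dtheta = theta - np.radians(t0s)
        energy += float(np.sum(0.5 * aks * dtheta * dtheta))
        coeff = (aks * dtheta / s)
        dc_du = v / (nu * nv)[:, None] - (c / (nu * nu))[:, None] * u
        dc_dv = u / (nu * nv)[:, None] - (c / (nv * nv))[:, None] * v
        fi = coeff[:, None] * dc_du
        fk = coeff[:, None] * dc_dv
        np.add.at(forces, i, fi)
        np.add.at(forces, k, fk)
        np.add.at(forces, j, -(fi + fk))

    dih = topology.dihedrals
    if len(dih):
        i, j, k, l = dih[:, 0], dih[:, 1], dih[:, 2], dih[:, 3]
        rij = mi(positions[i] - positions[j])
        rkj = mi(positions[k] - positions[j])
        rkl = mi(positions[k] - positions[l])
        m = np.cross(rij, rkj)
        nvec = np.cross(rkj, rkl)
        mm = np.einsum("ij,ij->i", m, m)
        nn = np.einsum("ij,ij->i", nvec, nvec)
        cosphi = np.clip(np.einsum("ij,ij->i", m, nvec)
                         / np.sqrt(mm * nn), -1.0, 1.0)
        phi = np.arccos(cosphi)
        phi = np.where(np.einsum("ij,ij->i", rij, nvec) < 0, -phi, phi)
        kd = topology.dihedral_k
        nd = topology.dihedral_n
        gd = np.radians(topology.dihedral_phase)
        energy += float(np.sum(kd * (1.0 + np.cos(nd * phi - gd))))
        ddphi = -kd * nd * np.sin(nd * phi - gd)
        nrkj = np.linalg.norm(rkj, axis=1)
        fi = (-ddphi * nrkj / mm)[:, None] * m
        fl = (ddphi * nrkj / nn)[:, None] * nvec
        rkj2 = np.einsum("ij,ij->i", rkj, rkj)
        p = (np.einsum("ij,ij->i", rij, rkj) / rkj2)[:, None]
        q = (np.einsum("ij,ij->i", rkl, rkj) / rkj2)[:, None]
        sv = p * fi - q * fl
        np.add.at(forces, i, fi)
        np.add.at(forces, j, sv - fi)
        np.add.at(forces, k, -sv - fl)
        np.add.at(forces, l, fl)

    return energy, forces


# ---------------------------------------------------------------------------
# pressure
# ---------------------------------------------------------------------------

@dataclass
class VirialAccumulator:
    """Clausius-virial bookkeeping: P = 2/(3V)·(KE + ½ Σ r·f).

    ``rf_sum`` must be accumulated pairwise (Σ_pairs r_ij·f_ij with
    minimum-image r_ij), which is the image-consistent form of Σ rᵢ·Fᵢ for
    forces crossing periodic boundaries; the pair kernels above return it.
    """

    kinetic_energy: float = 0.0    # kJ/mol
    rf_sum: float = 0.0            # kJ/mol (Σ_pairs r·f, without the ½)
    volume: float = 1.0            # Å³


def virial_pressure(acc: VirialAccumulator) -> float:
    """Instantaneous pressure in bar."""
    p = 2.0 / (3.0 * acc.volume) * (acc.kinetic_energy + 0.5 * acc.rf_sum)
    return p * KJ_PER_MOL_A3_TO_BAR


def kinetic_energy(velocities, masses) -> float:
    """kJ/mol from Å/fs and Dalton."""
    return 0.5 * KE_FACTOR * float(np.sum(masses * np.einsum(
        "ij,ij->i", velocities, velocities)))
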