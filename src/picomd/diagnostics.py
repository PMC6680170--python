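"""Trajectory analyses: φ/ψ free-energy maps and crystallographic B-factors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import KB


@dataclass
class FreeEnergyMap:
    """Dihedral-space free energy on a 72×72 grid (5° bins).

    Probabilities are converted with E = −kB·T·ln(p) and shifted so the
    minimum is exactly zero; empty bins carry +inf.
    """

    counts: np.ndarray
    free_energy: np.ndarray
    edges: np.ndarray
    temperature: float

    @property
    def resolution_deg(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def contour_levels(self, spacing: float = 4.0, n: int = 7) -> np.ndarray:
        """Levels for a marching-squares contour export."""
        return np.arange(1, n + 1) * spacing


def ramachandran_free_energy(phi_deg, psi_deg, temperature: float = 298.0,
                             bins: int = 72) -> FreeEnergyMap:
    """Boltzmann inversion of a φ/ψ sample onto a 5°-resolution map."""
    phi_deg = np.asarray(phi_deg, dtype=float)
    psi_deg = np.asarray(psi_deg, dtype=float)
    if len(phi_deg) != len(psi_deg):
        raise ValueError("phi and psi samples must have equal length")
    if len(phi_deg) < 100:
        raise ValueError("too few samples for a free-energy map (need >= 100)")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    wrap = lambda a: (a + 180.0) % 360.0 - 180.0
    counts, _, _ = np.histogram2d(wrap(phi_deg), wrap(psi_deg),
                                  bins=[edges, edges])
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        energy = -KB * temperature * np.log(prob)
    energy -= energy[np.isfinite(energy)].min()
    return FreeEnergyMap(counts=counts, free_energy=energy, edges=edges,
                         temperature=temperature)


def compute_dihedrals(frames: np.ndarray, quadruple) -> np.ndarray:
    """Dihedral angle (degrees) of an atom quadruple over trajectory frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    i, j, k, l = quadruple
    b1 = frames[:, j] - frames[:, i]
    b2 = frames[:, k] - frames[:, j]
    b3 = frames[:, l] - frames[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def phi_psi_series(frames: np.ndarray, topology):
    """(φ, ψ) series in degrees from the topology's backbone annotation."""
    phis = topology.metadata.get("phi")
    psis = topology.metadata.get("psi")
    if not phis or not psis:
        raise ValueError("topology carries no backbone torsion annotation")
    return (compute_dihedrals(frames, phis[0]),
            compute_dihedrals(frames, psis[0]))


# ---------------------------------------------------------------------------
# B-factors
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the transformed coordinates.  Raises on degenerate input (fewer
    than three non-collinear fitting points).
    """
    if weights is None:
        weights = np.ones(len(mobile))
    w = weights / weights.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    h = (w[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise ValueError("degenerate configuration: superposition failed")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ m0.T).T + rc


def bfactors(frames: np.ndarray, selection=None, superpose: bool = True,
             fit_selection=None) -> np.ndarray:
    """Per-atom B-factors B = (8π²/3)·⟨|r − ⟨r⟩|²⟩ in Å².

    Frames are superposed onto the first frame (least-squares, on
    ``fit_selection`` or all atoms) before the fluctuation average, so
    rigid-body motion does not inflate the result.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need at least two trajectory frames")
    n_atoms = frames.shape[1]
    if selection is None:
        selection = np.arange(n_atoms)
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty atom selection")
    if fit_selection is None:
        fit_selection = np.arange(n_atoms)
    fit_selection = np.asarray(fit_selection, dtype=int)

    if superpose:
        ref = frames[0]
        aligned = np.empty_like(frames)
        aligned[0] = ref
        for t in range(1, len(frames)):
            # zero-weight atoms outside the fit selection get transformed too
            aligned[t] = kabsch_superpose(
                frames[t], ref, weights=_fit_weights(n_atoms, fit_selection))
    else:
        aligned = frames
    mean = aligned.mean(axis=0)
    msf = np.mean(np.sum((aligned - mean[None]) ** 2, axis=2), axis=0)
    return (8.0 * np.pi ** 2 / 3.0) * msf[selection]


def _fit_weights(n_atoms: int, fit_selection: np.ndarray) -> np.ndarray:
    w = np.zeros(n_atoms)
    w[fit_selection] = 1.0
    return w
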