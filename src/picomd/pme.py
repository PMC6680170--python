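"""Smooth particle-mesh Ewald: reciprocal-space energy and forces.

Charges are spread onto a regular grid in fractional coordinates with
cardinal B-splines (fourth order by default) and the reciprocal-space sum is
evaluated with an FFT; the grid spacing is kept below 1 Å.  The analytic
gradient of the spline weights gives forces that are exactly consistent with
the interpolated energy.  The real-space companion (erfc damping with the
same β) lives in :mod:`picomd.forces`; the self-energy and the optional
uniform-background correction for non-neutral systems are provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fftn, ifftn

from .units import COULOMB


@dataclass
class EwaldParams:
    beta: float                  # 1/Å real-space damping
    grid: tuple[int, int, int]   # PME mesh points per axis
    spline_order: int = 4
    cutoff: float = 8.0          # direct-space cutoff, Å

    def __post_init__(self):
        if self.spline_order != 4:
            raise ValueError("only fourth-order B-splines are supported")


def pme_grid_size(cell, spacing: float = 0.9) -> tuple[int, int, int]:
    """Even mesh sizes giving a grid spacing below the requested value."""
    widths = cell.perpendicular_widths
    sizes = []
    for w in widths:
        k = int(np.ceil(w / spacing))
        if k % 2:
            k += 1
        sizes.append(max(k, 8))
    return tuple(sizes)


def _bspline4(t: np.ndarray):
    """Fourth-order cardinal B-spline weights and derivatives.

    ``t`` in [0, 1) is the fractional offset; returns (w, dw) of shape
    (..., 4) for the four grid points floor(u)-3 … floor(u).
    """
    # arguments of M4 at the four support points: t, t+1, t+2, t+3
    x0 = t
    x1 = t + 1.0
    x2 = t + 2.0
    x3 = t + 3.0
    w3 = x0 ** 3 / 6.0                                   # M4(t): point k0
    w2 = (-3 * x1 ** 3 + 12 * x1 ** 2 - 12 * x1 + 4) / 6.0
    w1 = (3 * x2 ** 3 - 24 * x2 ** 2 + 60 * x2 - 44) / 6.0
    w0 = (4.0 - x3) ** 3 / 6.0                           # M4(t+3): point k0-3
    # dM4/dx = M3(x) - M3(x-1)
    def m3(x):
        y = np.zeros_like(x)
        m = (x >= 0) & (x < 1)
        y[m] = 0.5 * x[m] ** 2
        m = (x >= 1) & (x < 2)
        y[m] = 0.5 * (-2 * x[m] ** 2 + 6 * x[m] - 3)
        m = (x >= 2) & (x < 3)
        y[m] = 0.5 * (3 - x[m]) ** 2
        return y

    d3 = m3(x0) - m3(x0 - 1.0)
    d2 = m3(x1) - m3(x1 - 1.0)
    d1 = m3(x2) - m3(x2 - 1.0)
    d0 = m3(x3) - m3(x3 - 1.0)
    w = np.stack([w0, w1, w2, w3], axis=-1)
    dw = np.stack([d0, d1, d2, d3], axis=-1)
    return w, dw


def _spline_factors(k: int) -> np.ndarray:
    """|b(m)|² Euler exponential-spline moduli for fourth order."""
    # M4 at the integer knots 1, 2, 3
    knots = np.array([1.0 / 6.0, 4.0 / 6.0, 1.0 / 6.0])
    m = np.arange(k)
    denom = np.zeros(k, dtype=complex)
    for j, c in enumerate(knots):
        denom += c * np.exp(2j * np.pi * m * j / k)
    mod2 = np.abs(denom) ** 2
    # odd-order zeros cannot occur for order 4 except at k/2 for tiny grids
    mod2[mod2 < 1e-10] = np.inf
    return 1.0 / mod2


def pme_reciprocal(positions, charges, cell, params: EwaldParams,
                   allow_non_neutral: bool = False,
                   remove_net_force: bool = True):
    """Reciprocal-space energy (kJ/mol) and forces (kJ/mol/Å).

    The returned energy includes neither the real-space erfc sum, the
    self-energy, nor exclusion corrections.  A net-charged system is
    rejected unless ``allow_non_neutral`` applies the uniform neutralizing
    background correction.
    """
    q_total = float(np.sum(charges))
    volume = cell.volume
    if abs(q_total) > 1e-8 and not allow_non_neutral:
        raise ValueError(
            f"system has net charge {q_total:.4f} e; pass "
            "allow_non_neutral=True to apply a neutralizing background")

    k1, k2, k3 = params.grid
    frac = cell.fractional(positions) % 1.0
    u = frac * np.array([k1, k2, k3])
    k0 = np.floor(u).astype(int)
    t = u - k0
    w = np.empty((len(positions), 3, 4))
    dw = np.empty((len(positions), 3, 4))
    for ax in range(3):
        w[:, ax, :], dw[:, ax, :] = _bspline4(t[:, ax])

    offs = np.arange(-3, 1)
    idx = (k0[:, :, None] + offs[None, None, :])
    idx[:, 0, :] %= k1
    idx[:, 1, :] %= k2
    idx[:, 2, :] %= k3

    # spread charges: outer product of the per-axis weights
    wxyz = (w[:, 0, :, None, None] * w[:, 1, None, :, None]
            * w[:, 2, None, None, :])
    flat = ((idx[:, 0, :, None, None] * k2 + idx[:, 1, None, :, None]) * k3
            + idx[:, 2, None, None, :])
    grid = np.bincount(
        flat.reshape(-1),
        weights=(charges[:, None]
                 * wxyz.reshape(len(positions), -1)).reshape(-1),
        minlength=k1 * k2 * k3).reshape(k1, k2, k3)

    # reciprocal-space influence function
    ginv = np.linalg.inv(cell.matrix)          # columns are reciprocal vectors
    m1 = np.fft.fftfreq(k1, 1.0 / k1)
    m2 = np.fft.fftfreq(k2, 1.0 / k2)
    m3f = np.fft.fftfreq(k3, 1.0 / k3)
    mm = np.stack(np.meshgrid(m1, m2, m3f, indexing="ij"), axis=-1)
    mvec = mm @ ginv.T                          # m · rows of inv(H)ᵀ
    m2abs = np.einsum("...i,...i->...", mvec, mvec)
    b2 = (_spline_factors(k1)[:, None, None]
          * _spline_factors(k2)[None, :, None]
          * _spline_factors(k3)[None, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        influence = np.where(
            m2abs > 0,
            np.exp(-np.pi ** 2 * m2abs / params.beta ** 2) / m2abs, 0.0)
    influence = influence * b2 / (2.0 * np.pi * volume)

    qhat = fftn(grid)
    energy = COULOMB * float(np.sum(influence * np.abs(qhat) ** 2))

    # potential grid for forces: φ = F⁻¹[2·influence·Q̂] (real)
    phi = np.real(ifftn(2.0 * influence * qhat)) * (k1 * k2 * k3)

    phi_at = phi.reshape(-1)[flat.reshape(len(positions), -1)]
    phi_at = phi_at.reshape(len(positions), 4, 4, 4)
    # derivative of the weight product along each grid axis
    dwx = (dw[:, 0, :, None, None] * w[:, 1, None, :, None]
           * w[:, 2, None, None, :])
    dwy = (w[:, 0, :, None, None] * dw[:, 1, None, :, None]
           * w[:, 2, None, None, :])
    dwz = (w[:, 0, :, None, None] * w[:, 1, None, :, None]
           * dw[:, 2, None, None, :])
    gx = np.einsum("nijk,nijk->n", phi_at, dwx) * k1
    gy = np.einsum("nijk,nijk->n", phi_at, dwy) * k2
    gz = np.einsum("nijk,nijk->n", phi_at, dwz) * k3
    dedu = np.stack([gx, gy, gz], axis=1) * charges[:, None]
    # du_a/dx_j = K_a * ginv[j, a]; K already folded in above
    forces = -COULOMB * dedu @ ginv.T
    if remove_net_force:
        # B-spline interpolation leaves a tiny spurious net force; remove it
        # so total momentum is conserved exactly
        forces -= forces.mean(axis=0, keepdims=True)

    if abs(q_total) > 1e-8:
        energy += background_energy(q_total, params.beta, volume)
    return energy, forces


def self_energy(charges, beta: float) -> float:
    """Ewald self-interaction removal, −ke·β/√π·Σq²."""
    return -COULOMB * beta / np.sqrt(np.pi) * float(np.sum(
        np.asarray(charges) ** 2))


def background_energy(q_total: float, beta: float, volume: float) -> float:
    """Uniform neutralizing background for net-charged systems."""
    return -COULOMB * np.pi / (2.0 * beta ** 2 * volume) * q_total ** 2
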