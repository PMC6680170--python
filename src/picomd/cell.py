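"""Triclinic simulation cell with periodic wrapping and minimum-image vectors.

The cell is stored as a lower-triangular 3x3 matrix whose *rows* are the
three cell vectors, so a Cartesian coordinate ``x`` maps to fractional
coordinates via ``f = x @ inv(H)`` and back via ``x = f @ H``.  Orthorhombic
cells are the special case of a diagonal matrix.
"""

from __future__ import annotations

import numpy as np


class TriclinicCell:
    """Periodic triclinic cell defined by a lower-triangular vector matrix."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError("cell matrix must be 3x3")
        if not np.allclose(matrix[np.triu_indices(3, 1)], 0.0):
            raise ValueError("cell matrix must be lower triangular "
                             "(rows are cell vectors)")
        if np.linalg.det(matrix) <= 0:
            raise ValueError("cell volume must be positive")
        self.matrix = matrix
        self._inv = np.linalg.inv(matrix)
        self._diag = np.allclose(matrix, np.diag(np.diag(matrix)))
        self._shifts27 = None

    @classmethod
    def cubic(cls, edge: float) -> "TriclinicCell":
        return cls(np.eye(3) * float(edge))

    @classmethod
    def orthorhombic(cls, lengths) -> "TriclinicCell":
        return cls(np.diag(np.asarray(lengths, dtype=float)))

    @classmethod
    def from_lengths_angles(cls, lengths, angles_deg) -> "TriclinicCell":
        """Build the lower-triangular cell from a, b, c and α, β, γ (degrees)."""
        a, b, c = lengths
        al, be, ga = np.radians(angles_deg)
        v1 = [a, 0.0, 0.0]
        v2 = [b * np.cos(ga), b * np.sin(ga), 0.0]
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
        return cls(np.array([v1, v2, [cx, cy, cz]]))

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def lengths(self) -> np.ndarray:
        """Norms of the three cell vectors."""
        return np.linalg.norm(self.matrix, axis=1)

    @property
    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite faces along each axis (image-convention
        relevant thickness)."""
        m = self.matrix
        widths = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            n = np.cross(m[j], m[k])
            widths[i] = abs(np.dot(m[i], n)) / np.linalg.norm(n)
        return widths

    def fractional(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self._inv

    def cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into the primary image [0, 1)³ in fractional space."""
        frac = self.fractional(coords) % 1.0
        # guard against fractional == 1.0 from floating-point round-off
        frac[frac >= 1.0] = 0.0
        return frac @ self.matrix

    def minimum_image(self, dvecs: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors.

        Valid for distances below half the smallest perpendicular cell width
        (enforced upstream by the neighbor-search preconditions).
        """
        dvecs = np.asarray(dvecs, dtype=float)
        if self._diag:
            lengths = np.diag(self.matrix)
            return dvecs - lengths * np.round(dvecs / lengths)
        frac = dvecs @ self._inv
        frac -= np.round(frac)
        d0 = frac @ self.matrix
        # skewed cells: fractional rounding alone is not guaranteed minimal;
        # refine over the 27 adjacent images (exact within one period)
        if self._shifts27 is None:
            from itertools import product

            self._shifts27 = np.array(list(product((-1, 0, 1), repeat=3)),
                                      dtype=float) @ self.matrix
        cand = d0[..., None, :] + self._shifts27
        norms = np.einsum("...ki,...ki->...k", cand, cand)
        best = np.argmin(norms, axis=-1)
        return np.take_along_axis(
            cand, best[..., None, None], axis=-2).squeeze(-2)

    def scaled(self, factors) -> "TriclinicCell":
        """Return a new cell scaled along the Cartesian axes.

        ``factors`` is a scalar or per-axis triple; every cell vector has its
        Cartesian components multiplied component-wise, which is how weak
        pressure coupling rescales the box.
        """
        f = np.broadcast_to(np.asarray(factors, dtype=float), (3,))
        return TriclinicCell(self.matrix * f[None, :])

    def __repr__(self) -> str:  # pragma: no cover
        return f"TriclinicCell(lengths={self.lengths}, volume={self.volume:.1f})"
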