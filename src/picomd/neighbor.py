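"""Grid-based neighbor search in triclinic cells, fused with force evaluation.

Atoms are binned into a grid of parallelepiped "cubes" whose target spacing
is cutoff/3 for cutoffs below 9.5 Å and cutoff/4 above.  The neighbor volume
around a cube is a block of cubes along each axis from which geometrically
unreachable corner cubes are pruned (in the cutoff/3 case, 4 cubes in each
of the 8 corners, leaving 311 of 343 offsets).  The search runs every step
and is intertwined with the nonbonded force computation; a pair list can be
stored on the fly and reused for several steps ("sloppy pair lists"),
accepting transiently missed interactions.  The pair-list cutoff that keeps
the associated energy drift acceptable is estimated from a random-walk
argument: particles drift apart by roughly the square root of the number of
reuse steps times a thermal step length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .cell import TriclinicCell


def grid_spacing(cutoff: float) -> float:
    """Target grid spacing: cutoff/3 below 9.5 Å, cutoff/4 at and above."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return cutoff / 3.0 if cutoff < 9.5 else cutoff / 4.0


@dataclass
class PairListPolicy:
    """Sloppy-pair-list policy; the empirical constant converts thermal speed
    into an expected inter-update travel distance (Å·Dalton/(Kelvin·fs))."""

    cutoff_force: float
    update_frequency: int = 1
    time_step: float = 5.0
    temperature: float = 298.0
    avg_particle_mass: float = 18.0154
    constant: float = 0.001

    def __post_init__(self):
        if self.update_frequency < 1:
            raise ValueError("update_frequency must be >= 1")


def pairlist_cutoff(policy: PairListPolicy) -> float:
    """Pair-list cutoff = force cutoff + sqrt(N_reuse) × thermal step.

    The buffer grows with the square root of (update_frequency − 1) — a
    one-dimensional random walk in pair distance — times
    time_step × temperature × constant / average particle mass.
    """
    extra = (np.sqrt(policy.update_frequency - 1.0) * policy.time_step
             * policy.temperature * policy.constant / policy.avg_particle_mass)
    return float(policy.cutoff_force + extra)


def average_particle_mass(topology) -> float:
    """Mean particle mass with each water molecule counted as one particle."""
    is_w = topology.is_water
    water_mols = set()
    for mol in topology.molecules:
        if is_w[mol].all():
            water_mols.add(int(topology.molecule_id[mol[0]]))
    n_water = len(water_mols)
    n_other = int(np.sum(~is_w))
    total_mass = float(topology.masses.sum())
    return total_mass / (n_water + n_other)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def _grid_counts(cell: TriclinicCell, spacing: float) -> np.ndarray:
    widths = cell.perpendicular_widths
    return np.maximum(np.floor(widths / spacing).astype(int), 1)


class Grid:
    """Cube partition of a cell with padded cube→atom buckets.

    ``order`` sorts atoms so that atoms in the same cube are contiguous
    (memory-locality layout; functionally only the bucket map matters).
    """

    def __init__(self, cell: TriclinicCell, positions: np.ndarray,
                 spacing: float):
        self.cell = cell
        self.counts = _grid_counts(cell, spacing)
        self.spacing = spacing
        n1, n2, n3 = (int(x) for x in self.counts)
        frac = cell.fractional(positions) % 1.0
        frac[frac >= 1.0] = 0.0
        ijk = np.minimum((frac * self.counts).astype(int), self.counts - 1)
        self.cube_ijk = ijk
        self.cube_id = (ijk[:, 0] * n2 + ijk[:, 1]) * n3 + ijk[:, 2]
        self.n_cubes = n1 * n2 * n3
        self.order = np.argsort(self.cube_id, kind="stable")
        occupancy = np.bincount(self.cube_id, minlength=self.n_cubes)
        self.max_per_cube = int(occupancy.max()) if len(positions) else 0
        self.cube_atoms = np.full((self.n_cubes, max(self.max_per_cube, 1)),
                                  -1, dtype=int)
        slot = np.zeros(self.n_cubes, dtype=int)
        for a in self.order:
            c = self.cube_id[a]
            self.cube_atoms[c, slot[c]] = a
            slot[c] += 1

    @property
    def cube_volume(self) -> float:
        return self.cell.volume / self.n_cubes


# ---------------------------------------------------------------------------
# search pattern
# ---------------------------------------------------------------------------

@dataclass
class SearchPattern:
    """Precomputed cube-offset pattern for a given cutoff and grid shape."""

    offsets: np.ndarray          # (n, 3) kept offsets, including (0,0,0)
    pruned: np.ndarray           # (m, 3) geometrically unreachable offsets
    counts: np.ndarray           # grid counts the pattern was built for
    cutoff: float
    extent: np.ndarray           # searched block half-width per axis

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)

    def half_offsets(self) -> np.ndarray:
        """Forward half of the pattern (excluding the origin), such that each
        unordered cube pair is visited once."""
        o = self.offsets
        keep = ((o[:, 2] > 0)
                | ((o[:, 2] == 0) & (o[:, 1] > 0))
                | ((o[:, 2] == 0) & (o[:, 1] == 0) & (o[:, 0] > 0)))
        return o[keep]


def min_cube_separation(offset, cell: TriclinicCell, counts) -> float:
    """Exact minimum distance between a cube and the cube at integer offset.

    Both cubes are translates of the parallelepiped spanned by the scaled
    cell vectors, so the minimum reduces to a tiny box-constrained least
    squares: min ‖(o + u) · C‖ over u ∈ [−1, 1]³.  For orthorhombic cells
    the solution is the per-axis clamp in closed form.
    """
    o = np.asarray(offset, dtype=float)
    if getattr(cell, "_diag", False):
        spacing = np.diag(cell.matrix) / np.asarray(counts, dtype=float)
        gaps = np.maximum(np.abs(o) - 1.0, 0.0) * spacing
        return float(np.linalg.norm(gaps))
    c = cell.matrix / np.asarray(counts, dtype=float)[:, None]
    b = o @ c
    res = lsq_linear(c.T, -b, bounds=(-1.0, 1.0), tol=1e-12)
    return float(np.linalg.norm(c.T @ res.x + b))


def build_search_pattern(cutoff: float, spacing: float,
                         cell: TriclinicCell) -> SearchPattern:
    """Build the corner-pruned offset pattern for a cutoff and cell.

    An offset is pruned when the minimum distance between the central cube
    and the offset cube reaches the cutoff (pair inclusion is strict,
    r < cutoff, so such cubes cannot contribute).  Pruning is purely
    geometric and therefore lossless.
    """
    widths = cell.perpendicular_widths
    if np.any(widths < 2.0 * cutoff):
        raise ValueError(
            f"cell widths {widths} must be at least twice the cutoff "
            f"{cutoff} Å (minimum-image convention)")
    counts = _grid_counts(cell, spacing)
    actual = widths / counts
    extent = np.ceil(cutoff / actual - 1e-9).astype(int)
    kept, pruned = [], []
    for i in range(-extent[0], extent[0] + 1):
        for j in range(-extent[1], extent[1] + 1):
            for k in range(-extent[2], extent[2] + 1):
                o = (i, j, k)
                if max(abs(i), abs(j), abs(k)) <= 1:
                    kept.append(o)
                    continue
                if min_cube_separation(o, cell, counts) >= cutoff - 1e-9:
                    pruned.append(o)
                else:
                    kept.append(o)
    return SearchPattern(offsets=np.array(kept, dtype=int),
                         pruned=np.array(pruned, dtype=int).reshape(-1, 3),
                         counts=counts, cutoff=cutoff, extent=extent)


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def _reduced_half_offsets(pattern: SearchPattern, counts):
    """Half offsets deduplicated modulo the grid size.

    On small grids distinct offsets can address the same cube pair (o and
    o ± counts) or each other's reverse; only one representative is kept.
    Offsets that are their own reverse modulo the grid need an i<j filter,
    like the origin cube.
    """
    counts = np.asarray(counts)
    seen: dict[tuple, bool] = {}
    out = []
    for o in pattern.half_offsets():
        rep = tuple(int(x) for x in (o % counts))
        rev = tuple(int(x) for x in ((-o) % counts))
        if rep in seen or rev in seen:
            continue
        self_paired = rep == rev
        seen[rep] = True
        out.append((np.asarray(rep), self_paired))
    return out


def find_pairs(positions: np.ndarray, cell: TriclinicCell, cutoff: float,
               grid: Grid, pattern: SearchPattern):
    """Enumerate all unordered atom pairs with min-image distance < cutoff.

    Returns (i, j, dvec, r) with dvec the minimum-image vector from j to i.
    """
    n = len(positions)
    if n == 0:
        return (np.zeros(0, int), np.zeros(0, int),
                np.zeros((0, 3)), np.zeros(0))
    counts = grid.counts
    n2, n3 = int(counts[1]), int(counts[2])

    cache = getattr(pattern, "_reduced_cache", None)
    key = tuple(int(x) for x in counts)
    if cache is None or cache[0] != key:
        reduced = _reduced_half_offsets(pattern, counts)
        reps = np.array([[0, 0, 0]] + [list(r) for r, _ in reduced], dtype=int)
        selfp = np.array([True] + [s for _, s in reduced], dtype=bool)
        pattern._reduced_cache = (key, reps, selfp)
    else:
        _, reps, selfp = cache

    # all offsets at once: (m, n) target cube ids, (m, n, kmax) candidates
    ijk = (grid.cube_ijk[None, :, :] + reps[:, None, :]) % counts
    cid = (ijk[..., 0] * n2 + ijk[..., 1]) * n3 + ijk[..., 2]
    jj = grid.cube_atoms[cid]                          # (m, n, kmax)
    kmax = jj.shape[-1]
    ii = np.broadcast_to(np.arange(n)[None, :, None], jj.shape)
    mask = jj >= 0
    mask &= np.where(selfp[:, None, None], jj > ii, True)
    ii = ii[mask]
    jj = jj[mask]
    dvec = cell.minimum_image(positions[ii] - positions[jj])
    r2 = np.einsum("ij,ij->i", dvec, dvec)
    keep = r2 < cutoff * cutoff
    return ii[keep], jj[keep], dvec[keep], np.sqrt(r2[keep])


@dataclass
class PairList:
    """Stored neighbor pairs with the step they were created at."""

    i: np.ndarray
    j: np.ndarray
    shifts: np.ndarray           # integer periodic image shift per pair
    creation_step: int
    cutoff: float                # pair-list cutoff used at creation
    n_atoms: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    def to_frame(self, positions, cell):
        """Debug dump: i, j, image shift, current distance."""
        import pandas as pd

        d = cell.minimum_image(positions[self.i] - positions[self.j])
        return pd.DataFrame({
            "i": self.i, "j": self.j,
            "shift_x": self.shifts[:, 0], "shift_y": self.shifts[:, 1],
            "shift_z": self.shifts[:, 2],
            "distance": np.linalg.norm(d, axis=1),
        })


class StalePairListError(RuntimeError):
    pass


def fused_search_and_forces(state, topology, grid: Grid,
                            pattern: SearchPattern, nonbonded_params,
                            store_pairlist: bool = False,
                            pairlist_cutoff_value: float | None = None,
                            step_index: int = 0):
    """Grid neighbor search intertwined with the nonbonded force pass.

    Forces use the force cutoff of ``nonbonded_params``; when
    ``store_pairlist`` is requested, all pairs out to the (larger) pair-list
    cutoff are recorded on the fly for reuse in subsequent steps.  The
    forces are identical whether or not the list is stored.
    """
    from . import forces as _forces

    cutoff_force = nonbonded_params.cutoff
    search_cutoff = cutoff_force
    if store_pairlist:
        search_cutoff = pairlist_cutoff_value or cutoff_force
        if search_cutoff < cutoff_force:
            raise ValueError("pair-list cutoff must be >= force cutoff")
    if pattern.cutoff < search_cutoff - 1e-9:
        raise ValueError("search pattern built for a smaller cutoff")

    ii, jj, dvec, r = find_pairs(state.positions, state.cell, search_cutoff,
                                 grid, pattern)
    ii, jj, dvec, r = _filter_excluded(topology, ii, jj, dvec, r)

    plist = None
    if store_pairlist:
        frac = state.cell.fractional(state.positions[ii]
                                     - state.positions[jj])
        shifts = -np.round(frac).astype(int)
        plist = PairList(i=ii.copy(), j=jj.copy(), shifts=shifts,
                         creation_step=step_index, cutoff=search_cutoff,
                         n_atoms=state.n_atoms)
        within = r < cutoff_force
        ii, jj, dvec, r = ii[within], jj[within], dvec[within], r[within]

    energy, forces, virial = _forces.accumulate_pair_forces(
        topology, ii, jj, dvec, r, nonbonded_params)
    return energy, forces, virial, plist


def pairlist_reuse_step(state, topology, pairlist: PairList,
                        nonbonded_params, step_index: int,
                        update_frequency: int):
    """Nonbonded forces over a stored pair list at the current positions.

    Interactions of pairs that moved inside the force cutoff but were beyond
    the pair-list cutoff at creation are missed — the sloppy-pair-list
    trade-off.  A list older than the update frequency is an error; the
    caller must refresh it.
    """
    from . import forces as _forces

    age = step_index - pairlist.creation_step
    if age >= update_frequency:
        raise StalePairListError(
            f"pair list is {age} steps old (update frequency "
            f"{update_frequency}); refresh before reuse")
    ii, jj = pairlist.i, pairlist.j
    dvec = state.cell.minimum_image(state.positions[ii]
                                    - state.positions[jj])
    r = np.linalg.norm(dvec, axis=1)
    within = r < nonbonded_params.cutoff
    energy, forces, virial = _forces.accumulate_pair_forces(
        topology, ii[within], jj[within], dvec[within], r[within],
        nonbonded_params)
    return energy, forces, virial


def _filter_excluded(topology, ii, jj, dvec, r):
    """Drop 1-2/1-3 excluded and 1-4 pairs from the enumerated set.

    1-4 pairs are handled separately with their scaling factors; they are
    treated like exclusions for the plain nonbonded pass.
    """
    n = topology.n_atoms
    keys = np.minimum(ii, jj) * n + np.maximum(ii, jj)
    excl = topology.exclusions
    p14 = topology.pairs14
    banned = np.concatenate([
        excl[:, 0] * n + excl[:, 1] if len(excl) else np.zeros(0, int),
        p14[:, 0] * n + p14[:, 1] if len(p14) else np.zeros(0, int),
    ])
    if len(banned) == 0:
        return ii, jj, dvec, r
    banned = np.sort(banned)
    pos = np.searchsorted(banned, keys)
    pos[pos >= len(banned)] = len(banned) - 1
    keep = banned[pos] != keys
    return ii[keep], jj[keep], dvec[keep], r[keep]
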