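"""Shared fixtures: all test systems are generated programmatically."""

import numpy as np
import pytest

from picomd.constraints import build_all_constraints
from picomd.fixtures import build_test_molecule, build_water_box


@pytest.fixture(scope="session")
def small_water_box():
    """27 rigid waters at liquid density (cheap but periodic-realistic)."""
    return build_water_box(3, density_g_ml=0.997, seed=7, temperature=298)


@pytest.fixture(scope="session")
def water_box_216():
    """The 216-water benchmark fixture."""
    return build_water_box(6, density_g_ml=0.997, seed=11, temperature=298)


@pytest.fixture(scope="session")
def methane():
    return build_test_molecule("methane")


@pytest.fixture(scope="session")
def ethane():
    return build_test_molecule("ethane")


@pytest.fixture(scope="session")
def dipeptide():
    return build_test_molecule("capped_alanine_dipeptide")


@pytest.fixture(scope="session")
def methane_constraints(methane):
    top, state = methane
    return build_all_constraints(top)


def brute_force_pairs(positions, cell, cutoff):
    """O(N²) minimum-image pair enumeration over the 27 neighbor images.

    Independent oracle for the grid search: explicit minimum over all
    adjacent periodic images, no fractional-rounding shortcut.
    """
    from itertools import product

    n = len(positions)
    d0 = positions[:, None, :] - positions[None, :, :]
    best = None
    for s in product((-1, 0, 1), repeat=3):
        shift = np.array(s, dtype=float) @ cell.matrix
        dd = np.linalg.norm(d0 + shift, axis=2)
        best = dd if best is None else np.minimum(best, dd)
    iu = np.triu_indices(n, 1)
    mask = best[iu] < cutoff
    return set(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
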