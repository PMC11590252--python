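import numpy as np
import pytest

from cryosse.structures import ChainStructure, Residue
from cryosse.synthetic import SceneSpec, make_case
from cryosse.volumes import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """A 16^3 empty grid at 1 Å spacing, origin at the world origin."""
    return DensityMap(np.zeros((16, 16, 16), dtype=np.float32))


@pytest.fixture
def two_class_structure():
    """One helix and one sheet Cα 4 Å apart, overlapping 3 Å spheres."""
    return ChainStructure([
        Residue("A", 1, [6.0, 8.0, 8.0], "H", 1),
        Residue("A", 2, [10.0, 8.0, 8.0], "E", 2),
    ])


@pytest.fixture(scope="session")
def tiny_case():
    """A small noiseless synthetic case reused by slower tests."""
    return make_case(SceneSpec(total_residues=50, box_pad=12.0, noise=False, seed=7))


def brute_force_labels(structure, grid, radius=3.0):
    """Independent O(voxels x residues) labeling oracle: nearest Cα within
    the radius wins; exact helix/sheet distance ties go to helix."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    ca = structure.ca_array()
    cls = structure.classes_array()
    for idx in np.ndindex(grid.shape):
        center = grid.voxel_center(idx)
        best_d, best_c = np.inf, 0
        for p, c in zip(ca, cls):
            if c == 0:
                continue
            d = float(np.linalg.norm(center - p))
            if d > radius:
                continue
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and c == 1):
                best_d, best_c = d, c
        out[idx] = best_c
    return out
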