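import numpy as np
import pytest

from eccentric_mrsi import GridSpec, default_basis
from eccentric_mrsi.trajectories import design_eccentric_2d


@pytest.fixture(scope="session")
def grid16():
    return GridSpec(n_xy=16, fov_xy=0.22)


@pytest.fixture(scope="session")
def grid64():
    return GridSpec(n_xy=64, fov_xy=0.22)


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def plan16(grid16):
    """Small fully sampled eccentric plan for oracle comparisons."""
    return design_eccentric_2d(grid16, grid16.kmax / 2, af=1.0, seed=1,
                               sbw=2000.0, n_time=8)


def brute_force_nuft(k_points, grid, image):
    """Independent double-loop evaluation of the type-1 transform."""
    r = grid.image_coords()
    X, Y = np.meshgrid(r, r, indexing="ij")
    out = np.empty(len(k_points), dtype=complex)
    for j, (kx, ky) in enumerate(k_points):
        out[j] = np.sum(np.exp(2j * np.pi * (kx * X + ky * Y)) * image)
    return out


@pytest.fixture(scope="session")
def brute_nuft():
    return brute_force_nuft
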