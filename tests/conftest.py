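import numpy as np
import pytest

from histomech import (
    SimParams,
    TissueMesh,
    init_rest_state,
    make_cell_grid,
    subdivide_long_edges,
)


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def nest16() -> TissueMesh:
    """A 16-cell nest on a 20x20 um template, subdivided and rest-initialized."""
    mesh = make_cell_grid(20.0, 20.0, 16, seed=0)
    mesh = subdivide_long_edges(mesh, 1.0)
    return init_rest_state(mesh)


@pytest.fixture()
def tiny_mesh() -> TissueMesh:
    """A hand-built 2-cell mesh (two unit squares sharing a wall)."""
    positions = np.array(
        [[0, 0], [1, 0], [2, 0], [2, 1], [1, 1], [0, 1]], dtype=float
    )
    edges = np.array(
        [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [5, 0], [1, 4]], dtype=int
    )
    d = positions[edges[:, 1]] - positions[edges[:, 0]]
    rest = np.hypot(d[:, 0], d[:, 1])
    rest_angles = np.full(6, np.nan)
    rest_angles[[0, 2, 3, 5]] = np.pi
    rest_angles[[1, 4]] = 2 * np.pi / 3
    fixed = np.array([True, True, True, True, True, True])
    return TissueMesh(
        positions=positions,
        foundation=positions.copy(),
        edges=edges,
        rest_lengths=rest,
        rest_angles=rest_angles,
        faces=[[0, 1, 4, 5], [1, 2, 3, 4]],
        fixed=fixed,
    )
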