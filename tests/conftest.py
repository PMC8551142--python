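import numpy as np
import pytest

from brickphantom import make_brick_registry
from brickphantom.config import PhantomConfig


@pytest.fixture(scope="session")
def registry():
    return make_brick_registry()


@pytest.fixture(scope="session")
def config():
    return PhantomConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210828)


def brute_force_cells(placement, registry):
    """Independent rasterization oracle: scan the axis-aligned bounding box
    of the rotated brick and keep every lattice cell whose centre maps back
    into the local box under the inverse rotation."""
    import numpy as np

    from brickphantom.brick_model import brick_local_frame, lattice_unit

    spec = registry[placement.brick]
    u = lattice_unit(registry)
    m, t = brick_local_frame(placement, registry)
    dims = np.array(spec.dims)
    corners = np.array(
        [[x, y, z] for x in (0, dims[0]) for y in (0, dims[1]) for z in (0, dims[2])]
    )
    world = corners @ m.T + t
    lo = np.floor(world.min(axis=0) / u).astype(int)
    hi = np.ceil(world.max(axis=0) / u).astype(int)
    cells = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                center = (np.array([i, j, k]) + 0.5) * u
                local = m.T @ (center - t)
                if np.all(local > 0) and np.all(local < dims):
                    cells.add((i, j, k))
    return cells
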