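import numpy as np
import pytest

from vasobold import SimulationParams
from vasobold.vangeo import LABEL_VEIN, VesselVolume


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def straight_vessel_volume(
    n: int = 15,
    voxel_size: float = 0.8,
    axis: int = 2,
    diameter: float = 1.2,
    label: int = LABEL_VEIN,
    offset: tuple[int, int] = None,
) -> VesselVolume:
    """A single straight vessel spanning the grid along one axis."""
    if offset is None:
        offset = (n // 2, n // 2)
    c = np.zeros((n, n, n), dtype=bool)
    d = np.zeros((n, n, n))
    lab = np.zeros((n, n, n), dtype=np.uint8)
    idx = [slice(None)] * 3
    others = [a for a in range(3) if a != axis]
    idx[others[0]] = offset[0]
    idx[others[1]] = offset[1]
    idx = tuple(idx)
    c[idx] = True
    d[idx] = diameter
    lab[idx] = label
    return VesselVolume(c, d, lab, voxel_size)


@pytest.fixture()
def straight_vein() -> VesselVolume:
    return straight_vessel_volume()
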