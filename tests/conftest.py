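import warnings

import numpy as np
import pytest

from nes_atlas.environment import EnvLayerStack, compute_slope
from nes_atlas.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """One default synthetic world shared across tests (seed 11)."""
    return generate_world(seed=11)


@pytest.fixture(scope="session")
def stack(world):
    return EnvLayerStack(
        world.dem, compute_slope(world.dem), world.rainfall_true, world.temperature, world.geology
    )


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield


def brute_force_locations(points: np.ndarray, threshold_km: float = 10.0) -> list[list[int]]:
    """Independent union-find oracle over all point pairs (strict < threshold)."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            dij = float(np.hypot(*(points[i] - points[j])))
            if dij < threshold_km * 1000.0:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])
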