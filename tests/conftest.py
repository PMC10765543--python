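import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sdrmap.grid import MappingGrid, NeedleSite, Wall, build_default_grid

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_grid() -> MappingGrid:
    return build_default_grid()


def make_wall_grid(wall=Wall.LV, n_levels=2, n_cols=2, wrap=True) -> MappingGrid:
    """Single-wall toy lattice with sequential needle ids."""
    sites = [NeedleSite(lvl * n_cols + c, wall, lvl + 1, c)
             for lvl in range(n_levels) for c in range(n_cols)]
    return MappingGrid(sites, wrap=wrap)


@pytest.fixture
def toy_2x2() -> MappingGrid:
    return make_wall_grid(n_levels=2, n_cols=2, wrap=True)


@pytest.fixture
def toy_2x2_nowrap() -> MappingGrid:
    return make_wall_grid(n_levels=2, n_cols=2, wrap=False)


def random_toy_grid(rng: np.random.Generator) -> MappingGrid:
    """Random multi-wall lattice with random electrode dropout potential."""
    sites = []
    nid = 0
    walls = [Wall.RV, Wall.LV, Wall.SEPTUM]
    for wall in walls[:rng.integers(1, 4)]:
        n_levels = int(rng.integers(1, 5))
        n_cols = int(rng.integers(1, 5))
        for lvl in range(n_levels):
            for c in range(n_cols):
                if rng.random() < 0.85:  # occasionally missing needles
                    sites.append(NeedleSite(nid, wall, lvl + 1, c))
                    nid += 1
    if not sites:
        sites = [NeedleSite(0, Wall.LV, 1, 0)]
    return MappingGrid(sites, wrap=bool(rng.random() < 0.7))
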