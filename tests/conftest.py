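import numpy as np
import pytest

from allelewave.landscape import Landscape


@pytest.fixture(scope="session")
def flat_landscape():
    """All-land 20x20 grid, 1-degree cells, anchored at (30N, 10W)."""
    return Landscape.from_mask(np.ones((20, 20), dtype=bool))


@pytest.fixture(scope="session")
def europe_grid():
    """All-land grid on the full study bbox (30-75N, 10W-80E)."""
    return Landscape.from_mask(np.ones((45, 90), dtype=bool))


@pytest.fixture(scope="session")
def pond_landscape():
    """Land grid whose outer ring is water: interior no-flux everywhere."""
    mask = np.zeros((16, 16), dtype=bool)
    mask[1:-1, 1:-1] = True
    return Landscape.from_mask(mask)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_uniform_metric(n: int, spacing_km: float = 100.0, mask=None) -> Landscape:
    """Landscape with a synthetic uniform metric (dx = dy everywhere)."""
    shape = (n, n)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return Landscape(
        lat_min=0.0, lat_max=float(n), lon_min=0.0, lon_max=float(n),
        resolution=1.0, n_rows=n, n_cols=n,
        land_mask=np.asarray(mask, dtype=bool),
        dx_km=np.full(shape, spacing_km),
        dy_km=np.full(shape, spacing_km),
        area_km2=np.full(shape, spacing_km ** 2),
    )
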