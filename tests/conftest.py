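import numpy as np
import pytest

from thalmap import geodb, synthetic
from thalmap.grids import GridSpec, rectangular_grid, surface_from_flat


@pytest.fixture(scope="session")
def grid8():
    """8x8 unmasked grid over a Thailand-like extent."""
    return rectangular_grid(west=98.0, south=8.0, cell_size=0.5, n_rows=8, n_cols=8)


@pytest.fixture(scope="session")
def masked_grid():
    """6x6 grid with the four corner cells masked out."""
    mask = np.ones((6, 6), dtype=bool)
    for r, c in ((0, 0), (0, 5), (5, 0), (5, 5)):
        mask[r, c] = False
    return GridSpec(100.0, 10.0, 0.5, 6, 6, mask=mask)


@pytest.fixture(scope="session")
def study_small(grid8):
    """A small but complete synthetic study shared across tests."""
    return synthetic.simulate_study(
        grid8, n_sites=40, total_population=1e6, n_provinces=4, seed=12345
    )


def make_record(sid="s1", country="Thailand", n=100, lat=15.0, lon=100.0, **kw):
    defaults = dict(
        survey_id=sid,
        country=country,
        n_individuals=n,
        latitude=lat,
        longitude=lon,
    )
    defaults.update(kw)
    return geodb.SurveyRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record


def constant_surface(grid, value, scale="probability"):
    return surface_from_flat(grid, np.full(grid.n_unmasked, float(value)), scale=scale)


@pytest.fixture
def const_surface():
    return constant_surface
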