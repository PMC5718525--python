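import numpy as np
import pytest

import gammagel as gg
from gammagel.geometry import DoseGrid, GridGeometry


@pytest.fixture(scope="session")
def plan():
    return gg.table1_plan()


@pytest.fixture(scope="session")
def calc_grid(plan):
    """The plan sampled on the TPS-like 2.5 mm export grid."""
    return gg.generate_calculated_dose(plan, gg.default_calc_geometry())


@pytest.fixture(scope="session")
def gel_cal():
    return gg.default_gel_calibration()


@pytest.fixture(scope="session")
def film_model():
    return gg.default_film_calibration()


@pytest.fixture()
def small_grid():
    """A smooth 21^3 field on a 1 mm lattice for comparison statistics."""
    geom = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (21, 21, 21))
    x, y, z = geom.meshgrid_mm()
    data = 10.0 * np.exp(-((x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2) / 60.0)
    return DoseGrid(data, geom)


def smooth_random_grid(seed: int, shape=(21, 21, 21), amplitude=10.0) -> DoseGrid:
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
    raw = (raw - raw.min()) / np.ptp(raw)
    geom = GridGeometry((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), shape)
    return DoseGrid(amplitude * raw, geom)
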