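"""Shared fixtures: a small simulated design and a small imaging scene.

Session-scoped so the (deliberately reduced) simulations run once.
"""

import numpy as np
import pytest

from specflux.axes import FT_RAMAN, FTIR_MICRO, HTS_FTIR
from specflux.bands import default_band_table
from specflux.synthetic import (Design, make_scene, medium,
                                simulate_design_dataset,
                                simulate_hyperspectral_image)


@pytest.fixture(scope="session")
def band_table():
    return default_band_table()


@pytest.fixture(scope="session")
def small_datasets():
    """Bulk datasets for a reduced design: 4 media x 3 timepoints x 2 reps."""
    design = Design(
        media=tuple(medium(m) for m in ("nGlu", "iGlu", "iGlu1:Gly7", "Gly")),
        timepoints=(8.0, 24.0, 120.0),
        replicates=2,
        modalities=(HTS_FTIR, FT_RAMAN),
    )
    return simulate_design_dataset(design, seed=7)


@pytest.fixture(scope="session")
def small_image():
    """A 48x48 hyperspectral FTIR image of a lipid-rich scene."""
    scene = make_scene("nGlu", 120.0, shape=(48, 48), seed=11)
    return scene, simulate_hyperspectral_image(scene, FTIR_MICRO, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
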