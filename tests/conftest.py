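"""Shared fixtures: geometry, beam models, and commissioned tables.

Commissioning a table means simulating the full slab session (35 F_CAX,
36 displacement and 3 edge irradiations at full imager resolution), so
the tables are built once per session and shared.
"""

import numpy as np
import pytest

from epidose.commissioning import commission_from_fixtures
from epidose.geometry import BeamGeometry
from epidose.synthetic import (
    SyntheticBeamModel,
    generate_commissioning_fixtures,
    ground_truth,
    make_tmr_table,
    noise_free,
)


@pytest.fixture(scope="session")
def geom():
    return BeamGeometry()


@pytest.fixture(scope="session")
def model():
    return SyntheticBeamModel()


@pytest.fixture(scope="session")
def model_nf(model):
    return noise_free(model)


@pytest.fixture(scope="session")
def truth(model):
    return ground_truth(model)


@pytest.fixture(scope="session")
def table_nf(model_nf, geom):
    """Table commissioned on noise-free fixtures (parameter recovery)."""
    return commission_from_fixtures(*generate_commissioning_fixtures(model_nf, geom, seed=11))


@pytest.fixture(scope="session")
def table(model, geom):
    """Table commissioned on fixtures with realistic imager noise."""
    return commission_from_fixtures(*generate_commissioning_fixtures(model, geom, seed=11))


@pytest.fixture(scope="session")
def tmr_table(model):
    return make_tmr_table(model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
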