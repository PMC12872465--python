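"""Shared fixtures: small reservoirs and pinned-seed simulated datasets.

The simulated tables are expensive relative to the rest of the suite, so
they are session-scoped and shared between the unit tests and the
end-to-end accuracy tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import enzyres as ez

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: the degraded catalyst subset used for the enzyme-ablation checks:
#: broad-specificity cleavers without the inhibitory feedback enzymes
THREE_ENZYMES = ["trypsin", "elastase", "thermolysin"]


@pytest.fixture(scope="session")
def reservoir():
    """Full seven-catalyst surrogate reservoir, pinned seed."""
    return ez.build_reservoir(seed=0)


@pytest.fixture(scope="session")
def reservoir_three():
    return ez.build_reservoir(seed=0, enzyme_names=THREE_ENZYMES)


@pytest.fixture(scope="session")
def classification_table(reservoir):
    """60 random (S1, S2) steady-state samples at 37 C, pH 7.4."""
    return ez.classification_scenario(reservoir, n_samples=60, seed=1)


@pytest.fixture(scope="session")
def classification_table_three(reservoir_three):
    return ez.classification_scenario(reservoir_three, n_samples=60, seed=1)


@pytest.fixture(scope="session")
def temperature_table(reservoir):
    """21 temperature levels x 4 replicate measurements (84 rows)."""
    return ez.temperature_scenario(reservoir, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
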