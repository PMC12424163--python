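"""Shared fixtures: the standard scaled column-ensemble experiment.

The three management scenarios are run once per session on the reduced
hypsography with matched forcing seeds and reused by the mechanism and
acceptance tests.  Window years are the first/last three years of the
default near-term and long-term projection blocks, a deliberately
scaled-down stand-in for the full 30-year ensembles.
"""

import numpy as np
import pytest

from hypoxsim.forcing import ForcingConfig, generate_forcing
from hypoxsim.scenario import (ScenarioSpec, run_time_slice,
                               standard_fixture_columns)

FIXTURE_WINDOWS = ((2016, 2018), (2098, 2100))
FIXTURE_SEED = 1
EARLY, LATE = FIXTURE_WINDOWS


@pytest.fixture(scope="session")
def fixture_forcing():
    return generate_forcing(ForcingConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def scenario_suite(fixture_forcing):
    """All three scenarios on the standard fixture, matched seeds."""
    out = {}
    for name in ("ConstantN", "DecreasingN", "Oyster"):
        spec = ScenarioSpec(name=name, windows=FIXTURE_WINDOWS,
                            seed=FIXTURE_SEED)
        out[name] = run_time_slice(spec, fixture_forcing,
                                   standard_fixture_columns(), dt=0.5)
    return out
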