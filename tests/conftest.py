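"""Shared fixtures: canonical stimuli generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mlsod.detector import run_ml_sod
from mlsod.experiments import (
    StimulusProtocol,
    centered_object,
    make_retina_stimulus,
    stage_lists,
)
from mlsod.metrics import transient_frames


@pytest.fixture(scope="session")
def protocol():
    """Canonical conditions: 100 frames at 100 Hz over a seeded texture."""
    return StimulusProtocol(seed=1)


@pytest.fixture(scope="session")
def standard_stimulus(protocol):
    """6x6-px dark object at 200 px/s, static background, retina lattice."""
    obj = centered_object(6, 200.0, protocol)
    return make_retina_stimulus(obj, protocol)


@pytest.fixture(scope="session")
def standard_outputs(standard_stimulus):
    """Per-stage output lists of the two-arm dark pathway."""
    retina, _ = standard_stimulus
    return stage_lists(run_ml_sod(retina))


@pytest.fixture(scope="session")
def burn_in(standard_stimulus):
    retina, _ = standard_stimulus
    return transient_frames(retina.dt)


@pytest.fixture(scope="session")
def tiny_stimulus(protocol):
    """3x3-px (sub-lattice) dark object at 200 px/s."""
    obj = centered_object(3, 200.0, protocol)
    return make_retina_stimulus(obj, protocol)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
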