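from __future__ import annotations

import numpy as np
import pytest

from hcsleep.config import SimulationParams
from hcsleep.synthetic import generate_session


@pytest.fixture(scope="session")
def std_session():
    """One 30-min default synthetic session shared across test modules."""
    params = SimulationParams(duration_s=1800.0, seed=3)
    record, truth = generate_session(params, seed=3)
    return params, record, truth


@pytest.fixture(scope="session")
def quiet_lfp():
    """A 20-s plain-noise LFP trace (no events) for detector unit tests."""
    from hcsleep.core import ChannelTrace, Modality, Region

    rng = np.random.default_rng(11)
    fs = 1000.0
    samples = rng.standard_normal(int(20 * fs)) * 10.0
    return ChannelTrace(
        name="lfp",
        modality=Modality.LFP,
        region=Region.CA1,
        sampling_rate_hz=fs,
        samples=samples,
    )
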