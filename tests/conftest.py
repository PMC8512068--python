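"""Shared fixtures: small deterministic recordings and window sets."""

import numpy as np
import pytest

from fogsense.io import CHANNEL_NAMES, SensorRecording
from fogsense.synthetic import SimulationConfig, make_balanced_windowset, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_recording(rng):
    """A 400-sample nine-channel recording with all three annotations."""
    n = 400
    ann = np.ones(n, dtype=np.int64)
    ann[:50] = 0          # out-of-experiment lead-in
    ann[200:260] = 2      # a FOG episode
    ann[350:] = 0         # out-of-experiment tail
    return SensorRecording(
        timestamps=np.arange(n) / 64 * 1000,
        channels={c: rng.normal(1.0, 0.3, size=n) for c in CHANNEL_NAMES},
        annotations=ann,
        fs=64.0,
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small aligned simulation shared across tests (6 FOG episodes)."""
    cfg = SimulationConfig(n_fog_events=6, seed=42)
    ws, gt = make_balanced_windowset(cfg, w=2.0)
    return cfg, ws, gt


@pytest.fixture(scope="session")
def sim_recording():
    cfg = SimulationConfig(n_fog_events=4, seed=9)
    rec, gt = simulate_recording(cfg)
    return cfg, rec, gt
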