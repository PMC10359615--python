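import numpy as np
import pytest

from apekin.synthgen import ExperimentDesign, NoiseModel


@pytest.fixture
def design():
    return ExperimentDesign()


@pytest.fixture
def quiet():
    """Noiseless noise model (exact model evaluation)."""
    return NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)


@pytest.fixture
def noise3pct():
    """The standard 3% proportional noise model used in recovery tests."""
    def _make(seed: int) -> NoiseModel:
        return NoiseModel(seed=seed)
    return _make


@pytest.fixture
def flat_trace():
    """Constant-E_FRET trace factory (value, duration, cadence)."""
    def _make(value=0.475, duration=300.0, dt=0.17):
        t = np.arange(0.0, duration, dt)
        return t, (1 - value) * 1000.0, value * 1000.0
    return _make
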