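import numpy as np
import pytest

from somnomorph.hypnogram import EventAnnotations, Hypnogram
from somnomorph.synthetic import SimConfig

#: 16-epoch toy night used across metric tests; enumerated by hand:
#: onset at epoch 2, last sleep epoch 12, SPT 11 epochs, TST 8 epochs.
TOY_STAGES = ("W", "W", "N2", "N2", "N1", "SWS", "W", "W",
              "REM", "REM", "N2", "W", "N2", "W", "W", "W")


@pytest.fixture
def toy_night() -> Hypnogram:
    return Hypnogram(stages=TOY_STAGES, lights_out_epoch=0, lights_on_epoch=16)


@pytest.fixture
def no_events() -> EventAnnotations:
    return EventAnnotations()


@pytest.fixture
def small_sim() -> SimConfig:
    return SimConfig(n_subjects=5, n_epochs=60, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
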