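import numpy as np
import pytest

from middecode import synth


@pytest.fixture(scope="session")
def small_session_spec() -> synth.SessionSpec:
    """Tiny 4-condition session: 2 participants, 40 epochs, 250 Hz raw."""
    return synth.SessionSpec(
        n_participants=2,
        n_blocks=1,
        trials_retained_per_block=40,
        raw_rate_hz=250.0,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_epochs(small_session_spec) -> synth.EpochSet:
    return synth.generate_participant(small_session_spec, 0)


@pytest.fixture(scope="session")
def preprocessed_small(small_epochs):
    from middecode.preprocess import preprocess_epochs

    return preprocess_epochs(small_epochs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
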