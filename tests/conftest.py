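import numpy as np
import pytest

from vadistill.fixtures import PoolConfig, build_fixture_pools


@pytest.fixture(scope="session")
def small_pools():
    """A small but complete fixture-pool set shared across test modules."""
    config = PoolConfig(
        n_speech=12,
        n_background=10,
        n_bird=6,
        n_soundscape=2,
        speech_duration_s=2.0,
        background_duration_s=2.0,
        bird_duration_s=2.0,
        soundscape_duration_s=16.0,
        soundscape_rate=16_000,
    )
    return build_fixture_pools(config, seed=123)
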