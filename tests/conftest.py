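import numpy as np
import pytest

from rrsonic.pipeline import PipelineConfig
from rrsonic.synth_data import SynthSpec, generate_breath_audio


@pytest.fixture(scope="session")
def cfg():
    """Default pipeline configuration."""
    return PipelineConfig()


@pytest.fixture(scope="session")
def short_recording():
    """A 5-min synthetic recording at a constant 40 bpm (default noise)."""
    spec = SynthSpec(duration=300.0, rr_profile=40.0, seed=11)
    return generate_breath_audio(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
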