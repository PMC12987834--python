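import numpy as np
import pytest

from mvfuse.models import ModelConfig, build_model
from mvfuse.synthgen import SegmentArrays, SynthConfig, generate_segments


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig.tiny(input_size=32, init_seed=7)


@pytest.fixture(scope="session")
def fusion_model(tiny_model_config):
    return build_model("fusion", tiny_model_config)


@pytest.fixture(scope="session")
def view_pair(tiny_model_config):
    rng = np.random.default_rng(11)
    size = tiny_model_config.input_size
    return (rng.random((size, size), dtype=np.float32),
            rng.random((size, size), dtype=np.float32))


@pytest.fixture(scope="session")
def small_dataset() -> SegmentArrays:
    """10 patients, ~32 px views, strong lesions: quick but non-degenerate."""
    cfg = SynthConfig(n_patients=10, segments_per_patient=4.0, prevalence=0.3,
                      image_size=32, contrast=0.2, severity=0.95, seed=5)
    return SegmentArrays.from_samples(generate_segments(cfg))
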