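import numpy as np
import pytest

from segssl.model import ModelSpec
from segssl.segments import WindowingConfig, assign_pseudo_labels
from segssl.synthetic import SyntheticConfig, generate_segments


def tiny_synth_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A miniature 3-class dataset for fast pipeline tests."""
    defaults = dict(
        n_classes=3,
        segments_per_class=4,
        segment_length_range=(150, 260),
        sampling_rate_hz=50.0,
        class_signatures=[
            [[(1.0, 1.0)], [(1.0, 0.5)], [(2.0, 0.3)]],
            [[(3.0, 0.8)], [(3.0, 1.0)], [(6.0, 0.2)]],
            [[(6.0, 0.9)], [(6.0, 0.4)], [(12.0, 0.5)]],
        ],
        noise_sigma=0.2,
        phase_mode="per_segment",
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_segments():
    return generate_segments(tiny_synth_config())


@pytest.fixture(scope="session")
def tiny_index(tiny_segments):
    return assign_pseudo_labels(
        tiny_segments, WindowingConfig(window_length=64, stride=32)
    )


@pytest.fixture(scope="session")
def small_spec():
    return ModelSpec(channels=(8, 12, 16), kernel=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
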