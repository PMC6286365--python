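import pytest

from qhtskit.config import PipelineConfig, SynthSection
from qhtskit.plates import PlateLayout
from qhtskit.synth import AssayModel, make_library

@pytest.fixture
def layout():
    return PlateLayout()


@pytest.fixture
def clean_assay():
    """Noise-free assay under the optimised screening conditions."""
    return AssayModel(noise_cv=0.0)


@pytest.fixture
def noisy_assay():
    return AssayModel(noise_cv=0.05)


@pytest.fixture
def small_library():
    return make_library(n_inactive=60, n_true=4, n_counter_fp=5, n_promiscuous=3, seed=7)


@pytest.fixture
def small_config():
    """Small but complete screen configuration for end-to-end runs."""
    return PipelineConfig(
        seed=11,
        synth=SynthSection(n_inactive=150, n_true=5, n_counter_fp=8, n_promiscuous=4),
    )


@pytest.fixture
def noise_free_config(small_config):
    synth = small_config.synth.model_copy(update={"noise_cv": 0.0})
    return small_config.model_copy(update={"synth": synth})

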