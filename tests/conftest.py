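import pytest

from lifmap import (DEFAULT_PARAMS, MappingConfig, StimulusSpec, frozen_table1)


@pytest.fixture(scope="session")
def base_params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def mapping():
    return MappingConfig()


@pytest.fixture(scope="session")
def bias_stim():
    return StimulusSpec.bias(200.0)


@pytest.fixture(scope="session")
def spike_stim():
    return StimulusSpec.spikes(frozen_table1(), weight=0.5)
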