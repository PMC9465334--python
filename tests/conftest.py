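import numpy as np
import pytest

from ecochg import (
    StimulusSpec,
    SynthesisParams,
    amplitude_for_snr,
    preprocess_recording,
    synth_recording,
)


@pytest.fixture
def stim500():
    return StimulusSpec(frequency=500)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(stim500):
    """100-epoch/polarity noise-only recording, unit noise SD."""
    return synth_recording(
        SynthesisParams(stimulus=stim500, cm_amplitude=0.0, seed=101)
    )


@pytest.fixture
def signal_recording(stim500):
    """Strong (20 dB raw-DIF SNR) 500 Hz CM recording."""
    amp = amplitude_for_snr(stim500, 20.0)
    return synth_recording(
        SynthesisParams(stimulus=stim500, cm_amplitude=amp, seed=202)
    )


@pytest.fixture
def preprocessed_signal(signal_recording):
    return preprocess_recording(signal_recording)
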