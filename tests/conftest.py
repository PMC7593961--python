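import numpy as np
import pytest

from abrffr.preprocess import AveragedResponse


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_response(waveform, sampling_rate, t0=0.0, noise_variance=0.0):
    """Wrap a bare waveform as an AveragedResponse for measurement tests."""
    n = len(waveform)
    times = t0 + np.arange(n) / sampling_rate
    return AveragedResponse(
        waveform=np.asarray(waveform, dtype=float),
        times=times,
        weights=np.ones(1),
        noise_variance=noise_variance,
        n_epochs=1,
    )


@pytest.fixture
def response_factory():
    return make_response
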