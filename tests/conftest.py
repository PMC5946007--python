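import numpy as np
import pytest

from blankloss import (
    GammaISI,
    StimulationProtocol,
    default_template,
    generate_spike_train,
    synthesize_trace,
)


@pytest.fixture(scope="session")
def tonic_model():
    """Tonically firing cell: mean rate 1.12 Hz, Gamma shape 2."""
    return GammaISI.from_rate(1.12, 2.0)


@pytest.fixture(scope="session")
def hfs_protocol():
    """High-frequency stimulation: 130 Hz, 2 ms total blanking window."""
    return StimulationProtocol.from_blanking_window(f_st=130.0, t_b=2e-3)


@pytest.fixture(scope="session")
def template():
    return default_template(sampling_rate=20_000.0)


@pytest.fixture(scope="session")
def clean_trace_factory(template):
    """Artifact-free noisy trace + its ground-truth train, keyed by seed."""

    def make(seed, duration=20.0, rate_hz=2.0, noise_sd=0.05):
        model = GammaISI.from_rate(rate_hz, 2.0)
        train = generate_spike_train(model, duration, seed)
        trace = synthesize_trace(
            train, template, None, None, noise_sd, template.sampling_rate, seed + 10_000
        )
        return train, trace

    return make
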