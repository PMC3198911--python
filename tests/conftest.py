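import numpy as np
import pytest

from semgtorque.synthetic import (
    SAMPLE_RATE_DEFAULT,
    clean_processed_recording,
    draw_subject,
    generate_recording,
)

# short protocol executions keep the unit tests fast; the acceptance
# suite exercises full-length (33,520-sample) recordings
SHORT_N = 7000


@pytest.fixture(scope="session")
def subject():
    return draw_subject("test-subject", seed=321)


@pytest.fixture(scope="session")
def short_recording(subject):
    return generate_recording(subject, n_samples=SHORT_N, seed=99)


@pytest.fixture(scope="session")
def clean_recording(subject):
    """Noise-free envelopes + ground-truth torque (short)."""
    return clean_processed_recording(subject, n_samples=SHORT_N)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
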