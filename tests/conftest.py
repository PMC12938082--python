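import numpy as np
import pytest

from lungsounds.audio import DEFAULT_SR, AudioRecording


@pytest.fixture(scope="session")
def sr() -> int:
    return DEFAULT_SR


@pytest.fixture(scope="session")
def tone():
    """Factory for pure-tone recordings."""

    def make(freq: float, duration: float = 2.0, amplitude: float = 0.5) -> AudioRecording:
        t = np.arange(int(round(duration * DEFAULT_SR))) / DEFAULT_SR
        return AudioRecording(amplitude * np.sin(2 * np.pi * freq * t))

    return make


@pytest.fixture(scope="session")
def small_cycle_corpus():
    """Twelve single-cycle items per class at 15 dB SNR (shared, read-only)."""
    from lungsounds.synth import generate_cycle_corpus

    return generate_cycle_corpus(12, seed=7, snr_db=15)
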