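import numpy as np
import pytest

from speechmark.audio import AudioSample

RATE = 22050


def tone(freq: float, duration: float, rate: float = RATE, amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(duration * rate))) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def sawtooth(freq: float, duration: float, rate: float = RATE) -> np.ndarray:
    t = np.arange(int(round(duration * rate))) / rate
    return 2.0 * ((freq * t) % 1.0) - 1.0


@pytest.fixture
def make_audio():
    def _make(samples, rate=RATE, **kwargs):
        kwargs.setdefault("word_count", 8)
        kwargs.setdefault("sex", "male")
        return AudioSample(samples=np.asarray(samples, dtype=float), rate=rate, **kwargs)

    return _make
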