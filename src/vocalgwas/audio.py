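"""Audio container and WAV I/O.

The unit the signal processing operates on is a mono waveform with a
sampling rate and an optional task/vowel label. Files are plain PCM
16-bit WAV, matching the study recordings (44.1 kHz, 16-bit), though any
rate is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile


class EmptyAudioError(ValueError):
    """Raised when an operation receives (or would produce) no audio."""


@dataclass
class AudioSegment:
    """Mono audio: float samples in [-1, 1], a rate in Hz and a label."""

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise EmptyAudioError("audio must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def with_samples(self, samples: np.ndarray) -> "AudioSegment":
        return replace(self, samples=np.asarray(samples, dtype=float))


def read_wav(path) -> AudioSegment:
    """Read a mono PCM WAV file into an AudioSegment scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioSegment(samples=np.asarray(data, dtype=float), rate=float(rate))


def write_wav(path, seg: AudioSegment) -> None:
    """Write an AudioSegment as PCM 16-bit WAV."""
    peak = np.max(np.abs(seg.samples))
    scaled = seg.samples / peak if peak > 1.0 else seg.samples
    wavfile.write(path, int(round(seg.rate)), np.round(scaled * 32767).astype(np.int16))
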