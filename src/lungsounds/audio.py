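"""Mono audio container and WAV I/O.

All pipeline stages consume :class:`AudioRecording`: a float64 mono waveform
plus its sampling rate. Lung-sound recordings are expected at 44.1 kHz (the
rate of single-channel electronic stethoscopes); other rates are resampled
before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_SR = 44100


@dataclass(frozen=True)
class AudioRecording:
    """Single-channel waveform with its sampling rate.

    Parameters
    ----------
    samples : np.ndarray
        1-D float array; amplitudes nominally in [-1, 1].
    sr : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sr: int = DEFAULT_SR

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"audio must be mono (1-D), got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains non-finite samples")
        if self.sr <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.sr}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sr

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path: str | Path) -> AudioRecording:
    """Read a WAV file as mono float audio.

    Integer PCM is scaled to [-1, 1]; multichannel input is averaged to mono.
    """
    sr, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioRecording(data, sr)


def write_wav(path: str | Path, audio: AudioRecording, subtype: str = "float32") -> None:
    """Write mono audio to WAV as PCM-16 or float-32."""
    if subtype == "pcm16":
        clipped = np.clip(audio.samples, -1.0, 1.0)
        data = (clipped * 32767.0).round().astype(np.int16)
    elif subtype == "float32":
        data = audio.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r} (use 'pcm16' or 'float32')")
    wavfile.write(str(path), audio.sr, data)


def resample(audio: AudioRecording, sr: int) -> AudioRecording:
    """Resample to ``sr`` Hz with a polyphase filter; no-op if already there."""
    if audio.sr == sr:
        return audio
    from math import gcd

    g = gcd(sr, audio.sr)
    out = resample_poly(audio.samples, sr // g, audio.sr // g)
    return AudioRecording(out, sr)
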