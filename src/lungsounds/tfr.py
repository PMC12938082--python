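"""Four time-frequency representations of lung-sound audio.

Each representation maps mono 44.1 kHz audio to a :class:`TFImage` — a 2-D
grid (frequency-like axis x time) with axis metadata — which
:func:`to_model_input` converts to the fixed 256x256x3 array consumed by the
classifiers:

* :func:`spectrogram` — STFT, 128-sample frames, 50% overlap, 1024-point FFT,
  one-sided power, ``10*log10`` scaling;
* :func:`mel_spectrogram` — 2048-sample periodic Hann window, 24-sample hop,
  4096-point FFT, 128 triangular Mel bands over 62.5 Hz - 15 kHz;
* :func:`gammatonegram` — 64-channel gammatone (auditory-model) filter bank,
  ERB-spaced center frequencies from 50 Hz to Nyquist, time-domain filtering,
  magnitudes integrated over 25 ms windows at a 10 ms hop, ``20*log10``
  scaling, optional display clipping to [-90, -30] dB;
* :func:`scalogram` — continuous wavelet transform with the analytic bump
  wavelet on a logarithmic scale grid (10 voices per octave).

The gammatone channels are implemented as 4th-order all-pole complex
resonators (a frequency-shifted one-pole lowpass raised to the 4th power),
whose magnitude response matches the classic gammatone filter; taking ``|y|``
of the complex output yields the per-channel envelope directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .audio import DEFAULT_SR, AudioRecording

#: floor added before logarithms so silence maps to a finite dB value
LOG_EPS = 1e-10

TF_KINDS = ("spectrogram", "mel", "gammatone", "scalogram")


@dataclass
class TFImage:
    """One time-frequency representation.

    ``values`` has shape ``(len(freq_axis), len(time_axis))`` with the
    frequency axis ascending. ``log_scaled`` records whether values are in
    decibels already.
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    kind: str
    log_scaled: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.kind not in TF_KINDS:
            raise ValueError(f"kind must be one of {TF_KINDS}, got {self.kind!r}")
        if self.values.shape != (len(self.freq_axis), len(self.time_axis)):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.freq_axis)}, {len(self.time_axis)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFImage values must be finite")


@dataclass(frozen=True)
class SpectrogramParams:
    frame: int = 128
    hop: int = 64
    nfft: int = 1024


@dataclass(frozen=True)
class MelBankParams:
    n_mels: int = 128
    f_lo: float = 62.5
    f_hi: float = 15000.0
    win: int = 2048
    hop: int = 24
    nfft: int = 4096

    def __post_init__(self) -> None:
        if not (self.f_lo < self.f_hi):
            raise ValueError("mel band edges must satisfy f_lo < f_hi")


@dataclass(frozen=True)
class GammatoneBankParams:
    n_channels: int = 64
    f_min: float = 50.0
    f_max: float | None = None  # None -> Nyquist
    twin: float = 0.025
    thop: float = 0.010
    erb_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 gammatone channels")
        if self.f_max is not None and self.f_min >= self.f_max:
            raise ValueError("f_min must be below f_max")


@dataclass(frozen=True)
class ScalogramParams:
    f_min: float = 20.0
    f_max: float | None = None  # None -> Nyquist
    voices_per_octave: int = 10
    #: bump wavelet shape: center mu and half-width sigma in radians
    mu: float = 5.0
    sigma: float = 0.6


def _frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    if len(x) < frame:
        raise ValueError(f"audio ({len(x)} samples) shorter than one frame ({frame})")
    return np.lib.stride_tricks.sliding_window_view(x, frame)[::hop]


def spectrogram(
    audio: AudioRecording, params: SpectrogramParams | None = None, log: bool = True
) -> TFImage:
    """One-sided STFT power spectrogram (Hamming window).

    Power is normalized so the two-sided per-frame sum equals the windowed
    frame energy (Parseval); one-sided bins except DC and Nyquist carry the
    doubled power. ``log`` applies ``10*log10(P + eps)``.
    """
    params = params or SpectrogramParams()
    sr = audio.sr
    frames = _frame_signal(audio.samples, params.frame, params.hop)
    window = np.hamming(params.frame)
    spec = np.fft.rfft(frames * window, n=params.nfft, axis=1)
    power = np.abs(spec) ** 2 / params.nfft
    power[:, 1:-1] *= 2.0  # fold negative frequencies (keep DC and Nyquist)
    values = power.T
    if log:
        values = 10.0 * np.log10(values + LOG_EPS)
    freqs = np.fft.rfftfreq(params.nfft, d=1.0 / sr)
    times = (np.arange(frames.shape[0]) * params.hop + params.frame / 2) / sr
    return TFImage(values, freqs, times, kind="spectrogram", log_scaled=log)


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(params: MelBankParams, sr: int = DEFAULT_SR) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filters on FFT bins.

    Returns (weights of shape (n_mels, nfft//2 + 1), band center frequencies).
    """
    if params.f_hi > sr / 2:
        raise ValueError(f"f_hi {params.f_hi} Hz above Nyquist {sr / 2} Hz")
    edges_mel = np.linspace(hz_to_mel(params.f_lo), hz_to_mel(params.f_hi), params.n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    fft_freqs = np.fft.rfftfreq(params.nfft, d=1.0 / sr)
    weights = np.zeros((params.n_mels, len(fft_freqs)))
    for m in range(params.n_mels):
        lo, ctr, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        weights[m] = np.maximum(0.0, np.minimum(up, down))
    return weights, edges_hz[1:-1]


def mel_spectrogram(
    audio: AudioRecording, params: MelBankParams | None = None, log: bool = True
) -> TFImage:
    """128-band mel spectrogram (periodic Hann, 2048-sample window, 24-sample hop)."""
    params = params or MelBankParams()
    sr = audio.sr
    frames = _frame_signal(audio.samples, params.win, params.hop)
    window = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(params.win) / params.win)  # periodic Hann
    spec = np.fft.rfft(frames * window, n=params.nfft, axis=1)
    power = np.abs(spec) ** 2 / params.nfft
    weights, centers = mel_filterbank(params, sr)
    values = weights @ power.T
    if log:
        values = 10.0 * np.log10(values + LOG_EPS)
    times = (np.arange(frames.shape[0]) * params.hop + params.win / 2) / sr
    return TFImage(values, centers, times, kind="mel", log_scaled=log)


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray | float:
    """Glasberg-Moore equivalent rectangular bandwidth, ERB(f) = 24.7(4.37 f/1000 + 1)."""
    return 24.7 * (4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def hz_to_erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate (ERB-number) scale: 21.4 log10(4.37 f / 1000 + 1)."""
    return 21.4 * np.log10(4.37 * np.asarray(f, dtype=float) / 1000.0 + 1.0)


def erb_rate_to_hz(u: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(u, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_center_freqs(params: GammatoneBankParams | None = None, sr: int = DEFAULT_SR) -> np.ndarray:
    """ERB-rate-uniform center frequencies from ``f_min`` up to Nyquist, ascending."""
    params = params or GammatoneBankParams()
    f_max = params.f_max if params.f_max is not None else sr / 2
    u = np.linspace(hz_to_erb_rate(params.f_min), hz_to_erb_rate(f_max), params.n_channels)
    freqs = np.asarray(erb_rate_to_hz(u))
    freqs[0], freqs[-1] = params.f_min, f_max  # exact endpoints
    return freqs


def _gammatone_channel(x: np.ndarray, fc: float, sr: int, erb_width: float) -> np.ndarray:
    """Envelope of one 4th-order all-pole gammatone channel (complex demod form)."""
    b = 1.019 * erb_width * float(erb_bandwidth(fc))
    T = 1.0 / sr
    pole = np.exp(-2.0 * np.pi * b * T + 2j * np.pi * fc * T)
    a = np.poly([pole] * 4)
    gain = np.abs(1.0 - pole * np.exp(-2j * np.pi * fc * T)) ** 4
    from scipy.signal import lfilter

    y = lfilter([gain], a, x)
    return np.abs(y)


def gammatonegram(
    audio: AudioRecording,
    params: GammatoneBankParams | None = None,
    log: bool = True,
    clip_db: tuple[float, float] | None = None,
) -> TFImage:
    """64-channel gammatonegram: filter-bank envelopes integrated per window.

    Each channel's envelope is reduced to its RMS over ``twin``-second windows
    advancing by ``thop``; ``log`` applies ``20*log10``. ``clip_db`` limits
    the displayed dynamic range (export only; leave None for model inputs).
    """
    params = params or GammatoneBankParams()
    sr = audio.sr
    win = int(round(params.twin * sr))
    hop = int(round(params.thop * sr))
    x = audio.samples
    if len(x) < win:
        raise ValueError(f"audio ({len(x)} samples) shorter than one window ({win})")
    freqs = erb_center_freqs(params, sr)
    n_frames = (len(x) - win) // hop + 1
    values = np.empty((params.n_channels, n_frames))
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    for ch, fc in enumerate(freqs):
        env = _gammatone_channel(x, fc, sr, params.erb_width)
        values[ch] = np.sqrt(np.mean(env[idx] ** 2, axis=1))
    if log:
        values = 20.0 * np.log10(values + LOG_EPS)
        if clip_db is not None:
            values = np.clip(values, clip_db[0], clip_db[1])
    times = (np.arange(n_frames) * hop + win / 2) / sr
    return TFImage(values, freqs, times, kind="gammatone", log_scaled=log)


def _bump_hat(omega: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Bump wavelet in the frequency domain (analytic, support (mu-sigma, mu+sigma))."""
    w = (omega - mu) / sigma
    out = np.zeros_like(omega)
    inside = (np.abs(w) < 1.0) & (omega > 0)
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - w[inside] ** 2))
    return out


def scalogram_frequencies(params: ScalogramParams, sr: int = DEFAULT_SR) -> np.ndarray:
    f_max = params.f_max if params.f_max is not None else sr / 2
    n = int(np.floor(params.voices_per_octave * np.log2(f_max / params.f_min))) + 1
    freqs = params.f_min * 2.0 ** (np.arange(n) / params.voices_per_octave)
    return freqs[freqs <= f_max + 1e-9]


def scalogram(audio: AudioRecording, params: ScalogramParams | None = None) -> TFImage:
    """CWT magnitude with the analytic bump wavelet.

    Scales are chosen so pseudo-frequencies (``mu / (2 pi s)`` in cycles per
    sample) form a log grid with ``voices_per_octave`` steps per octave from
    ``f_min`` to Nyquist; rows are ordered by ascending frequency. One column
    per sample. Values are linear magnitudes (no log), float32.
    """
    params = params or ScalogramParams()
    sr = audio.sr
    x = audio.samples
    n = len(x)
    freqs = scalogram_frequencies(params, sr)
    X = np.fft.fft(x)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample
    values = np.empty((len(freqs), n), dtype=np.float32)
    for k, f in enumerate(freqs):
        s = params.mu * sr / (2.0 * np.pi * f)  # scale with pseudo-frequency f
        psi = _bump_hat(s * omega, params.mu, params.sigma)
        values[k] = np.abs(np.fft.ifft(X * psi)).astype(np.float32)
    times = np.arange(n) / sr
    return TFImage(values, freqs, times, kind="scalogram", log_scaled=False)


def to_model_input(img: TFImage, size: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Fixed-size model input: min-max normalize, bilinear resize, 3 channels.

    A constant grid (degenerate min-max) maps to all zeros. Output values lie
    in [0, 1] with shape ``size + (3,)``.
    """
    v = np.asarray(img.values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in TFImage")
    lo, hi = v.min(), v.max()
    v = np.zeros_like(v) if hi - lo <= 0 else (v - lo) / (hi - lo)
    resized = _sk_resize(v, size, order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    resized = np.clip(resized, 0.0, 1.0)
    return np.repeat(resized[:, :, None], 3, axis=2)


_REPRESENTATIONS = {
    "spectrogram": spectrogram,
    "mel": mel_spectrogram,
    "gammatone": gammatonegram,
    "scalogram": scalogram,
}


def compute_representation(audio: AudioRecording, kind: str, **kwargs) -> TFImage:
    """Dispatch by representation name ('spectrogram', 'mel', 'gammatone', 'scalogram')."""
    try:
        fn = _REPRESENTATIONS[kind]
    except KeyError:
        raise ValueError(f"unknown representation {kind!r}; expected one of {list(_REPRESENTATIONS)}")
    return fn(audio, **kwargs)


def save_tfimage(img: TFImage, path: str | Path) -> None:
    """Write a TFImage as an NPZ bundle (values + axes + kind)."""
    np.savez(
        str(path),
        values=img.values,
        freq_axis=img.freq_axis,
        time_axis=img.time_axis,
        kind=img.kind,
        log_scaled=img.log_scaled,
    )


def load_tfimage(path: str | Path) -> TFImage:
    with np.load(str(path)) as z:
        return TFImage(
            z["values"], z["freq_axis"], z["time_axis"], str(z["kind"]), bool(z["log_scaled"])
        )


def export_png(img: TFImage, path: str | Path, clip_db: tuple[float, float] | None = None) -> None:
    """Render a TFImage to PNG (matplotlib, viridis, log-frequency-friendly)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = img.values
    if clip_db is not None and img.log_scaled:
        v = np.clip(v, clip_db[0], clip_db[1])
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.pcolormesh(img.time_axis, img.freq_axis, v, shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(img.kind)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
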