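"""Synthetic auscultation recordings with known ground truth.

Clinical lung-sound corpora are rarely redistributable, so every downstream
stage of the pipeline (segmentation, featurization, classification) is
exercised on synthetic recordings that emulate the acoustics reported in the
auscultation literature:

* **normal** — soft band-limited (100-600 Hz) breath noise under an
  inhale/exhale double-hump amplitude envelope, inspiration louder, with a
  short end-expiratory pause closing each cycle;
* **rhonchi** — normal breath noise plus a low-pitched amplitude-modulated
  tonal component near 150 Hz, concentrated in expiration (the snoring /
  whistling quality of airway-narrowing sounds);
* **fine crackle** — normal breath noise plus many short (≈5 ms) damped
  sinusoids at 400-800 Hz clustered in inspiration (sudden opening of small
  airways);
* **coarse crackle** — normal breath noise plus fewer, longer (≈15 ms)
  damped sinusoids at 150-350 Hz (low-pitched bubbling of mucous airways).

These four classes are separable by construction (distinct spectral bands and
transient structure); they are acoustic stand-ins, not clinical facsimiles.

Each recording concatenates 3-7 respiratory cycles whose durations fall in
the physiologically plausible 1.25-5.5 s range, and carries exact boundary
annotations plus per-event onsets, so segmentation accuracy can be scored
against ground truth. Additive white noise is scaled to a requested SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.signal import butter, sosfilt

from .audio import DEFAULT_SR, AudioRecording, write_wav

SOUND_CLASSES = ("normal", "rhonchi", "fine_crackle", "coarse_crackle")

#: admissible respiratory-cycle duration range (seconds)
DURATION_RANGE = (1.25, 5.5)

#: default cycle-duration sampler range, kept inside the admissible range
DEFAULT_DURATION_SAMPLER_RANGE = (1.5, 4.5)

_DEFAULT_EVENT_DENSITY = {"fine_crackle": 20.0, "coarse_crackle": 8.0}


@dataclass(frozen=True)
class CycleSpec:
    """Parameters of one synthetic respiratory cycle.

    Parameters
    ----------
    sound_class : str
        One of ``normal``, ``rhonchi``, ``fine_crackle``, ``coarse_crackle``.
    duration : float
        Cycle length in seconds, inside ``duration_range``.
    inspiration_fraction : float
        Fraction of the breath spent inhaling, in (0, 1).
    event_density : float
        Number of crackle transients per cycle (crackle classes only).
    snr_db : float
        Target signal-to-noise ratio when noise is added downstream.
    seed : int
        Seed for the cycle's private random stream.
    duration_range : tuple of float
        Admissible (min, max) cycle duration in seconds.
    """

    sound_class: str
    duration: float
    inspiration_fraction: float = 0.45
    event_density: float | None = None
    snr_db: float = np.inf
    seed: int = 0
    duration_range: tuple[float, float] = DURATION_RANGE

    def __post_init__(self) -> None:
        if self.sound_class not in SOUND_CLASSES:
            raise ValueError(
                f"unknown sound class {self.sound_class!r}; expected one of {SOUND_CLASSES}"
            )
        lo, hi = self.duration_range
        if not (lo <= self.duration <= hi):
            raise ValueError(
                f"cycle duration {self.duration} s outside admissible range [{lo}, {hi}] s"
            )
        if not (0.0 < self.inspiration_fraction < 1.0):
            raise ValueError("inspiration_fraction must lie in (0, 1)")
        if self.event_density is None:
            object.__setattr__(
                self, "event_density", _DEFAULT_EVENT_DENSITY.get(self.sound_class, 0.0)
            )
        if self.event_density < 0:
            raise ValueError("event_density must be >= 0")


@dataclass
class SyntheticRecording:
    """Generated audio with ground-truth annotations.

    ``boundaries`` are half-open 0-based sample spans ``[start, end)``, one per
    respiratory cycle, contiguous by construction. ``events`` holds
    ``(onset_sample, kind)`` pairs for transient events. ``clean`` and
    ``noise`` retain the two additive parts so the realized SNR can be
    recomputed exactly.
    """

    audio: AudioRecording
    boundaries: list[tuple[int, int]]
    label: str
    events: list[tuple[int, str]] = field(default_factory=list)
    clean: np.ndarray | None = None
    noise: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.boundaries:
            if start != prev_end or end <= start:
                raise ValueError("boundaries must be contiguous, increasing spans")
            prev_end = end
        if self.boundaries and prev_end != len(self.audio):
            raise ValueError("boundary spans must cover the whole recording")

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)

    def boundary_times(self) -> np.ndarray:
        """All distinct boundary instants in seconds (n_cycles + 1 values)."""
        pts = [self.boundaries[0][0]] + [end for _, end in self.boundaries]
        return np.asarray(pts, dtype=float) / self.audio.sr


def _bandpass_noise(rng: np.random.Generator, n: int, sr: int, lo: float, hi: float) -> np.ndarray:
    sos = butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    return x / (np.std(x) + 1e-12)

def _hump(n: int) -> np.ndarray:
    """Raised-cosine hump on [0, 1]."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return np.sin(np.pi * t) ** 2


def _breath_envelope(
    n: int, sr: int, inspiration_fraction: float
) -> tuple[np.ndarray, int, int]:
    """Amplitude envelope of one cycle.

    Returns (envelope, inspiration_end_sample, pause_start_sample). The
    envelope is two overlapping raised-cosine humps (inspiration louder) and a
    near-silent end-expiratory pause.
    """
    pause = int(min(0.30, 0.10 * n / sr) * sr)
    breath = n - pause
    insp_end = int(round(inspiration_fraction * breath))
    env = np.zeros(n)
    # overlap the humps by 25% of the shorter phase so the mid-cycle dip stays shallow
    insp_len = min(breath, int(round(insp_end * 1.25)))
    exp_start = max(0, int(round(insp_end * 0.75)))
    env[:insp_len] += _hump(insp_len)
    env[exp_start:breath] += 0.65 * _hump(breath - exp_start)
    env /= env.max() + 1e-12
    env += 0.02  # faint baseline so the pause is quiet, not digital silence
    return env, insp_end, breath


def _damped_sinusoid(sr: int, freq: float, decay_s: float, dur_s: float) -> np.ndarray:
    n = max(1, int(round(dur_s * sr)))
    t = np.arange(n) / sr
    return np.exp(-t / decay_s) * np.sin(2 * np.pi * freq * t)


def _place_events(
    rng: np.random.Generator, n_events: int, lo: int, hi: int, min_gap: int
) -> np.ndarray:
    """Draw n_events onsets in [lo, hi) with pairwise gaps >= min_gap."""
    if n_events == 0 or hi <= lo:
        return np.empty(0, dtype=int)
    span = hi - lo
    # jittered grid guarantees the gap whenever the span allows it
    slot = max(span // n_events, min_gap)
    onsets = []
    for k in range(n_events):
        base = lo + k * slot
        if base >= hi:
            break
        jitter = rng.integers(0, max(1, slot - min_gap))
        onsets.append(min(base + jitter, hi - 1))
    return np.asarray(onsets, dtype=int)


def generate_cycle(
    spec: CycleSpec, sr: int = DEFAULT_SR
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Synthesize one clean respiratory cycle.

    Returns
    -------
    waveform : np.ndarray
        Exactly ``round(duration * sr)`` samples, peak amplitude <= 1.
    events : list of (onset_sample, kind)
        Onsets of transient events (crackle bursts, rhonchus tone start).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * sr))
    env, insp_end, pause_start = _breath_envelope(n, sr, spec.inspiration_fraction)

    # crackle classes carry a quieter vesicular component so the explosive
    # transients dominate the waveform, as they do on clinical recordings
    base_amp = 0.2 if spec.sound_class in ("fine_crackle", "coarse_crackle") else 0.35
    x = base_amp * _bandpass_noise(rng, n, sr, 100.0, 600.0) * env
    events: list[tuple[int, str]] = []

    if spec.sound_class == "rhonchi":
        f0 = rng.uniform(130.0, 170.0)
        t = np.arange(n) / sr
        am = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(8.0, 16.0) * t + rng.uniform(0, 2 * np.pi))
        exp_env = np.zeros(n)
        exp_env[insp_end:pause_start] = _hump(pause_start - insp_end)
        tone = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        x += 0.55 * tone * am * exp_env
        events.append((insp_end, "rhonchus"))
    elif spec.sound_class in ("fine_crackle", "coarse_crackle"):
        fine = spec.sound_class == "fine_crackle"
        n_events = int(round(spec.event_density))
        dur_s = 0.005 if fine else 0.015
        decay_s = dur_s / 3.0
        # fine crackles cluster in inspiration; coarse spill into early expiration
        window_end = insp_end if fine else min(pause_start, int(insp_end * 1.5))
        lo = int(0.05 * window_end)
        min_gap = int((3 if fine else 2) * dur_s * sr)
        onsets = _place_events(rng, n_events, lo, max(lo + 1, window_end), min_gap)
        for onset in onsets:
            freq = rng.uniform(400.0, 800.0) if fine else rng.uniform(150.0, 350.0)
            burst = _damped_sinusoid(sr, freq, decay_s, dur_s * 1.6)
            # crackles are explosive and conspicuous against the breath noise
            amp = 1.8 * rng.uniform(0.85, 1.0)
            stop = min(n, onset + len(burst))
            x[onset:stop] += amp * burst[: stop - onset]
            events.append((int(onset), spec.sound_class))

    peak = np.abs(x).max()
    if peak > 1.0:
        x /= peak * 1.01
    return x, events


def generate_recording(
    sound_class: str,
    n_cycles: int,
    cycle_duration_sampler: Callable[[np.random.Generator], float] | None = None,
    snr_db: float = np.inf,
    seed: int = 0,
    sr: int = DEFAULT_SR,
    inspiration_fraction: float = 0.45,
    event_density: float | None = None,
    allow_any_cycle_count: bool = False,
    clip_durations: bool = False,
) -> SyntheticRecording:
    """Concatenate ``n_cycles`` cycles of one class and add noise at ``snr_db``.

    The boundary list marks exactly the concatenation points. ``snr_db=inf``
    yields the clean concatenation. A sampler returning a duration outside the
    admissible range raises, unless ``clip_durations`` clamps it.
    """
    if not allow_any_cycle_count and not (3 <= n_cycles <= 7):
        raise ValueError(
            f"n_cycles={n_cycles} outside the default 3..7 range "
            "(pass allow_any_cycle_count=True to override)"
        )
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    lo_s, hi_s = DEFAULT_DURATION_SAMPLER_RANGE
    if cycle_duration_sampler is None:
        cycle_duration_sampler = lambda g: g.uniform(lo_s, hi_s)  # noqa: E731

    seeds = np.random.SeedSequence(seed).spawn(n_cycles + 1)
    pieces: list[np.ndarray] = []
    boundaries: list[tuple[int, int]] = []
    events: list[tuple[int, str]] = []
    pos = 0
    for k in range(n_cycles):
        dur = float(cycle_duration_sampler(rng))
        lo, hi = DURATION_RANGE
        if not (lo <= dur <= hi):
            if clip_durations:
                dur = min(max(dur, lo), hi)
            else:
                raise ValueError(
                    f"sampled cycle duration {dur:.3f} s outside admissible range [{lo}, {hi}] s"
                )
        spec = CycleSpec(
            sound_class=sound_class,
            duration=dur,
            inspiration_fraction=inspiration_fraction,
            event_density=event_density,
            snr_db=snr_db,
            seed=int(seeds[k].generate_state(1)[0] % (2**31)),
        )
        wave, cycle_events = generate_cycle(spec, sr=sr)
        pieces.append(wave)
        boundaries.append((pos, pos + len(wave)))
        events.extend((pos + onset, kind) for onset, kind in cycle_events)
        pos += len(wave)

    clean = np.concatenate(pieces)
    if np.isinf(snr_db):
        noise = np.zeros_like(clean)
    else:
        noise_rng = np.random.default_rng(seeds[-1].generate_state(1)[0] % (2**31))
        noise = noise_rng.standard_normal(len(clean))
        p_signal = float(np.mean(clean**2))
        p_target = p_signal / (10.0 ** (snr_db / 10.0))
        noise *= np.sqrt(p_target / float(np.mean(noise**2)))
    mix = clean + noise
    peak = np.abs(mix).max()
    if peak > 1.0:  # common scale keeps the clean/noise power ratio intact
        clean, noise, mix = clean / peak, noise / peak, mix / peak
    return SyntheticRecording(
        audio=AudioRecording(mix, sr),
        boundaries=boundaries,
        label=sound_class,
        events=events,
        clean=clean,
        noise=noise,
        seed=seed,
    )


def generate_corpus(
    n_per_class: int,
    seed: int = 0,
    snr_db: float = np.inf,
    classes: Sequence[str] = SOUND_CLASSES,
    sr: int = DEFAULT_SR,
    n_cycles_range: tuple[int, int] = (3, 7),
) -> list[SyntheticRecording]:
    """Generate a balanced labelled corpus of multi-cycle recordings.

    ``n_per_class`` recordings per class, each with a uniformly drawn number
    of cycles in ``n_cycles_range``. Deterministic in ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    top = np.random.SeedSequence(seed)
    recs: list[SyntheticRecording] = []
    for ci, cls in enumerate(classes):
        child = np.random.SeedSequence(entropy=top.entropy, spawn_key=(ci,))
        rng = np.random.default_rng(child.generate_state(1)[0] % (2**31))
        for k in range(n_per_class):
            n_cycles = int(rng.integers(n_cycles_range[0], n_cycles_range[1] + 1))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            recs.append(
                generate_recording(cls, n_cycles, snr_db=snr_db, seed=rec_seed, sr=sr)
            )
    return recs


def generate_cycle_corpus(
    n_per_class: int,
    seed: int = 0,
    snr_db: float = np.inf,
    classes: Sequence[str] = SOUND_CLASSES,
    sr: int = DEFAULT_SR,
) -> list[SyntheticRecording]:
    """Generate a balanced corpus of *single-cycle* items.

    Mirrors how a cycle-level database is compiled clinically: multi-cycle
    recordings are generated, then sliced at their ground-truth boundaries
    until ``n_per_class`` cycles per class are collected. Each returned item
    is a one-cycle :class:`SyntheticRecording`.
    """
    top = np.random.SeedSequence(seed)
    items: list[SyntheticRecording] = []
    for ci, cls in enumerate(classes):
        child = np.random.SeedSequence(entropy=top.entropy, spawn_key=(1000 + ci,))
        rng = np.random.default_rng(child.generate_state(1)[0] % (2**31))
        cycles: list[SyntheticRecording] = []
        while len(cycles) < n_per_class:
            n_cycles = int(rng.integers(3, 8))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_recording(cls, n_cycles, snr_db=snr_db, seed=rec_seed, sr=sr)
            for start, end in rec.boundaries:
                if len(cycles) >= n_per_class:
                    break
                cycles.append(
                    SyntheticRecording(
                        audio=AudioRecording(rec.audio.samples[start:end], sr),
                        boundaries=[(0, end - start)],
                        label=cls,
                        events=[
                            (on - start, kind)
                            for on, kind in rec.events
                            if start <= on < end
                        ],
                        seed=rec_seed,
                    )
                )
        items.extend(cycles)
    return items


def save_recording(rec: SyntheticRecording, path: str | Path, subtype: str = "float32") -> None:
    """Write a recording as WAV plus a JSON sidecar with its annotations."""
    path = Path(path)
    write_wav(path, rec.audio, subtype=subtype)
    sidecar = {
        "label": rec.label,
        "boundaries": [list(b) for b in rec.boundaries],
        "events": [[int(on), kind] for on, kind in rec.events],
        "seed": rec.seed,
        "sr": rec.audio.sr,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
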