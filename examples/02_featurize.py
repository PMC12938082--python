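"""Compute the four time-frequency representations of one respiratory cycle.

Each representation maps the same audio to a different frequency axis
(linear FFT bins, mel bands, ERB-spaced gammatone channels, wavelet
pseudo-frequencies); all convert to the same fixed 256x256x3 model input.
"""

from lungsounds import (
    gammatonegram,
    generate_recording,
    mel_spectrogram,
    scalogram,
    spectrogram,
    to_model_input,
)
from lungsounds.audio import AudioRecording

rec = generate_recording("fine_crackle", n_cycles=3, snr_db=20, seed=3)
start, end = rec.boundaries[0]
cycle = AudioRecording(rec.audio.samples[start:end], rec.audio.sr)
print(f"one {cycle.duration:.2f} s fine-crackle cycle\n")

for name, img in [
    ("spectrogram", spectrogram(cycle)),
    ("mel-spectrogram", mel_spectrogram(cycle)),
    ("gammatonegram", gammatonegram(cycle)),
    ("scalogram", scalogram(cycle)),
]:
    rows, cols = img.values.shape
    f0, f1 = img.freq_axis[0], img.freq_axis[-1]
    print(f"{name:16s} {rows:4d} x {cols:6d}  freq axis {f0:7.1f} .. {f1:7.1f} Hz")
    model_in = to_model_input(img)
    print(f"{'':16s} -> model input {model_in.shape}, values in [{model_in.min():.2f}, {model_in.max():.2f}]")
# The row x column sizes differ per method (hop and bandwidth choices);
# the 256x256x3 conversion is what makes them comparable classifier inputs.
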