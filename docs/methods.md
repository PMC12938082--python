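# Methods

This note documents the models and algorithmic choices behind `lungsounds`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical decisions taken where
the design was genuinely open.

## Synthetic lung sounds

The generator produces labelled recordings of 3–7 respiratory cycles with
cycle durations drawn uniformly from [1.5, 4.5] s (inside the admissible
[1.25, 5.5] s range, so duration-filter edge effects cannot reject true
cycles), at 44.1 kHz mono. Each cycle is built from:

* a **breath-noise base**: white noise band-limited to 100–600 Hz under a
  double-hump amplitude envelope — two overlapping raised-cosine lobes
  (inspiration louder, expiration at 0.65 of its height, 25% overlap so the
  mid-cycle dip stays shallow) followed by a near-silent end-expiratory
  pause of min(0.3 s, 10% of the cycle). The pause is what makes cycle
  boundaries detectable: it is the quietest part of the cycle by
  construction, as it is physiologically.
* class-specific additions:
  - **rhonchi**: an amplitude-modulated (8–16 Hz) tone at 130–170 Hz
    confined to expiration — the low-pitched snoring/whistling quality of
    airway narrowing;
  - **fine crackle**: ~20 damped sinusoids of ≈5 ms at 400–800 Hz clustered
    in inspiration — the sudden-airway-opening transients;
  - **coarse crackle**: ~8 damped sinusoids of ≈15 ms at 150–350 Hz over
    inspiration and early expiration — low-pitched bubbling.

Crackle cycles use a quieter vesicular base (amplitude 0.2 vs 0.35) and
burst amplitudes of 1.8×U(0.85, 1) before peak normalization, so the
transients dominate the waveform the way clinically conspicuous crackles
do; this makes each individual burst recoverable by an independent
band-limited envelope-peak detector (verified in the tests), not merely
visible in aggregate statistics.

Noise is additive white Gaussian, scaled so that
10·log₁₀(P_clean/P_noise) equals the requested SNR exactly; the clean and
noise parts are retained on the recording so realized SNR is recomputable.
Determinism: every recording derives all randomness from its seed via
`numpy` seed sequences — same seed, bit-identical audio.

**What the generator does not emulate:** heart-sound contamination,
friction rubs, variable sensor coupling, airflow physiology, inter-subject
spectral variability, or recording-chain coloration. Classes are separable
by construction (distinct bands and transient structure). Passing tests on
this corpus therefore demonstrates that the pipeline machinery is correct
and noise-robust at the stated SNRs — not that the classifier reaches
clinical accuracy on real patients.

## Cycle segmentation

Band-energy envelope: 10 ms Hamming frames at 50% overlap, zero-padded to a
512-point FFT, per-frame sum of power bins in [80, 1000] Hz. A 10 ms window
has a ±200 Hz mainlobe, so rejection of components just below 80 Hz is
resolution-limited (a 30 Hz tone still leaks ≈30% of its energy into the
band); the band edge is about *relative* suppression of motion/heart energy,
not a brick wall.

Robust smoothing is Whittaker-type penalized least squares (second-
difference penalty, weight λ = 1e5 at the 4.99 ms envelope hop, an effective
width of ≈90 ms) with iteratively reweighted bisquare residual weights — an
isolated crackle-burst spike is down-weighted to irrelevance within a few
iterations while the breathing pattern passes through.

Boundary decision rule (the elements are individually standard; their
combination here is this package's reconstruction of
"boundaries from DTW pattern similarity", with every threshold exposed in
`BoundaryConfig`):

1. candidate minima of the smoothed envelope with prominence ≥ 5% of the
   envelope range and separation ≥ 1.25 s (the shortest plausible cycle);
2. a **depth gate**: a true boundary lies in the end-expiratory pause, so
   its envelope value must be within 20% of the envelope floor (measured
   against the 95th percentile as ceiling); mid-cycle inspiration/expiration
   dips sit well above this level;
3. boundary refinement to the midpoint between the minimum and the end of
   its low plateau (the pause midpoint), since the minimum itself sits
   mid-pause while the annotated boundary is the next-breath onset;
4. patterns delimited by the surviving minima (plus the envelope ends) are
   min-max normalized, resampled to ≤128 points, and compared by DTW; with
   the medoid pattern's distances d_i and their median m, a pattern with
   d_i > 2·m is atypical. A boundary is dropped only when **both** patterns
   it delimits are atypical — an internal spurious minimum splits one real
   cycle into two atypical halves and is merged away, while a boundary next
   to a single odd-but-real cycle keeps support from its other side.
   Patterns shorter than 1.25 s are merged into their more similar neighbor
   first.

DTW is the classic dynamic program over steps {(1,0),(0,1),(1,1)} with
|a_i − b_j| local cost. The row recurrence is evaluated with an exact
prefix-minimum unrolling of the within-row dependency, making each row a
vectorized O(m) operation; equality with exhaustive path enumeration is
asserted in the tests.

Frame-to-sample mapping uses frame centers; spans are 0-based, half-open.
Duration filtering keeps the closed interval [1.25, 5.5] s. On the standard
validation corpus (40 recordings, 15 dB SNR) boundary recall within
±0.25 s is 100%; recall is essentially unchanged at 0 dB.

## Time-frequency representations

* **Spectrogram** — one-sided STFT power (Hamming, 128/64/1024), normalized
  so two-sided per-frame power sums to windowed-frame energy; log scale
  10·log₁₀(P + 1e-10).
* **Mel-spectrogram** — periodic Hann 2048, hop 24, FFT 4096; 128
  triangular filters on the HTK mel scale over [62.5, 15000] Hz. The
  24-sample hop (≈1840 frames/s) is unusually dense and is honored as the
  configured default but exposed in `MelBankParams` for callers who prefer
  a conventional hop.
* **Gammatonegram** — 64 channels at ERB-rate-uniform centers
  (21.4·log₁₀(4.37f/1000 + 1)) from exactly 50 Hz to Nyquist. Each channel
  is a 4th-order all-pole complex gammatone resonator (a frequency-shifted
  one-pole low-pass raised to the 4th power, bandwidth 1.019·ERB(f), unit
  gain at center): filtering a real signal with the complex filter yields
  the channel envelope as |y| directly. Envelopes are integrated as RMS
  over 25 ms windows at a 10 ms hop; log scale 20·log₁₀(·); the [−90, −30]
  dB dynamic-range clip applies to display/export only, never to model
  inputs.
* **Scalogram** — analytic bump wavelet (frequency-domain support
  (μ−σ, μ+σ), μ = 5, σ = 0.6) evaluated by FFT, scales chosen so
  pseudo-frequencies form a 10-voices-per-octave log grid from 20 Hz to
  Nyquist. Values are linear magnitudes in float32 (one column per sample).

`to_model_input` min-max normalizes, bilinearly resizes to 256×256 and
replicates to 3 channels (grayscale replication rather than a rendered
colormap: deterministic and colormap-independent). A constant image maps to
zeros (degenerate min-max).

## Classifiers

The bundled backbone is a five-stage 3×3 stride-2 convolutional network
(channels 16-32-64-64-64, ReLU, He-scaled Gaussian weights drawn once from
a fixed seed), taking 256×256×3 to 8×8×64. It is deliberately frozen: fixed
random convolutional features preserve the coarse spectro-temporal layout
that separates the classes, require no weight downloads, and make every
result bit-reproducible. Pretrained backbones can be registered behind the
same `BackboneSpec` contract; with them, `feature_map_shape` becomes e.g.
7×7×1920 and partial fine-tuning is the backbone wrapper's responsibility.

Head inputs are standardized per feature on training-set moments before
optimization — raw ReLU features have wildly uneven scales, and a fixed
learning rate across them makes Adam erratic.

* **cnn** — flattened feature map → dense-128 ReLU → dense-4 softmax. The
  map is flattened rather than pooled because the discriminative cue is
  *where* on the frequency axis energy sits; global pooling averages that
  away.
* **cnn_lstm** — feature map → 9×64 sequence → BiLSTM-256 (forget-gate bias
  1) → FC-512 ReLU with L2 (1e-4) and dropout 0.5 → softmax. The 9×64
  reshaping splits the spatial grid into 3×3 regions (for 7×7 the balanced
  partition is sizes 3,2,2 per axis; other sizes use the nearest balanced
  split), averages each region, and reduces channels by contiguous-group
  means of ⌈C/64⌉ channels — chosen for linearity and oracle-checkability.
  Region traversal is row-major and defines LSTM time order.
* **cnn_svm** — global-average-pooled features, standardized, linear SVM
  (C = 1.0); the backbone weight hash is provably unchanged by training.

Training (network heads): Adam at 0.001, batch 16, categorical
cross-entropy, up to 100 epochs; learning rate halves after 5 epochs
without validation-loss improvement (floor 1e-5); early stopping after 15
epochs without improvement, restoring the minimum-validation-loss weights.
All heads run on a small in-package reverse-mode autodiff engine over
numpy (gradients verified against finite differences); training is
single-threaded and deterministic per seed.

## Evaluation protocol

Stratified cycle-level splits with largest-remainder rounding per class,
deterministic per (seed, repeat index); subject-level splitting (whole
subjects allocated to one partition) is available as the leakage-safe
alternative. Ten repeats by default; accuracy is reported as mean ± sample
standard deviation (ddof = 1) in percent, rounded to one decimal in
reports. The representative repeat is the one with accuracy closest to the
mean, ties toward the lower index; class-wise precision/recall/F1
(one-vs-rest; a zero denominator yields 0 with a warning) and the confusion
matrix are taken from it. Multiclass accuracy is trace/total — the standard
extension of the binary TP/TN form. A failing repeat is excluded from the
aggregate and recorded in the report with a warning.

Problem sizes used by the validation runs: the boundary-recovery corpus is
40 recordings (≈250 boundaries) at 15 dB SNR; the classification corpus is
400 single-cycle items (100 per class, sliced from multi-cycle recordings
at their ground-truth boundaries), with features computed once and shared
across the 10 repeats, since the frozen representation does not depend on
the split. At these sizes the full protocol (generation, featurization,
10 training runs) completes in a few minutes on one CPU; the observed
result with the default pipeline (gammatonegram + CNN head) is mean test
accuracy ≈ 91% ± 4 — the acceptance script recomputes it from scratch on
each run.

## Known limitations

* The boundary decision thresholds (depth gate 0.2, θ = 2.0, prominence
  5%) were designed against the synthetic envelope morphology; clinical
  envelopes with incomplete expiratory pauses (e.g. severe obstruction)
  would need the gate relaxed.
* The mel hop of 24 samples makes mel images ~40× wider than the other
  representations before resizing; this is a configuration fidelity choice,
  not a performance one.
* The scalogram stores one column per sample (float32); long recordings are
  better sliced into cycles before featurization.
* The tiny backbone is not a stand-in for pretrained accuracy levels;
  comparisons between representations or heads on synthetic data do not
  transfer to clinical rankings.
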