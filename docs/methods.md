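# Methods

## Problem setting

Four-class motor-imagery EEG decoding: given a trial in which a subject
imagines moving the left hand, right hand, foot or tongue, classify the
class from 22-channel EEG. The physiological signal is event-related
desynchronization/synchronization (ERD/ERS): imagining a hand movement
attenuates the Mu (8–14 Hz) and Beta (16–24 Hz) sensorimotor rhythms over
the contralateral motor cortex (channels C3/C4), foot imagery modulates
the midline channel Cz, and tongue imagery shows bilateral Beta changes.
The data layout throughout is the BCI Competition IV-2a one: 25 channels
(22 EEG + 3 EOG) at 250 Hz, 288 cue-annotated trials per subject, cue at
2 s and imagery from 3 s to 6 s within each trial.

## Preprocessing

1. **Band-pass 8–30 Hz** — 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`), i.e. zero-phase, on the continuous
   recording. Filtering before epoching avoids edge transients inside
   the analysis window. Only the band is fixed by the protocol; the
   realization (order, zero phase) is the standard MI-EEG choice.
2. **EOG removal** — exclusion of the three named EOG channels
   (`EOG-left`, `EOG-central`, `EOG-right`), taking 25 channels to 22.
   Regression-based ocular correction is deliberately out of scope; the
   target channel count matches plain exclusion.
3. **Epoching** — the 3–6 s imagery window of every trial, half-open in
   samples (`[onset + round(3·fs), onset + round(3·fs) + 750)` at
   250 Hz), 0-based.
4. **Wavelet-packet band selection** — a full `db4` packet tree to level
   5 with frequency-ordered (sequency) leaf indexing, so leaf *k* of 32
   passes band *k* of width 3.90625 Hz counted from DC. The four leaves
   tiling 7.8125–23.4375 Hz — the union of the two printed 7.8125 Hz-wide
   bands covering the Mu and Beta rhythms — are retained, all other leaf
   coefficients are zeroed, and the tree is inverted at the original
   length. Frequency ordering is essential: under natural (Paley) order
   the node→band mapping does not hold, because the high-pass branch of
   each split mirrors the spectrum. The tree is implemented as iterated
   `pywt.dwt`/`idwt` along the trial axis (vectorized over trials and
   channels) and is cross-checked in the tests against
   `pywt.WaveletPacket(order="freq")` leaf by leaf.
5. **Resampling 750 → 240 samples** — polyphase resampling to 80 Hz
   (3 s × 80 = 240). The retained content ends at 23.4375 Hz, well below
   the 40 Hz Nyquist of the target rate, so the step is lossless for the
   retained band while producing the 240-sample epoch format the network
   consumes. The step is configurable off (`output_samples=None`).

Degenerate inputs are rejected eagerly: band edges at or above Nyquist,
retained bands selecting no leaves, epochs shorter than `2^level`, and
trial windows extending past the recording (reported per trial index).

## Network

The `clrnet` variant is, in order:

* **CNN front-end** on the epoch treated as a single-plane 22 × 240
  image: conv 128@3×3 → conv 128@3×3 → maxpool 3×3 → conv 256@5×5 →
  conv 256@5×5 → maxpool 3×3 → dropout 0.5. All convolutions and the
  pools are stride-1 with same padding, so the spatial dimensions are
  preserved (22 × 240 × 256 features); stride-1 pooling performs no
  downsampling and is implemented literally as specified, with a
  stride-2 option exposed for smaller models. ReLU follows each
  convolution.
* **Projection** — the per-timestep feature columns (width
  22 · 256) pass through a learned linear map to width 200 = 2 · hidden,
  so the sequence entering the recurrent stack already has the feature
  width of a BiLSTM output and residual summands are shape-compatible.
* **Five BiLSTM blocks** B1..B5, 100 hidden units each, full-sequence
  outputs. Each direction runs the standard gated cell —
  `f, i, o = σ(·)`, candidate `tanh(·)`,
  `c_t = f ⊙ c_{t−1} + i ⊙ g`, `h_t = o ⊙ tanh(c_t)` — and the two
  hidden sequences are concatenated (width 200).
* **Residual cross-layer sums** `RES1 = B1 + B3`, `RES2 = RES1 + B5`,
  element-wise over full sequences and parameter-free. Full-sequence
  summation (rather than final states) is the shape-consistent reading
  of sequence-returning blocks; the read-out then takes the last time
  step of RES2.
* **Head** — dense 4 + softmax.

Ablation variants: `cnn` (front-end + flatten + dense head), `bilstm`
(raw time-major epochs into the five blocks), `cnn_bilstm` (no residual
sums; B5 feeds the read-out). `clrnet` and `cnn_bilstm` have identical
parameter counts since the sums add none.

The whole network, including backpropagation (BPTT through both LSTM
directions, transposed-kernel convolution gradients, argmax-scatter
pooling gradients) and the Adam optimizer, is implemented in NumPy in
`clrnet.nn` with float64 arithmetic. Gradients of every variant are
verified against central finite differences in the test suite; forward
passes are deterministic, and all weight initialization is uniform
fan-in from a single seeded generator per build.

## Training protocol

Batch size 8, 200 epochs ("iterations" read as passes over the data),
Adam with learning rate 1e-3 (unstated in the protocol; the common
default, logged in every run manifest), categorical cross-entropy,
per-subject models. The only statistic fitted during training is a
global input scale (the training set's standard deviation); it is never
computed from test trials, which the leakage test asserts. Two splits
are supported: `session_TE` (train on one session file, evaluate on the
other — the IV-2a protocol) and a stratified 50/50 split emulating two
sessions for simulated subjects. Which of these the original experiments
used is unknown; accuracies from the two protocols are not comparable
and every result carries its split in the run manifest.

## Simulator

`simulate_subject` generates: per-channel 1/f (α = 1) background noise
with a 10 µV RMS plus a white floor; ongoing Mu and Beta rhythms at
C3/Cz/C4 as band-filtered white noise (amplitude-modulated narrowband
processes, not sines, so wavelet band selection is meaningfully
exercised) with total rhythm power `snr` × background power, split
equally between the bands; class-dependent envelopes during the 3–6 s
imagery window with raised-cosine 0.25 s ramps (left → Mu+Beta power
× (1−erd_depth) at C4, right → at C3, foot → at Cz, tongue → Beta power
× (1+erd_depth) at C3 and C4); Poisson blink-like transients
(50–150 µV, ~0.4 s) on the EOG channels; 7 s trials separated by 1.5 s
rest (the paradigm fixes only within-trial timing). Defaults are the
study conditions: 72 trials per class (288 total), erd_depth 0.8,
snr 4, 4 blinks/min, seed-deterministic to the bit.

What the simulator does **not** model: volume conduction and channel
covariance (channels are independent), inter-subject variability,
non-stationary drifts, EMG or line-noise artifacts, and EOG bleed into
frontal EEG channels. Passing the recovery tests therefore shows that
the pipeline and network can extract class-dependent rhythm-power
structure under realistic spectra and SNR — not that the reported
real-data accuracies are reproduced. Those depend on real recordings and
an unstated train/test protocol; the published per-subject and mean
accuracies are kept as reference constants for side-by-side reporting
only.

## Problem sizes used in the checks

The analytic and property checks run at full data scale (288 trials,
22 × 750 → 22 × 240). The training-based checks use the full 288-trial
subject but a desk-scale architecture preset
(`ModelConfig.reduced()`: conv filters 8/8/16/16, hidden 32, stride-2
pooling, ~141 k parameters) and 30 training epochs, which reaches
≥ 0.99 held-out accuracy on the default simulated subject in about two
minutes of CPU; the full-size model (tens of millions of parameters) is
buildable and trainable through the same code paths but is intended for
real-data runs. The ablation ordering (clrnet ≥ cnn_bilstm ≥
max(cnn, bilstm)) is reported from short reduced runs for inspection
only; single short runs are too noisy to rank architectures and the
ranking claim belongs to the real-data experiments.

## Known limitations

* The GDF reading path is a thin wrapper over `mne.io.read_raw_gdf`;
  with no GDF fixture it is exercised only through its error branches in
  the tests.
* Leaves partially overlapping the retained band are zeroed, not kept;
  tones within ~2 Hz of a leaf edge lose a noticeable energy fraction to
  the `db4` transition bands (e.g. a 10 Hz tone retains ~0.88).
* Stride-1 same-padded max pooling preserves dimensions; the full-size
  model is consequently large and slow on CPU. The stride-2 option
  changes the architecture and is used only by the reduced preset.
* Whether the original 750 → 240 reduction was resampling or coefficient
  truncation is not documentable from the protocol text; resampling was
  chosen because it is lossless for the retained band and reproduces the
  printed epoch length.
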