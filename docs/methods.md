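# Methods

## Signal pipeline

Each trial is a `channels x samples` block at 128 Hz (32 EEG channels,
63 s in the DEAP layout). Processing per trial:

1. **Baseline removal** — the first `baseline_seconds` (default 3 s, the
   pre-stimulus interval) are dropped.
2. **Segmentation** — consecutive non-overlapping `segment_seconds`
   windows (default 3 s → 384 samples); a trailing remainder shorter
   than one window is discarded (floor rule).
3. **Band-pass** — 4th-order Butterworth per rhythm band (theta 4–8,
   alpha 8–13, beta 13–30, gamma 30–45 Hz), applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering is essential: any group delay
   would bias the instantaneous phase that the PLV is built on. Each
   3-s window is filtered independently by default; a `filter_whole`
   switch filters the trimmed 60 s before cutting instead (the order is
   genuinely ambiguous in PLV pipelines; both are supported, per-window
   is the default).
4. **Phase** — the analytic signal via the FFT Hilbert transform,
   computed per window without tapering or padding. The phase is the
   four-quadrant angle of `z(t)` (the two-quadrant arctan sometimes
   written for it cannot cover `[-pi, pi]`). Edge bias of the windowed
   Hilbert transform is accepted and bounded in tests with
   integer-cycle tones.
5. **PLV matrix** — all-pairs PLV computed as one complex Gram product
   `|Z Z^H|/N` with `Z = e^{i phi}`; verified in tests against an
   explicit double loop over all 496 channel pairs. The diagonal is set
   to 1 by definition (self-synchrony) rather than computed.

Matrices carry provenance (participant, video, window index, band,
level). **Group matrices** are element-wise means over all participants
for the same (video, window, band); convexity preserves symmetry, the
`[0, 1]` range and the unit diagonal. **Condition means** average all
matrices sharing a high/low label and reproduce per-band contrast maps.

Labels: a 1–9 self-rating binarizes at the strict threshold 4.5
(exactly 4.5 → low). Group matrices are labeled by the mean rating
across participants for that video, then the same threshold — a design
choice; majority vote is the obvious alternative, and on synthetic data
(ratings tightly clustered per condition) the two agree almost always.

## Synthetic cohort

The generator states a world in which every expected PLV is known in
closed form:

* Channel `i`, band `b`: `A_b sin(2 pi (f_b + delta_c) t + psi_c(t) +
  eps_i(t))` summed over bands, plus white noise (`noise_sd`, default
  0.1). Carriers default to band centres (6, 10.5, 21.5, 37.5 Hz).
* `psi_c` — community phase shared by all channels of community `c`:
  a random walk, step 0.05 rad/sample, so tones wander rather than
  repeat exactly. It cancels in within-community phase differences.
* `delta_c` — per-community carrier detuning on a 1 Hz grid
  (`detune_step`). Distinct communities then differ by an integer
  number of cycles per 3-s window, so cross-community relative phase
  sweeps full cycles and the expected cross-community PLV baseline
  is ~0. The random walk alone cannot deliver that baseline: a shared-
  variance walk decorrelates far too slowly over 3 s (segment PLV would
  stay near 0.9 between independent communities).
* `eps_i` — per-channel phase jitter: a stationary AR(1) Gaussian
  process with marginal standard deviation `jitter_sd` (condition- and
  band-resolvable) and correlation time 16 samples (125 ms). For a
  within-community pair the phase difference is `eps_i - eps_j`, so the
  expected PLV is the wrapped-Gaussian resultant
  `exp(-(s_i^2 + s_j^2)/2)` — the analytic recovery target.

The AR(1) correlation time is a deliberate compromise fixed a priori:
i.i.d. per-sample jitter would be spectrally flat and largely removed
by the band-pass filter (inflating recovered PLV), while very slow
jitter leaves too few effective samples per 3-s window (inflating the
resultant's noise floor). At 125 ms the jitter bandwidth (~1.3 Hz) fits
inside even the 4-Hz-wide theta band and a window holds ~24 effective
samples. Two residual biases remain and are documented rather than
tuned away: (a) the finite-sample resultant floor, ~+0.05 at jitter
levels near 1 rad — the PLV estimator is biased upward for any finite
window; (b) sideband clipping in the narrow theta band at large jitter
(≥ 1 rad), where recovery degrades to ~+0.2. Recovery validation
therefore uses the gamma band with a carrier at an integer number of
cycles per window (37 Hz); recovery at s ∈ {0, 0.5, 1} lands within
±0.10 of the closed form.

Ratings: each trial draws 4 ratings from a Gaussian (sd 1.0) around
the condition's `rating_means` entry (defaults 6.5 high / 2.5 low,
symmetric about the 4.5 threshold so labels balance), clipped to
[1, 9]. Conditions alternate by video index. All randomness derives
from `(seed, participant, video)`, so every trial is individually
reproducible.

What a green test does *not* establish: the generator produces
phase-modulated tones, not EEG — no 1/f background, no volume
conduction (which inflates real zero-lag PLV), no artifacts, no
inter-participant variability in community structure. Green means the
*machinery* (filters, phases, PLV, averaging, labeling, training) is
correct, not that real-data effect sizes will be reproduced.

## Classifier

Two convolution blocks (32 then 64 filters, 5 × 5, same padding, each
followed by batch-norm, 2 × 2 max-pool and dropout 0.4), then
flatten → dense(128, ReLU) → dense(2, softmax); 576 962 parameters for
32 × 32 input. Stated hyperparameters: dropout 0.4, batch 32, learning
rate 10⁻⁴. Choices the architecture description leaves open, fixed
here and overridable in `ModelConfig`: Adam optimizer with categorical
cross-entropy; pool window 2 × 2; dense width 128; at most 100 epochs
with early stopping (patience 10) on a validation slice; He-normal
initialisation. The train/test protocol is an explicitly seeded
stratified 80/20 split with 20 % of the training portion held out for
validation.

The network runs in float32 by default (float64 available via
`ModelConfig.dtype`, used by the numeric gradient-check test).
Backpropagation is verified against central differences for every
layer type; the conv biases are excluded from that check because the
following batch-norm absorbs them (their gradient is ~0 — they are
retained only to keep the conventional layer parameterisation).
Training is bit-reproducible for a fixed seed on one machine
(initialisation, dropout masks, shuffling and splits all derive from
it). Training-set accuracy in the history is accumulated over the
training batches themselves (dropout active), as deep-learning
frameworks report it; validation metrics use inference mode.

## Evaluation

Positive class = "high" for both dimensions. Accuracy, precision,
recall and F (= 2PR/(P+R), 0 when P+R = 0) and the ROC/PR curves with
trapezoid AUC are delegated to scikit-learn; the test-suite holds
independent brute-force oracles (explicit confusion table; Mann–Whitney
AUC with half-credit ties) and checks equivalence on random instances.
ROC is refused for single-class truth. `compare_levels` renders the
individual-vs-group per-band table with deltas.

## Numerical and degenerate-input policy

* All-zero signals have undefined phase → error, not NaN.
* PLV is clipped to 1 from above only to absorb `<=1e-16` floating
  excess; no other clipping.
* Matrices are validated on construction (square, entries in [0, 1]).
* Band edges at or above Nyquist are rejected.
* Ratings exactly 4.5, empty rating sets, single-class training sets
  and mismatched provenance all raise rather than guess.

## Known limitations

* Theta-band parameter recovery degrades at jitter ≥ 1 rad (sideband
  clipping); validated in gamma instead — see above.
* Per-window Hilbert phase carries edge bias of a few samples at each
  window end; integer-cycle tone tests bound it but it is not removed.
* Group labeling by mean rating is a convention; real corpora with
  polarized raters could flip labels relative to majority vote.
* Single-band inputs only; pooling all four bands into one classifier
  input is out of scope.
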