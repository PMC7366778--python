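# Methods

This note documents the models, defaults and design choices behind
`p300bci`, and what the synthetic-data experiments do and do not show.

## Protocol model

The speller presents a 6×6 grid; one repetition flashes each of the 12
rows/columns exactly once in a fresh uniform random permutation. Timing is
parameterized by flash, gap, inter-repetition and inter-character durations
plus a repetition count. Delays are counted **between consecutive units**
(`n−1` gaps, not `n`): this is the only reading under which the training
protocol (ISI 150 ms, 12 repetitions, 0.5 s/5 s delays) gives exactly
476.5 s for 15 characters, which anchors the whole timing model. Flash
onsets are accumulated as exact rational seconds and rounded to the nearest
sample once, so long sessions never accumulate floating-point drift. A
flash is a target iff it contains the attended character's row *or* column
— 2 of 12 per repetition, forced by the 360/2,160 epoch bookkeeping.

The per-decision time used in the ITR is stimulation time only,
`T = n_reps·12·ISI + (n_reps−1)·inter_rep`, with no processing or
inter-character latency: 13.55 s at online timing and 27.1 s at training
timing for 12 repetitions. This is the only convention under which both
reference ITR values (15.42 and 10.13 bits/min) reproduce, and 12 is
likewise the online repetition count consistent with both. The online
inter-character delay is not specified by the protocol; the package keeps
5 s as a stream-layout default, which never enters `T`.

## Synthetic sessions

The generator is the package's sole data source and defines its reference
conditions. Background noise is the sum of

* **pink (1/f) noise** (default sd 2 µV), synthesized by frequency-domain
  amplitude shaping `|X(f)| ∝ f^(−1/2)` with seeded random phases — an
  EEG-like spectrum that is exactly reproducible;
* a **10 Hz alpha sinusoid** (default 1 µV) with an independent random
  phase per channel — structured narrow-band interference inside the 1–20 Hz
  passband;
* **white sensor noise** (default sd 0.5 µV).

Every target flash adds a Gaussian bump (default amplitude 5 µV, peak
300 ms post-onset, width 60 ms, per-event latency jitter sd 20 ms) to all
channels, scaled by a fixed unit-norm spatial pattern — a raised cosine
over the middle third of the channel list, standing in for a
centro-parietal topography. Defaults were chosen once as plausible
mid-range ERP values; amplitudes of real P300s vary widely across subjects
and no fidelity to any particular recording is claimed. Overlapping
responses from flashes closer than the 500 ms epoch are summed linearly —
deliberately, because linear superposition is exactly the assumption of the
Toeplitz evoked model the xDAWN stage estimates.

**What passing tests show:** that the pipeline recovers planted structure
under its own model assumptions (correct linear algebra, correct
bookkeeping, correct causal processing). **What they do not show:**
robustness to blinks, EMG, electrode drift, volume conduction, non-Gaussian
or non-stationary noise, or subject-to-subject variability. The published
human accuracies are therefore not targets of the synthetic experiments.

## Preprocessing

Causal (forward-only) 4th-order Butterworth bandpass 1–20 Hz, then
decimation by 4 (500→125 Hz) with a causal anti-alias stage (redundant
given the 20 Hz cutoff vs the 62.5 Hz Nyquist, kept for safety), then
500 ms stimulus-locked epochs of exactly `floor(0.5·125) = 62` samples.
Zero-phase filtering is deliberately avoided: the method must run online,
where future samples do not exist; causality is also what makes the
streaming decoder provably identical to the offline run. The full 500 ms
window is retained per epoch (rather than a 250 ms sub-window) so the
250–500 ms P300 interval always lies inside the epoch; marker onsets are
rescaled by floor division on decimation. Epochs overrunning the recording
end are rejected and counted in the log.

## xDAWN

`A₁` is the least-squares solution of `X ≈ D₁A₁` via the normal equations
(the Gram matrix is `epoch_len × epoch_len`; rank deficiency raises with
the uncovered lags named). Expectations in the SSNR quotient are realized
as sample covariances normalized by the sample count; the denominator uses
the **total** signal covariance `XᵀX/n` as the quotient is written, not an
ERP-subtracted one. The generalized symmetric eigenproblem
`Σ₁u = λΣₓu` is solved by whitening + symmetric eigendecomposition
(`scipy.linalg.eigh`); if `Σₓ` is not positive definite a logged ridge
`ε = 10⁻¹⁰·tr(Σₓ)/C` is added. Eigenvector signs are fixed so the
largest-magnitude coefficient is positive, making fits deterministic.
Filters are fitted on the training session only and frozen for decoding.
The non-target response `A₂` is not separately modeled — its contribution
is part of the denominator's total covariance.

## Classifiers

All three detectors are authored in-package; scikit-learn appears only as
an independent cross-check in the tests.

* **LDA.** Fisher criterion `J(v) = vᵀS_b v / vᵀS_w v`, solved as the
  leading generalized eigenvector with shrinkage
  `S_w + 10⁻⁶·tr(S_w)/d·I` (186 features vs ~1,700 training epochs can be
  ill-conditioned). Bias = midpoint of the projected class means.
* **SVM.** Dual soft-margin problem with kernel `(x·y + 1)³`, solved by a
  maximal-violating-pair SMO loop; convergence when the KKT gap < 10⁻⁴
  (non-convergence raises with diagnostics). Default `C = 1` with class
  weights inversely proportional to class frequency, compensating the 1:5
  target/non-target imbalance; the reference study does not state its `C`.
* **MLP.** Two hidden tanh layers (32, 16) with a logistic output, exact
  backpropagated gradients, full-batch gradient descent (lr 0.5, 500
  iterations, seeded initialization). Inputs are standardized inside the
  model so the default learning rate is scale-free. Divergence (non-finite
  loss, or loss exploding an order of magnitude above its start — tanh
  saturation keeps even runaway training finite) raises with a
  smaller-lr suggestion. Layer sizes/lr/iterations are calibration
  defaults; only "two hidden layers, tanh" is fixed by the reference
  method.

Cross-validation is stratified 5-fold with a seeded shuffle; fold
accuracies are reported as mean ± sample (n−1) standard deviation — the
n−1 convention is verified against the published LDA row (89.56 ± 2.27).

## Decoding

Per-epoch scores are grouped per trial into a 12-stimulus × n_reps table
and **summed** over repetitions (the standard speller rule; thresholding
before aggregation would discard score magnitude). Row and column winners
are argmax with lowest-index tie-breaking (logged). The online simulator
processes the causal filter output and emits one decision per trial after
`n_reps` repetitions; because every filter is causal, computing the
filtered signal in one pass and slicing per trial is mathematically
identical to sample-by-sample streaming. Character→command mapping is a
pluggable dictionary defaulting to the identity.

## Metrics

Confusion counts define sensitivity TP/(TP+FN), precision TP/(TP+FP),
specificity TN/(TN+FP) and F = 2PS/(P+S); zero denominators raise rather
than return 0. The ITR uses the convention `0·log₂0 = 0`. `P` is
command-level accuracy and `T` stimulation time (see Protocol model).
Published tables are aggregated with column means and n−1 standard
deviations; recomputing from values printed at 4 decimals can differ from
a published aggregate in the last printed digit (e.g. F = 0.75365 from the
rounded SVM P1 inputs vs the printed 0.7537), which the tests tolerate at
one unit of printed precision.

## Problem sizes in the test suite

Exact checks run on closed forms and published tables in milliseconds.
Property checks use: one 15-character 64-channel training session and one
10-character held-out session at default conditions (pattern recovery,
high-SNR decoding); a 24-character zero-amplitude session (chance-level
decoding, binomial 95% interval of 1/36); and 20 seeded 6-character
sessions at 2 µV amplitude for the repetition-count monotonicity check —
moderate SNR keeps the accuracy-vs-repetitions curve away from floor and
ceiling so the comparison is informative. Plumbing tests use 8-channel
3-character sessions.

## Known limitations

* Synthetic noise is stationary and Gaussian-based; no artifacts.
* The epoch window choice (full 500 ms vs a 250 ms sub-window) is a
  documented interpretation, not a verified detail of the reference
  implementation; likewise the SSNR denominator (total covariance as
  printed).
* BrainVision import covers the common binary encodings via `mne` and maps
  stimulus codes through a user-supplied table; the original recordings'
  marker scheme is unknown, so no default table is shipped.
* No hyperparameter search, channel selection, artifact rejection or deep
  detectors — out of scope by design.
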