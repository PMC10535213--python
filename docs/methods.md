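# Methods

## The model

The classifier treats a subject's EEG as a sequence of short stationary
windows. Each 0.5-s window is summarized per channel and frequency band by
its differential entropy under a Gaussian assumption,
DE = ½ ln(2πe σ̂²) nats, with σ̂² the unbiased sample variance of the
band-filtered window. This reduces each window to a 4×9×9 tensor: four band
planes (θ 4–7, α 8–13, β 14–30, γ 31–50 Hz) on a 9×9 grid whose cells follow
the 10–20 electrode geometry (row 0 = prefrontal line, column 0 = left ear
side; the 32 montage channels occupy 32 cells, the remaining 49 cells are
identically zero).

Four convolutional blocks (3×3 same-padding convolution → batch
normalization → efficient channel attention → dropout → leaky ReLU, default
widths 64/128/256/64) encode each window; ECA pools each channel map to a
scalar, convolves across channels with an adaptive odd kernel
k = odd(⌊(log₂C + b)/γ⌋), b = 1, γ = 2, and gates channels with a sigmoid.
After 2×2 max pooling (9×9 → 4×4) and flattening, a bidirectional LSTM
(default hidden 128 per direction) reads runs of consecutive windows from
one trial; the final forward and backward hidden states are concatenated and
a linear layer with two sigmoid units produces class scores for
negative/positive. Training minimizes the MSE between scores and one-hot
labels with Adam. Predicted class is the argmax of the two units, exact ties
to class 0.

Separate models are trained for the valence and arousal dimensions; ratings
(1–9) binarize at 5, with 5 counted as negative/low.

## Individual Difference Module

A population model systematically misreads an unseen subject whose emotional
responses are stronger, weaker, delayed, or reported differently. The IDM
treats this as an observer problem: collect (score, label) pairs from part
of the subject's data, fit the monotone least-squares map from score to
label probability — weighted isotonic regression, solved exactly by
pair-adjacent violators — and apply the fitted step function to the
subject's remaining scores. One model is fitted per output unit. Fits are
evaluated right-continuously with clamping outside the observed score range;
exact score ties are pre-pooled to their weighted mean before PAV.

Two design points deserve emphasis:

- **Calibration split.** Per subject the data is split 50/50 (stratified,
  seeded) into a calibration part and an evaluation part; every "with IDM"
  number is computed on the evaluation part only, and is always paired with
  the "without IDM" accuracy *on the same part*, so the comparison has no
  leakage and no scale mismatch.
- **Tie handling at prediction.** Step functions are many-to-one, so the two
  units' calibrated values often coincide exactly (e.g. both 0 when scores
  are saturated and the calibration set is small). Breaking such ties toward
  class 0 would systematically overturn correct raw decisions, so calibrated
  prediction falls back to the raw-score ordering on exact ties. Since
  calibration is order-preserving up to ties, this is the unique
  rank-consistent completion of the argmax rule.

Degenerate calibration sets with a single observed class fall back to
identity calibration (raw scores passed through) with a logged warning,
rather than producing a constant classifier.

## Synthetic cohorts

The generator reproduces the DEAP recording geometry — 40 trials × 32
channels × 8064 samples at 128 Hz (63-s trials: 3-s baseline + 60 s) — and
the label structure the pipeline needs, nothing more. Each trial is pink
(1/f) background noise plus four band-limited noise components made with the
same Butterworth bank the preprocessor uses, so the featurizer sees genuine
band-power differences. The latent valence class scales the β/γ components
in the eight frontal channels by 1 + effect_size·(2v − 1); the effect ramps
on linearly over 0.25 s starting at the subject's response latency (a ramp,
not a circular shift, to avoid edge artifacts). Latent classes are balanced
per subject (half positive, seeded shuffle), mirroring stimulus-set design.
Self-ratings are drawn around the binarization threshold,
clamp(round(5 + (2v−1)(2 + effect_size) + bias + N(0, 0.5)), 1, 9), so
binarization recovers the latent class with high but imperfect fidelity.

Per-subject individual differences: amplitude gain ~ lognormal(0, 0.1),
response latency ~ U[0, 1] s, rating intensity bias ~ U[−1, 1], and a
monotone score distortion p ↦ p^a with a log-uniform in
[1/(1+s), 1+s] for distortion strength s. The distortion acts on the
subject's *reported* class confidence: the positive unit becomes d(p₁) and
the negative unit the dual 1 − d(1 − p₀). Applying one monotone map to both
units identically would leave the argmax decision invariant — the individual
difference would be unobservable by construction — whereas the dual form
biases borderline decisions toward one pole, which is precisely the
phenomenon the IDM corrects.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction, nonstationary background rhythms, inter-channel correlation
structure beyond shared band definitions, or arousal-linked band power (only
valence modulates the signal; arousal labels exist but are carried by
ratings alone). Passing tests therefore demonstrate correctness of the
pipeline's mechanics and the calibration behavior under monotone response
distortions — not performance on real EEG.

## Numerical choices

- Filters: 4th-order Butterworth band-pass in second-order sections, applied
  forward–backward (zero phase). Trials are filtered whole and then
  segmented, avoiding transients inside 64-sample windows.
- DE variance floor 1e−12 guards the log on constant segments (clamped value
  is logged).
- Empty grid cells hold 0, not NaN, so convolutions are defined; 0 here
  means "no electrode", not a measured entropy.
- The network is float64 numpy with manual backpropagation, verified against
  central finite differences in the test suite; Adam uses the standard
  bias-corrected update with framework-typical defaults (β₁ 0.9, β₂ 0.999).
- All randomness (cohort draws, weight init, dropout, shuffling, splits,
  fold assignment) flows from explicit integer seeds; reports serialize as
  canonical JSON and reproduce byte-for-byte under identical seeds.
- LSTM forget-gate bias initializes at 1 (standard practice to keep early
  memory open); other parameters use uniform fan-in initialization.

## Experiment scales

The shipped experiments (tests and `scripts/acceptance.py`) run on a
scaled-down study: 12 trials of 13 s per subject (20 half-second windows per
trial), network widths 8/16/16/8 with LSTM hidden 32 and 5-window sequences,
20 training epochs. Eight subjects at effect size 2 form the training cohort
(ten-fold cross-validation plus one full training run); ten seeded
two-subject cohorts at the default effect size 1 with distortion strength 1
form the cross-subject IDM experiment. The weaker cross-subject effect is
deliberate: unseen subjects with weaker, delayed, and distorted responses
are the regime the IDM exists for, and the paired per-subject
with/without-IDM report mirrors the structure of a cross-subject evaluation
table. Defaults in the library itself (40 trials, 63 s, widths
64/128/256/64, hidden 128, 10-window sequences, 100 epochs) correspond to
the full-scale study and remain available through configuration.

## Known limitations

- Training the default-width network on full-size cohorts is CPU-intensive;
  the numpy implementation favors transparency and testability over speed.
- The split policy 0.6/0.2/0.2 with floor arithmetic leaves one of 32
  subjects unassigned (19/6/6); the leftover policy is configurable
  (`leftover="train"` assigns it to training).
- Isotonic calibration needs both classes in the calibration half and at
  least 10 sequences per subject; below that it degrades to identity.
- The real-data loader is out of scope: users with DEAP access can construct
  `RawRecording` objects directly (trials × channels × samples plus channel
  names) and reuse everything downstream.
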