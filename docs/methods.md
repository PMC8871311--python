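# Methods

This note documents the models, the numerical choices, and the design
decisions behind `eegfusion`, and states what the synthetic-data checks do
and do not demonstrate about real EEG.

## Pipeline overview

A labelled EEG segment (one or more channels, a sampling rate, a class
label ictal/non-ictal) is mapped to a feature row in three stages:
band-pass preprocessing, signal decomposition (wavelet and/or empirical
mode), and per-sequence statistics. Rows are assembled into one of three
case matrices — DWT-only, EMD-only, or their column-wise fusion — and
scored with four fixed-hyperparameter classifiers.

## Preprocessing

A Butterworth band-pass, order 2 per edge, 0.5–70 Hz. The filter is
realised in second-order-sections form: a low-order band-pass whose edges
sit at extreme ratios of the sampling rate (0.5 Hz against a 256 Hz rate)
is ill-conditioned as a transfer-function polynomial but stable as
cascaded biquads. Application is forward-backward (`sosfiltfilt`) by
default, which nulls phase distortion and preserves length, at the cost of
doubling the effective attenuation; a single-pass mode is available via
`FilterSpec(zero_phase=False)`. Note 70 Hz is admissible even at the
single-channel dialect's 173.6 Hz rate (Nyquist 86.8 Hz). Inputs are
processed as-is — no padding beyond what the forward-backward scheme
itself implies. There is no notch filter and no artifact removal.

## Discrete wavelet transform

Five-level multiresolution analysis with the orthonormal Haar wavelet
(taps ±1/√2), via PyWavelets with symmetric boundary extension. The
orthonormal convention was chosen over the un-normalised (1, ±1) filter
bank because it makes two properties exactly testable: energy
conservation (Σx² equals the summed squared coefficients) and perfect
reconstruction (inverse transform returns the input to ~1e−13). Both are
asserted in the tests, together with equivalence against a dense
orthonormal analysis matrix built independently for n ≤ 64. Coefficient
sequences are ordered cA5, cD5, cD4, cD3, cD2, cD1, and for an input of
length n the level-k sequence has length ⌈n/2ᵏ⌉ (all canonical segment
lengths are powers of two, so the ceiling only matters for foreign
inputs). The minimum segment length for level 5 is 32 samples.

## Empirical mode decomposition

EMD is implemented from first principles (sifting), since no EMD library
is part of the dependency set:

* **Extrema** — strict three-point local maxima/minima; a plateau of
  equal samples yields a single extremum at the plateau midpoint, rounded
  down (a determinism rule for tie cases).
* **Envelopes** — natural cubic splines through the maxima (upper) and
  minima (lower), after mirroring the two extrema nearest each end across
  the endpoints. Mirroring is the least-surprise boundary rule and keeps
  end swings from contaminating the envelope mean; the envelope mean of a
  densely sampled unit sine stays below 0.05 in absolute value over the
  interior 80% of samples.
* **Sifting** — h ← h − (upper+lower)/2 until the Cauchy-style criterion
  SD = Σ(h_prev − h)²/Σh_prev² < 0.2 fires, capped at 100 iterations per
  IMF. SD < 0.2 is the convention of the classical EMD literature; the
  criterion is scale-free, so the decomposition is equivariant under
  amplitude scaling (tested to 1e−6 relative).
* **Termination** — IMFs are subtracted from the running residue until
  either 5 IMFs (the default) are extracted or the residue is
  monotone/trend (fewer than two maxima or two minima). A strictly
  monotone input therefore yields zero IMFs. Completeness
  (input = ΣIMFs + residue) holds to machine precision because the
  residue is maintained by exact subtraction.

Mode mixing is a known limitation of plain EMD and is deliberately not
remedied here (no ensemble or multivariate variants). On a 25 Hz + 3 Hz
two-tone signal the first IMF recovers the fast tone with r > 0.95 and the
second the slow tone with r > 0.9 over the interior 80% of samples.

## Statistical features

Eight statistics, all population (1/n) forms, exactly as defined in the
README. Three conventions deserve comment:

* **Curve length** uses the natural logarithm. A constant sequence has
  zero total variation, whose log is −∞; it is floored at ln(machine ε)
  ≈ −36.04 and flagged in the log, so degenerate synthetic inputs still
  produce finite matrices.
* **Kurtosis is raw**, not excess: a normal sample scores ≈ 3.
  Zero standard deviation maps skewness and kurtosis to 0 by convention.
* **Minimum** is the global minimum sample value. An alternative reading —
  the smallest absolute amplitude among strict local minima — is
  available via `stat_minima(x, interpretation="local_min_abs")`; the
  ambiguity is inherent in the feature's usual one-line definition and
  the global reading is the simplest consistent one.

Every statistic is verified against an independent brute-force pure-Python
re-implementation to 1e−10 relative tolerance on random sequences.

## Feature-matrix assembly and fusion

Column identity is fixed by a naming grammar `<stat>_<source>[_ch<k>]`
with sources cA5…cD1 and imf1…imf5, nested channel-major, then source,
then statistic; the channel suffix appears only for multi-channel
segments. Widths follow: 4 channels × 6 sequences × 7 stats = 168 (DWT),
4 × 5 × 6 = 120 (EMD), 288 fused; single-channel 42 / 30 / 72. Fusion is
plain column concatenation with the DWT block first, after checking row
counts, row-wise label agreement, and name disjointness. Variable-length
ictal segments are featurised as-is — the 1/n terms inside the formulas
are the only length normalisation; no resampling. Segments whose EMD
terminates short of 5 IMFs contribute all-zero blocks for the missing
IMFs, flagged in the log.

Whether filtering precedes segmentation or vice versa is immaterial for
the zero-phase path away from window edges; the pipeline filters each
segment independently, and `bandpass` on whole records is available when
edge effects matter.

## Classifiers and evaluation

Hyperparameters are fixed, not searched: linear SVM at C = 1, RBF SVM at
C = 100 with gamma = 'scale', decision tree (gini by default) at
max_depth = 4, bagging of 300 such trees on 50% bootstrap subsets.
Feature columns mix scales wildly (log-domain curve lengths vs. raw
variances), which is pathological for kernel machines, so SVM kinds get a
z-score standardisation fitted on training rows only; trees are
scale-invariant and run on raw features. The evaluation protocol is a
stratified 80/20 shuffle split with a fixed seed. Metrics (accuracy, F1
with ictal as the positive class, MCC) are computed from the package's
own confusion-count closed forms — with MCC defined as 0 whenever a
marginal is zero — and are cross-checked against scikit-learn's
implementations in the tests.

## Synthetic data: what it emulates and what it does not

The generator produces background EEG as unit-RMS 1/f-shaped ("pink")
noise scaled to 20 µV plus an 8–12 Hz alpha sinusoid (10 µV) with
per-channel random frequency and phase. Ictal activity adds a 3 Hz
spike-and-wave train — fundamental plus two harmonics at halving
amplitudes — whose RMS is `ictal_gain` times the nominal background RMS
(√(pink² + alpha²/2)); gain 3 is the default "clearly separable" setting.
The spike-wave phases come from an RNG stream separate from the
background's, so at gain 0 an "ictal" record is bitwise identical to a
background record: class separability is a genuine dial, from
distributional identity (classifiers score at chance) to easy separation.
Sampling structure mirrors the two dialects: 4096-sample ASCII files at
173.6 Hz (integer samples, split 8 × 512) and 4-channel EDF records at
256 Hz with annotated ictal intervals.

Passing the end-to-end checks on this generator demonstrates that the
pipeline's plumbing, feature definitions and classifiers behave correctly
and that accuracy tracks true class separation. It does **not**
demonstrate clinical performance: real ictal EEG has nonstationary
morphology, artifacts (eye blink, EMG), inter-subject variability and
class imbalance, none of which are modelled.

One subtlety: segments cut from the same source file share that file's
alpha parameters and noise realisation, so a row-level train/test split
can identify source files above chance even when the class labels carry
no signal. Chance-level (gain 0) behaviour is therefore assessed on
corpora with one independently drawn 512-sample segment per file
(`generate_labeled_segments`), where rows are i.i.d. and the binomial
50% reference is exact.

## Problem sizes and runtime

End-to-end evaluations use single-channel corpora of 96 segments per
class (512 samples each) across 10 seeds, both in the test suite and in
`scripts/acceptance.py`; with this implementation's sifting speed that
keeps a full run to about a minute on one CPU while leaving held-out test
sets of ~39 rows per seed. Dimensional bookkeeping for the multi-channel
dialect is exercised on a 120 s, 4-channel record with a 50 s ictal
interval.

## Known limitations

* Plain EMD mode mixing is not addressed.
* The EDF writer is minimal (16-bit, one-second records, uniform rate,
  microvolt physical dimension) and exists to produce synthetic fixtures;
  reading arbitrary real-world EDF goes through mne and assumes EEG
  channels are expressed in volts there.
* Ictal timestamps for multi-channel data are supplied as configuration
  (a JSON sidecar), not parsed from EDF+ annotations.
* No hyperparameter search, feature selection, or dimensionality
  reduction; the fixed settings above are the object of study, not a
  tuned optimum.
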