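# Methods

## Fuzzy entropy

The statistic is computed per epoch per channel. Windows of length `m`
are taken at starting points `i = 1..N-m` and each is centred by its own
window mean (local-mean removal). The same `N-m` vector count is used at
dimension `m+1` — at that dimension the `N-m` windows are exactly all that
fit in the series — so the two averages `phi_m` and `phi_{m+1}` run over
the same index set and their log-ratio is well defined. (The alternative
convention of `N-m+1` vectors at dimension `m` exists in the literature;
the package deliberately uses the matched-count form.)

Two similarity kernels are implemented:

* `as_printed` (default): `exp(-d^n / r)`. Under this form the statistic is
  **not** invariant to amplitude rescaling: substituting `a*x` scales
  `d^n / r` by `a^(n-1)` because `r` scales linearly with the SD while `d^n`
  scales as `a^n`.
* `normalized`: `exp(-(d/r)^n)`. Here `d/r` is dimensionless, so the
  statistic is exactly invariant to positive rescaling; this is the form
  common in the FuzzyEn literature.

Both forms are shift invariant: the local mean removal cancels any additive
offset and the SD is unchanged. In floating point the cancellation is not
bitwise — adding an offset `c` to samples of order 1 perturbs them by about
`|c| * 2^-52` before the algorithm ever sees them — so tests assert
invariance to `1e-12` for offsets up to the hundreds-of-microvolts scale of
realistic baselines, not for arbitrarily large `c`.

Parameters and defaults: `m = 2` (embedding dimension), `n = 4` (membership
gradient), `r = 0.2 * SD` with the *population* SD of the epoch at hand,
recomputed per epoch per channel. A constant epoch has `SD = 0`; rather
than divide by a zero tolerance the function warns and returns entropy 0
(a constant signal carries no complexity). Constant and affine-ramp inputs
give exactly 0 because every centred window is identical at both
dimensions, making `phi_m = phi_{m+1} = 1`.

### Numerical path

The fast path embeds with a stride index, computes condensed Chebyshev
distances with `scipy.spatial.distance.pdist`, and exploits the symmetry of
the similarity matrix: with `M` vectors and unit diagonal,
`phi = 2 * sum(S_condensed) / (M * (M-1))`. A literal triple-loop
transcription of the definition (`fuzzy_entropy_oracle`) is kept in the
public API for verification; the test suite checks agreement below `1e-10`
across 100+ random series (observed agreement is at machine precision,
~1e-15). Integral gradients are evaluated as integer powers, which is both
faster and bit-stable.

Strict nonnegativity of FuzzyEn is not guaranteed under local-mean removal;
the suite carries an empirical guard (entropy ≥ −1e−9 over 300 seeded white
noise series of length 500) rather than asserting a theorem the construction
does not provide.

## Preprocessing

The software chain mirrors a frontal two-electrode acquisition: 0.05–200 Hz
band-pass and 50 Hz mains notch at fs = 1000 Hz. Choices the cutoffs alone
do not fix:

* **Band-pass**: 4th-order Butterworth, second-order sections, applied
  forward–backward (`sosfiltfilt`) for zero phase; reflect padding at the
  edges avoids startup transients in the first epoch. SOS form keeps the
  extremely low 0.05 Hz corner (normalized frequency 1e-4) numerically
  stable.
* **DC**: the channel mean is subtracted before filtering. For records much
  shorter than the 20 s period of the high-pass corner, the filter alone
  leaves a visible DC residue; explicit demeaning makes the DC contract
  (output mean ≈ 0) hold at any record length.
* **Notch**: `iirnotch` with quality factor 30 (≈1.7 Hz −3 dB width),
  zero-phase. Measured attenuation of a 10 s unit 50 Hz tone is ≈39 dB;
  a 10 Hz tone passes within 1 dB.
* **Epoching**: 1.0 s non-overlapping epochs by default (1000 samples at
  1000 Hz), trailing partial window dropped. One second keeps the O(N²)
  entropy kernel cheap while giving stable estimates; both length and
  overlap are configurable.
* **Artifact rejection**: an epoch is dropped iff any sample exceeds
  ±100 µV (configurable). Deterministic peak rejection is the simplest
  defensible rule for frontal channels; no ICA/regression correction is
  attempted. Sample values are never modified.

No resampling is performed; data stay at the native rate.

## Features

One fuzzy-entropy value per channel per epoch, joined side by side into a
row per (subject, session, epoch time) with the 0/1 state label. If any
channel of an epoch time was rejected, the whole row is dropped (no
imputation); the drop count is logged. The table round-trips to CSV and is
the classifier's input format.

## Classification

RBF-kernel SVM with per-training-fold feature standardisation inside a
single sklearn Pipeline, so scaler statistics never see the test fold.
Hyperparameters are deliberately fixed rather than searched: `C = 1` and
kernel width `gamma = 1 / (n_features * Var(X_train))` (sklearn's "scale"
rule), both overridable. Folds are stratified by class and seeded; the
default protocol cross-validates **within each subject** (10 folds) and
reports per-subject means plus the cohort mean and SD across subjects. A
pooled, subject-blind mode is available by flag. The summary dispersion is
labelled `sd`: for a table of per-subject accuracies near 0.95 a dispersion
of ~0.02 is on the scale of a standard deviation, not a variance, and the
package reports it as such.

The 0–1 **fatigue score** is a sigmoid applied to the SVM margin, with the
slope fitted to the training data (no intercept), so the score is a
monotone transform of the decision function anchored at 0.5 on the
boundary. It is a display calibration, not a validated posterior
probability.

## Synthetic cohort

Each channel is `A * sin(2*pi*10Hz*t + phase) + sigma * white noise`, with
optional 50 Hz mains contamination; `A/sigma` is the state's SNR and total
RMS is held at 15 µV for every state, so classes differ in *structure*, not
energy, and peaks stay inside a plausible ±50 µV frontal range (rarely
touching the 100 µV rejection threshold). FuzzyEn of such a mixture grows
monotonically with the noise fraction, so the SNR pair is an analytically
motivated control knob for the entropy separation between states.

Defaults define the benchmark conditions: 12 subjects, 2 channels (FP1,
FP2), 1000 Hz, 30 s per state, SNR 4.0 (normal) vs 1.0 (fatigue), subject
jitter 0.1 (lognormal factor applied to both states of a subject, so
individuals differ in overall signal quality but preserve the state
ordering). The SNR pair was fixed by a pilot `calibrate_separation` run:
it yields a standardized entropy difference of roughly 25 between states,
far above the ≥1.5 design target, and the benchmark cohort classifies at
essentially 100%. The fatigue state is generated as the *higher*-entropy
state; the generator makes no claim about which direction real drowsiness
shifts EEG complexity.

What the generator does **not** emulate: 1/f background spectra,
non-stationarity within sessions, ocular/EMG artifacts (beyond what the
amplitude threshold would catch), micro-sleep events, or inter-channel
correlation. Passing the benchmark therefore demonstrates that the pipeline
correctly recovers an entropy difference that exists by construction — it
says nothing about detection power on real drowsy-driving EEG.

## Problem sizes in tests and the acceptance script

End-to-end checks use reduced cohorts chosen as sensible desk-scale
experiments: the null calibration runs 30 seeded cohorts of 3 subjects ×
12 s per state at equal SNRs (its chance-level band is ±3 binomial SDs of
the pooled tested-trial count); the determinism check runs 2-subject
cohorts twice; the separable benchmark runs the full 12-subject default
cohort once. The acceptance script repeats the benchmark, a 10-seed null,
a 100-epoch-per-state separation report, the notch measurement, and a
100-series oracle comparison, all derived from one `--seed`.

## Known limitations

* The as-printed similarity form couples the statistic to signal amplitude
  (see above); comparisons across recordings with very different gains
  should use the normalized form.
* Per-subject 10-fold CV with ~30 epochs per class yields 3-sample test
  folds; fold accuracies are correspondingly coarse.
* EDF export is not implemented (CSV is the generator's output format);
  EDF *input* is supported through the optional mne dependency.
* The artifact rule is amplitude-only and will not catch low-amplitude
  physiological contamination.
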