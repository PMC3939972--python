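# Methods

## Pipeline overview

Each subject contributes one multichannel resting EEG recording (default
120 s at 200 Hz). Five channels enter the analysis — Cz, C3, C4, T3, T4 —
and each channel is cut into 2-s windows with 50 % overlap (half-open
sample intervals starting at sample 0; a trailing partial window is
discarded so all windows have N = 400 samples; 119 windows per channel at
the defaults). For one feature type, the per-channel window features at a
given window index are concatenated into a single feature vector, giving
one design-matrix row per (subject, window index). Classification is a
soft-margin RBF-SVM under leave-one-participant-out cross-validation: one
fold per subject, all of that subject's windows held out together, and
standardisation and the kernel width computed on the training folds only.

## Approximate entropy

ApEn(m, r, N) = Φ^m − Φ^{m+1}, where Φ^q is the mean natural log of the
template match frequencies at embedding dimension q, matches counted under
the Chebyshev norm with d ≤ r, and the frequency denominator is the
template count N − q + 1. Defaults: m = 2, r = 0.1 × the window's own
standard deviation (population formula; at N = 400 the n vs n−1 choice is
negligible), minimum window length 50 samples. Tying r to the window SD
makes the statistic exactly scale- and translation-invariant; an absolute
tolerance can be supplied instead (required for constant windows, and
useful when a whole-recording SD is preferred).

**Self-match convention.** The classical definition counts each template as
matching itself, which keeps every match frequency positive. The
alternative that skips the j = i pair looks more principled but is
undefined whenever any template has no other neighbour within r — and at
m = 2, r = 0.1·SD, N = 400 that happens for essentially every realistic
signal we tested (white noise, band-limited pink noise, drifting
narrowband oscillations, and their mixtures all contain rare-amplitude
templates with no neighbour). Since finite window-level ApEn tables at
exactly these parameters are routinely reported for clinical EEG, the only
computable reading is the classical one, so `self_match="include"` is the
default. `"exclude"` is available as a flag and raises a `NoMatchError`
naming the offending template rather than silently flooring the count:
a zero match count at these parameters signals a misconfigured tolerance,
and flooring would hide it.

## Higuchi fractal dimension

For delay k = 1..k_max and offset m = 1..k, the decimated series
x(m), x(m+k), … has normalised curve length
L_m(k) = [Σ_i |x(m+ik) − x(m+(i−1)k)|] · (N−1)/(⌊(N−m)/k⌋·k) / k, and L(k)
is the mean of L_m(k) over the k offsets. D is the least-squares slope of
ln L(k) on ln(1/k): 1 for a smooth line, → 2 for white noise. Summing
rather than averaging over the offsets (a form that appears in parts of
the applied literature) multiplies L(k) by k and shifts the slope by −1,
which fails the ramp sanity check D = 1; the averaged form is used here
and the test-suite oracle transcribes the same equations naively.
Default k_max = 8 for N = 400, keeping ≥ 49 points in every decimated
series; the regression uses equal weights per k.

## Burg autoregressive coefficients

The AR(P) model is written x(t) = −Σ a_i x(t−i) + e(t). Burg's estimator
picks each stage's reflection coefficient to minimise the summed forward
and backward prediction error and updates the coefficient vector through
the Levinson–Durbin recursion, guaranteeing |k_p| < 1 (a stable model).
The recursion is implemented directly (about twenty lines) and is verified
against the statsmodels Burg routine to 1e-10 in the tests. Model order
P = 10 by default — a common choice for short EEG segments; the order is
recorded in every output. Coefficients are scale-invariant, so amplitude
calibration does not matter.

## Band power

Butterworth filters of order 5: delta (0–4 Hz) as a low-pass at 4 Hz (a
0 Hz band-pass corner is not realisable), theta 4–8, alpha 8–13 and beta
13–30 Hz as band-passes, designed once per (fs, band) as second-order
sections and checked for pole stability. Filtering is zero-phase
(forward–backward), which avoids phase distortion inside the short window
at the cost of doubling the effective roll-off. Band power is the *mean*
of the squared filtered samples, making it window-length invariant; it
scales as amplitude².

## Classifier and evaluation protocol

The SVM dual (maximise Σa_i − ½ΣΣ y_i y_j a_i a_j k(x_i,x_j) subject to
0 ≤ a_i ≤ C, Σ a_i y_i = 0) is solved by scikit-learn's SMO to KKT
tolerance 1e-3; the decision function f(x) = Σ a_i y_i k(x_i, x) − b is
cross-checked in the tests against a brute-force kernel sum over the
stored dual coefficients. Patient is fixed as +1, so sensitivity is the
patient detection rate. A decision value of exactly 0 predicts control.

Kernel width: σ defaults to the median pairwise Euclidean distance between
the standardised training points of the fold (deterministic and
scale-free); C defaults to 1. Neither is tuned per fold — no nested search —
keeping folds cheap and reproducible. Features are standardised with the
training fold's mean/SD only; the held-out subject never influences
training, standardisation or σ.

Fold accuracy is the fraction of the held-out subject's windows classified
correctly (window-level scoring; a subject-level majority vote is reported
as a secondary column). Summary statistics are mean ± sample SD (n−1) over
folds. Pooled window-level confusion counts give sensitivity, specificity
and accuracy; which windows enter these printed ratios (pooled vs per-fold
averaged) is a convention, and pooled is implemented and labelled as such.
Feature types are compared on their matched 20-fold accuracy vectors with
a variance-ratio F statistic (oriented as var(other)/var(ApEn)) and a
two-sided paired t test; no multiple-testing correction is applied across
the three comparisons, and a zero-variance difference vector is flagged
`degenerate` with p reported as 0.

## Synthetic cohorts

Each channel is x(t) = (1−ρ_s)·n(t) + ρ_s·o(t), z-scored, where n(t) is
unit-variance pink (1/f) noise band-limited to 1–40 Hz (mimicking an
acquisition chain's high-pass and anti-aliasing; unbounded 1/f drift
destroys template recurrence and with it any stable ApEn estimate —
white noise is available via `noise_color`), and o(t) is a unit-variance
8–12 Hz oscillation with slowly drifting instantaneous frequency and 0.2 Hz
amplitude waxing. All channels of a subject share ρ_s but have independent
realisations, so channel-level tables differ only by estimation noise.

ρ_s ~ Normal(μ_group, subject_sd), clipped to [0.02, 0.98], with
subject_sd = 0.05 by default. Group means come from inverting a frozen
ρ → E[windowed ApEn] lookup table (computed once by
`scripts/calibrate_regularity.py` over the monotone region ρ ∈ [0.40,
0.98]; below ρ ≈ 0.4 the oscillation is buried and ApEn saturates near
0.82): controls target mean ApEn 0.60 and patients 0.60 − gap, with
gap = 0.10 by default. The defaults emulate a 10 + 10 subject study,
120 s per recording at 200 Hz. Realised behaviour at the defaults (seed 1):
group ApEn gap 0.099, window-level ApEn in [0.25, 0.79], per-subject
window SDs a few hundredths — the scale reported for clinical cohorts.

**What the generator does not emulate.** Artifacts (blinks, muscle),
inter-channel correlation and montage geometry, non-stationarity beyond
slow oscillation drift, medication effects, and any spectral signature of
disease beyond the single regularity dial. In particular, because ρ moves
alpha-band share and regularity *together*, band power is nearly as
discriminative as ApEn on these cohorts by construction — passing tests
show the pipeline recovers a planted regularity difference, not that ApEn
dominates other features on real clinical EEG.

## Numerical and design choices

- Window segmentation is 0-based with half-open intervals; trailing
  samples are dropped so N is constant across windows (required for
  comparable ApEn values). The first window starts at sample 0.
- Channel names match case-insensitively; the T3≡T7 / T4≡T8 alias map is
  off by default and opt-in.
- Cohorts are written as delimited text (header row of channel names, one
  column per channel, 10 significant digits) plus a `manifest.csv`
  (subject_id, group, filename); EDF recordings are read via mne with
  values kept in the file's physical units.
- The pipeline caches feature CSVs by a content hash of everything
  upstream (generator spec or data directory, windowing, feature
  parameters); re-running with one changed parameter recomputes only the
  affected stages. Reports carry no timestamps, so runs with the same seed
  are byte-identical.
- Determinism: the cohort generator consumes a single seeded NumPy
  Generator in a fixed subject/channel order; the SMO solver is
  deterministic for a fixed training set.

## Test problem sizes

Full-scale checks (10 + 10 subjects, 120 s) are run once — the planted-gap
recovery and LOPO power check. Protocol-level checks that do not depend on
recording length (fold structure, permutation leak detector, chance-level
behaviour of null cohorts) use 20-s recordings, and plumbing tests use
2 + 2 subject cohorts; these sizes are stated here as the package's own
choices for a comfortably fast default test run.

## Known limitations

- The exclude-self ApEn variant is faithful but rarely usable at the
  default tolerance (see above); it exists for convention comparisons at
  larger r.
- AR model order cannot be validated against clinical data from here;
  P = 10 is a field convention, not a fitted choice.
- With 20 subjects a LOPO fold is a single subject, so fold accuracies are
  strongly bimodal and their SD is large; the mean over folds is the
  meaningful summary.
- The F/paired-t feature comparison treats fold accuracies as exchangeable
  paired observations; with n = 20 folds its power is limited and no
  correction for the three simultaneous comparisons is applied.
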