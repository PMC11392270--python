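# Methods

## Signals and preprocessing

The unit of analysis is a whole EHG record: three bipolar abdominal
channels (S1 = E2−E1, S2 = E2−E3, S3 = E4−E3) sampled at 20 Hz for about
30 minutes.  Analysis uses the vertically oriented S2 and the
cervix-adjacent horizontal S3.  Each signal is band-limited with a
4th-order Butterworth filter applied forward–backward (zero phase) and
15 s are trimmed from each end before any spectrum or entropy
computation, discarding the filter transients.  Both the trim and the
filter order are configurable (`ExtractionConfig`).

Ten bands are used (Hz): B0 0.08–1.0 (reference), B1 1.0–2.2,
B2 2.2–3.5, B3 3.5–5.0, Bb 0.3–4.0, B0b 0.08–4.0, B0L 0.08–0.3,
B0L′ 0.125–0.575, B0L″ 0.225–0.475, B0H′ 0.575–1.0.  In code the prime
is spelled `p` (`B0Lp`, `B0Lpp`, `B0Hp`).  Spectral bins are indexed
half-open, k_L = ⌈f_lo/df⌉ to k_U = ⌈f_hi/df⌉ exclusive, so a bin shared
by two adjacent band edges (e.g. 1.0 Hz between B0 and B1) is counted
once, in the upper band.

## Features

* **PF** — frequency of the largest in-band power-spectrum bin.
  Ties take the lowest-frequency bin.
* **MF** — smallest in-band frequency at which cumulative in-band power
  first reaches half the total in-band power.
* **PA** — largest in-band peak of the band-filtered signal's spectrum
  divided by the largest B0-band peak of the B0-filtered signal.  PA is
  dimensionless, scale-free, and identically 1 in bands B0 and B0b,
  which are therefore excluded from feature sets.
* **SE** — sample entropy with embedding dimension m = 3, Chebyshev
  distance and tolerance r = 0.15 × SD of the analyzed (band-filtered)
  series, population SD.  Matches are unordered template pairs i ≠ j,
  with length-m templates indexed over [1, N−m+1] and length-(m+1)
  templates over [1, N−m]; the ratio c_{m+1}/c_m is insensitive to the
  ordered/unordered convention applied consistently, and the O(N²) test
  oracle mirrors the same convention.  When either count is zero the
  published fallback −ln((N−m)/(N−m−1)) is returned verbatim; note this
  expression is negative as printed.  A flag
  (`SEParams.sign_corrected_fallback`) yields the positive variant; the
  default does not silently correct the published form.  A constant
  series returns 0 (every pair matches at every length).

The spectrum estimator is the single full-length boxcar periodogram, so
the equations' single-spectrum indexing holds exactly; Welch averaging
(Hann window, 50 % overlap, configurable segment length) is available as
configuration and is used by the scaled experiments (below) because it
substantially stabilizes peak-height estimates on short records.
Optional decimation before the entropy computation (factor
⌊fs/(2.5·f_hi)⌋ per band) bounds the O(N²) pair count on long records;
it is off by default.

## Feature sets and selection

Feature sets: set 1 = {PF, MF, PA, SE} × {S2, S3} × 10 bands minus PA in
B0/B0b (76); set 2 = set 1 minus bands B0H′ and Bb (60); set 3 = bands
{B0L, B0L′, B3, B0b} only (30); set 4 = set 3 minus B0b (24).

Features are pre-sorted by two-sample Wilcoxon rank-sum p-values
(premature vs term) computed on the feature table, with an option to
supply an external ordering; the ordering only fixes tie-breaks and
histogram indexing.  One stabilized selection run repeats, for i = 1…N
(default N = 200):

1. a stratified 80/20 holdout split (per-class proportions to rounding);
2. a full greedy forward ranking of all K features on the training
   partition, scoring each candidate subset by stratified 5-fold
   cross-validated MCE in which the four training folds are
   SMOTE-balanced and the held-out fold is predicted untouched.  Within
   a step all candidates share the same derived seed, so they face the
   same SMOTE draws (paired comparison); argmin ties go to the earlier
   (lower-p) feature.  The step's accumulated MCE reuses the value from
   the argmin search rather than re-drawing;
3. the prefix minimizing that repetition's MCE curve (first minimum)
   increments the occurrence histogram.

The final subset size is the first minimizer of the average MCE curve
and the subset is that many highest histogram peaks.  Running the
procedure per classifier × feature set and counting first/second
histogram peaks across runs yields the top-two candidate biomarkers
(A, B); ties in the tally break lexicographically.

For speed, the inner CV loop uses closed-form LDA (pooled-covariance
pseudo-inverse) and Gaussian naive Bayes implementations whose
predictions are asserted, in the test suite, to match the scikit-learn
estimators used everywhere else; SVMs and QDA always go through
scikit-learn.

## Resampling and leak audit

SMOTE synthesizes minority rows by interpolating between a minority
sample (cycled) and one of its k = 5 nearest minority neighbours
(Euclidean distance in the active feature subspace), with uniform
interpolation weight, up to exact parity with the majority count.  The
neighbour count and metric are package defaults, not values asserted
from elsewhere.  Every synthetic row records its two parent ids; a
`LeakAudit` verifies for each row that both parents belong to the active
training partition (and training folds) and never to a held-out set.
All partition operations canonicalize row order by record id before
seeded shuffling, so results are independent of file enumeration order,
and all seeds derive from one base seed through `SeedSequence` key
paths.

## Evaluation

The evaluation phase consumes the same persisted partitions as the
selection phase.  Per repetition the full training partition is
SMOTE-balanced, the classifier fitted, and Se, Sp, PPV, NPV, CA
(exact count arithmetic; zero-denominator values reported as NaN and
excluded from means with a logged count) plus trapezoidal AUC are
computed on the untouched test partition and, for the generalization
check, on the raw training partition.  Means use sample SDs (n−1).
ROC curves are averaged vertically (mean ± SD of sensitivity on a
uniform false-positive-rate grid).  Classifiers with calibrated
posteriors expose them as the premature likelihood; margin classifiers
(SVMs) are squashed through a logistic so the 0.5 level coincides with
their decision boundary.  Single-feature decision thresholds are located
by bisection on (likelihood − 0.5) and averaged across repetitions and
classifiers; two-feature boundaries are the 0.5-level isoline of the
mean likelihood over a 200×200 grid padded 10 % beyond the observed
feature range.

## Synthetic generator

Each record sums, per channel, (i) 1/f^1.2 background noise (unit SD,
independent per channel); (ii) a very-low-frequency line at 0.095 Hz
(drift/breathing residue) that supplies the B0 reference peak; (iii) a
narrowband FWL line at a subject-specific center (uniform in
0.35 ± 0.05 Hz, class-independent, so the peak location carries no
class signal) whose spectral peak is multiplied by
`fwl_peak_gain` (default 3) in premature records by narrowing the line
width at unchanged power, so band power and signal regularity stay
class-independent and only the peak-amplitude feature carries the
effect; (iv) three
maternal-heart harmonics (fundamental 1.35 Hz ≈ 81 bpm, per-record SD
0.035 Hz, lowered by `mhr_shift` = 0.17 Hz in premature records) whose
third harmonic forms a broad hump inside B3 (harmonic line widths are tied to the class-independent base rate, so hump heights carry no class signal); and (v) a mid-band
(1.3–3.2 Hz) burst of heavily dispersed, class-independent amplitude
standing in for Fast-Wave-High/motion variability.  Narrow components
use mean-reverting (Ornstein–Uhlenbeck) frequency jitter so line widths
do not grow with record duration; amplitudes share one per-record
lognormal scale (electrode coupling) that ratio features cancel, plus
small independent jitters.  Channel projections make the FWL component
strongest on S3 and the heart component strongest on S2, mirroring the
electrode geometry.

The generator's class contrasts live exactly on the two headline
features — PA S3 B0L′ elevated, MF S2 B3 lowered — so planted-pair
recovery is a sharp test; other features react only through spectral
overlap.  Component amplitudes were chosen so the feature distributions
resemble the published ones (term PA centred near 0.4, premature near
0.7, overlapping classes).  The generator does not model
contraction-burst morphology, electrode artifacts, non-stationarity
beyond the frequency jitter, or between-channel correlation of the
background noise; passing tests therefore demonstrate correctness of
the pipeline's mechanics and its ability to recover planted spectral
effects, not clinical performance on real EHG.

## Scaled experiments

The experiments module runs the pipeline at desk scale: 200 records
(40 premature / 160 term across TL/IL/CL/ICL), 300 s per record, N = 10
holdout repetitions per stabilized run, two classifiers (LDA, Gaussian
naive Bayes) × two feature sets (set 3, set 4), Welch estimator with
512-sample segments, and entropy decimation on.  These sizes keep one
replicate around a minute while remaining large enough for the planted
pair to dominate the tally; the null configuration (gain 1, shift 0)
makes the two classes identically distributed, so the pipeline's mean
test AUC near 0.5 verifies the absence of false discovery.  The
headline numbers of the original cohorts (e.g. CA ≈ 76–78 %,
AUC 0.81–0.86, PA threshold ≈ 0.66) require the PhysioNet datasets and
are not reproduced by the synthetic experiments.

## Known limitations

* The WFDB reader supports the subset of the header grammar the EHG
  datasets use (single segment, one format-16 signal file).
* The p-value pre-sort is computed on the full dataset's feature table
  when no external ordering is supplied; since it only fixes tie-breaks
  and histogram indexing, it does not leak into the held-out metrics.
* QDA's pseudo-inverse behaviour is emulated with a tiny covariance
  regularizer (1e-9) rather than a literal Moore–Penrose solve.
* The average-MCE curve minimizer takes the first (global) minimum;
  with few repetitions the optimal subset size is noisy, which is the
  instability the occurrence histogram exists to absorb.
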