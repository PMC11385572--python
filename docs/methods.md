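# Methods

`alphasel` implements a complete cueing-phase EEG analysis chain for
studying attentional selection during goal-directed memory retrieval,
together with a synthetic-data generator that emulates the underlying
three-phase task.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show.

## The task being emulated

Participants first encode associations between objects and two screen
locations (one lateral: left/right, one vertical: top/bottom).  In the
cueing phase each object reappears and, 500 ms later, a cue marks either
one location as relevant (selective cue, along the horizontal or vertical
axis) or both (neutral cue).  With 120 objects, three repetitions per
object and three cue types, the cueing phase comprises 360 trials per
participant, 120 per cue type.  In the final retrieval phase the
task-relevant location is reported (two-alternative forced choice) and the
response confidence rated on a 1–4 scale.  All EEG analyses operate on
epochs of −1000..3000 ms around object onset; the cue appears at +500 ms.

## Synthetic EEG model

Each trial's 64-channel signal (extended 10/20 montage; 27 homologous
left/right pairs and 10 midline sites) is a sum of:

* **Pink background noise** — Gaussian 1/f^β noise per channel
  (β = `noise_exponent`, default 1) with RMS `noise_std_uv` (default 5 µV),
  generated by spectral shaping and scaled analytically to the target RMS.
* **Ongoing posterior alpha** — a sinusoid at `alpha_freq` (default 10 Hz)
  with random per-trial phase, amplitude `alpha_amplitude_uv` (default
  12 µV) at parieto-occipital channels and a 20% fraction elsewhere.
* **Contralateral alpha suppression** — in selective trials with a lateral
  target, the ongoing-alpha amplitude at posterior channels contralateral
  to the target is scaled by `10**(alpha_suppression_db/20)` inside
  `suppression_window` (default 200–900 ms post-cue, 100 ms raised-cosine
  ramps).  Because the ongoing alpha dominates alpha-band power at
  posterior sites (oscillation ~72 µV² vs. ~2 µV² of in-band pink noise),
  the baselined contralateral-minus-ipsilateral power difference lands
  within a few percent of `alpha_suppression_db` (default −1 dB).
* **PCN** — a Gaussian-envelope negative deflection (`pcn_amplitude_uv`,
  default −2 µV; SD `pcn_width_ms`, default 60 ms) added at the member of
  PO7/PO8 contralateral to the lateral target, centred `pcn_latency_ms`
  (default 450 ms) after cue onset.
* **Location-specific alpha patterns** — one fixed topography per location
  (left/right/top/bottom), shared by all participants of a simulation,
  carried by an alpha-band sinusoid with its own random per-trial phase and
  active post-cue (`pattern_window`).  Selective trials receive the target
  location's pattern at `location_pattern_gain` (per-channel RMS amplitude,
  default 0.6 µV); neutral trials receive both encoded locations' patterns
  at half gain (a zero-signal alternative is selectable via
  `neutral_pattern="zero"`).

The four topographies are drawn as Gaussian vectors, orthogonalized in the
left-hemisphere + midline channel subspace, and then *magnitude-mirrored*
onto the homologous right-hemisphere channels (random sign, equal absolute
value).  The mirror is deliberate: squared pattern amplitude — what alpha
*power* features see — is then hemisphere-symmetric, so the location
pattern cannot leak a spurious contralateral/ipsilateral power asymmetry
into the lateralization analyses, while the four power topographies remain
distinct and linearly separable.  Because phases of noise alpha and pattern
alpha are independent, expected alpha power at a channel adds the two
contributions, and discriminability scales monotonically with the gain.

Default effect magnitudes are design choices, not estimates: the study this
machinery targets reports cluster time windows, not effect sizes in dB or
µV.  The defaults produce a moderate, human-plausible effect pattern —
selective-condition effects comfortably detectable in groups of ~8
participants, neutral-condition effects (quarter pattern power, no
lateralized injection) below cluster-detection threshold — mirroring the
qualitative dissociation the pipeline is built to detect.

Behavior is generated per object (one retrieval report each): accuracy is
Bernoulli (default 0.84 in both conditions); RT is log-normal with a
participant-level intercept (SD 0.30 log units), a small per-condition
participant slope (SD 0.03), a selective-vs-neutral shift of −0.09 log
units (≈ −135 ms at the group mean) and a +0.40 log-unit penalty on
incorrect trials; confidence is ordinal with category probabilities that
favour higher ratings on correct trials and in the selective condition,
exponentially tilted by a participant-level bias (SD 0.6) so participant
means spread by ~0.4 categories, as between-participant confidence SDs of
real groups do.
This reproduces the target pattern — RT and confidence advantages for
selective cues at equal accuracy, with paired effect sizes (d_av) around
0.1–0.3 — without claiming to reproduce any particular dataset.

Everything is deterministic given `(seed, participant_id)`; the location
topographies depend on the seed only, so they are shared across
participants within one simulated study.

## Time–frequency decomposition

Complex Morlet wavelets on a geometric grid: 26 frequencies from 4 to
30 Hz, cycles rising geometrically from 4 to 11.25 (temporal SD
σ_t = cycles/(2πf)).  Exactly six family members fall in the closed 8–13 Hz
alpha band, giving 64 × 6 = 384 decoding features.  Numerical choices:
support truncated at ±3.5 σ_t; unit-energy amplitude normalization (the
choice is immaterial after dB baselining, which a test asserts); FFT
convolution with zero padding, sharing one forward FFT across all
frequencies; single-precision arithmetic by default (~7 significant digits,
far below physiological noise; float64 available via a flag).  The
per-frequency half-wavelet edge region is recorded in the output
(`edge_samples`); with −1000..3000 ms epochs the longest wavelet (4 Hz,
≈560 ms half-length) leaves all analysis windows (≥ −200 ms) untouched.

Decibel baselining divides by the *across-trial* mean power per channel ×
frequency in the −200..0 ms window and is applied to single trials —
averaged rather than single-trial baselines for stability; because the
baseline is a per-(channel, frequency) constant, the contra/ipsi split and
the dB conversion commute.  The decoding branch deliberately consumes raw
(non-baselined) power; the lateralization branch consumes dB.

## Decoding

Per participant, timepoint and contrast (left/right on horizontal-cue
trials, top/bottom on vertical-cue trials; the same two contrasts run on
all neutral trials, labelled by their encoded locations):

1. trials of each class are randomly split into 3 blocks, surplus trials
   beyond `floor(n/3)` per class removed at random;
2. feature vectors (384 raw alpha-power values) are averaged within each
   (block, class) cell — 6 averages, so each training fold is a 384 × 4
   matrix;
3. a linear soft-margin SVM (C = 1, features standardized with
   training-fold statistics) is trained on 2/3 of the averages and tested
   on the rest, 3-fold cross-validated — with two classes the
   error-correcting-output-codes construction reduces to this single
   binary learner;
4. the whole assignment is redrawn over 10 iterations; accuracy is the
   fraction of correctly predicted test averages over iterations, folds
   and contrasts, smoothed with a 5-point moving window (shrinking at the
   edges rather than padding).

The decoding grid takes every 5th sample of the 250 Hz time–frequency
grid (50 Hz); the analysis window is −200..2000 ms and statistics are
restricted to 500..2000 ms.  Chance is 1/2.  Per-(participant, contrast)
RNG streams are derived from the config seed, so results are reproducible
and independent of participant processing order.

A caution on single-permutation chance checks: shuffling the class labels
once and re-running the decoder does *not* estimate chance without bias at
small trial counts.  A fixed permutation retains a chance correlation of
order 1/√n with the true labels, and because the mislabeling is consistent
across timepoints, folds and iterations, a decoder facing a decodable
signal can exploit it — we measure permuted-label accuracies of 52–55%
at 30 trials per class under the default generator effects.  Cutting the
correlation (60 trials per class, the emulated study's own design) leaves
only the opposite-signed cross-validation depletion bias (test sets drawn
without replacement are anti-correlated with training composition),
bringing permuted-label accuracy to ≈48–50%.  The chance-calibration
checks in the test suite and the acceptance script therefore state the
trial counts they use, and tolerances around the 50% level account for
these finite-sample effects rather than for binomial noise alone.

## Cluster permutation inference

Pointwise one-sample (or paired) t statistics are thresholded at the
t-distribution critical value for the cluster-forming alpha (0.05; halved
per tail for two-sided tests); contiguous supra-threshold runs (4-connected
voxels for time–frequency maps) form clusters, separately per sign.

* **Sign-flip test** (accuracy vs. chance; one-sided "greater" by design,
  since accuracy is hypothesized to exceed chance): each of 100,000
  permutations flips every participant's whole deviation series with
  probability 0.5; the maximum cluster statistic (mass = summed t by
  default; size available) forms the null; cluster p-values use the
  add-one estimator (1+b)/(1+m), which cannot be zero, and a cluster is
  significant at p ≤ α.
* **Paired label-exchange test** (contra vs. ipsi; condition contrasts):
  exchanging a participant's condition pair is equivalent to flipping the
  sign of their difference, so the same engine runs on A−B with the
  cluster *size* statistic over 10,000 permutations; a cluster is
  significant when its size strictly exceeds the 95th percentile of the
  permutation maxima.  The integer-valued size statistic is heavily tied,
  which together with the strict inequality makes this rule conservative
  in practice (empirical family-wise error well below the nominal 5%;
  the sign-flip test sits at the nominal level).  Both tests' family-wise
  error control is verified by simulation in the test suite.

Numerical details: permutation t maps are computed vectorized from
sign-weighted sums (the sum of squares is flip-invariant); zero-variance
points yield t = 0 (never a cluster member at the null value) and
infinite t is capped; tie comparisons between observed and permutation
statistics use a relative tolerance of 1e-8 so that permutations
reproducing the observed arrangement count as ties regardless of
floating-point summation order.

## Lateralization and PCN

Trials whose selective cue marks the vertical axis have no lateral target
and are excluded (half of the selective trials by design); neutral trials
keep their encoded lateral location as the side definition, since both
locations remain relevant under a neutral cue.  For a left-side target the
contralateral signal is the mean over right-hemisphere members of the
posterior pairs PO7/8, PO3/4, O1/2 (alpha branch; dB, averaged over the
closed 8–13 Hz band) or PO7/8 alone (ERP branch; µV after −200..0 ms
baseline subtraction), mirrored for right-side targets; the per-trial
contra/ipsi means are averaged per participant.  Statistics run in the
500..1500 ms window.  The ERP branch operates on broadband epochs; an
optional moving-average smoothing flag exists but defaults off, since the
synthetic data contain no high-frequency artifacts that preprocessing
would normally remove.

## Behavioral statistics

Five measures per participant × condition: accuracy (%), RT over all and
over correct trials, confidence over all and over correct trials.  Paired
t-tests (two-sided) with the 95% CI of the mean difference, and Cohen's
d_av = (M₁−M₂) / ((SD₁+SD₂)/2) with *sample* SDs.  The reporting helper
truncates (not rounds) d_av to two decimals, matching the convention of
printed reports of this statistic (e.g. 0.2354 → 0.23); internal values
keep full precision.  The t statistic is never reconstructed from printed
means/SDs — that requires the pairwise correlation — so t is only tested
against synthetic raw data.

## Problem sizes

The package's tests and the acceptance script run the chain at desk scale
as a deliberate choice: 250 Hz native simulation (skipping the 1000 Hz →
250 Hz resampling step, which is tested separately), 2–10 participants,
12–48 objects, and permutation counts of 500–5,000 instead of
10,000–100,000.  Study-scale defaults (30 participants, 120 objects,
1000 Hz) remain the `SimConfig` defaults and are exercised once in the
test suite for structural properties.

## Known limitations

* The generator's effects are stylized: stationary sinusoidal alpha, a
  single Gaussian PCN, no eye movements, muscle artifacts, ERP components
  other than the PCN, or trial-to-trial latency jitter.  Passing
  effect-recovery tests shows the analysis chain is correct and
  calibrated, not that real EEG would yield these effect sizes.
* Preprocessing (filtering, channel/trial rejection, ICA) is out of scope;
  the pipeline consumes clean epochs.
* Decoding supports exactly two classes per contrast; multiclass ECOC,
  cross-condition generalization and temporal generalization are not
  implemented.
* Cluster inference is temporal (or time × frequency); spatial
  channel-neighbourhood clustering and TFCE are not implemented.
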