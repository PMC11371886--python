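# Methods

This note documents the models and estimators implemented in `hrvcohort`,
the parameter choices that matter, and what the synthetic data do and do
not establish.

## Artifact filtering

Holter analysis software exports RR intervals that still contain ectopic
beats and detection artifacts. The filter accepts a beat when (i) its
interval lies inside absolute bounds (default 300–2000 ms), (ii) it
carries no non-normal annotation, and (iii) it deviates from the running
median of the most recently accepted 11 beats by at most 20%. The running
reference uses accepted beats only, which makes the filter idempotent:
re-filtering a filtered series changes nothing. All three parameters are
configurable (`FilterParams`); the defaults mirror common Holter practice.
This filter is a stated convention, not a reproduction of any particular
vendor pipeline.

Eligibility is metadata-driven: recordings are excluded for pacemaker
stimulation, for atrial fibrillation covering at least half the recording
time (`af_fraction >= 0.5`), or after heart transplantation. AF detection
itself is out of scope; the fraction arrives as annotation.

## Time domain

Sample (n−1) standard deviations throughout. Mean HR is 60000 / mean(NN)
rather than the mean of instantaneous rates (the two differ by Jensen's
inequality; the choice is configurable in spirit by computing from the NN
series directly). SDANN segments are contiguous 5-minute windows of
elapsed time from the first accepted beat; segments whose summed interval
time covers less than half the window are dropped, since gaps from
rejected beats would otherwise bias segment means. SDANN is reported
missing — never zero — when fewer than two valid segments exist. pNN50
uses the strict inequality (differences *greater than* 50 ms).

## Frequency domain

The NN series is resampled to a uniform 4 Hz tachogram. The spectral
pipeline uses **cubic-spline** interpolation: linear interpolation acts as
a sinc² low-pass relative to the beat rate (≈1.3 Hz) and attenuates the
HF band (0.15–0.40 Hz) by ≈20%, biasing LF/HF upward by ≈25%; the cubic
spline keeps the distortion under ~2%. (`resample_tachogram` itself
defaults to linear, the simplest contract; the marker pipeline passes
`method="cubic"`.)

Band powers integrate a Welch PSD (Hann window, 5-minute segments, 50%
overlap, mean and linear trend removed) over half-open bands
ULF (0, 1/300] Hz, VLF (1/300, 0.04], LF (0.04, 0.15], HF (0.15, 0.40];
total power integrates (0, 0.40]. Powers are in ms² (ms²/Hz integrated
over Hz). With 5-minute segments the ULF band contains a single Fourier
bin, so Welch ULF mainly reflects oscillations near the 5-minute period —
slower rhythms are absorbed by per-segment detrending. This is why the
two time-resolved ULF summaries exist:

* **ULF Fourier** — band power of each detrended 30-minute window
  (stepped by 5 minutes), summarised by the interquartile range of the
  track. The long window resolves periods of 5 minutes and above.
* **ULF wavelet** — a maximal-overlap discrete wavelet transform (MODWT,
  least-asymmetric order-8 `sym8` wavelet, circular boundary) of the
  detrended tachogram; the track is the per-time-point sum of squared
  detail coefficients over the levels whose nominal dyadic bands
  [rate/2^(j+1), rate/2^j] intersect the ULF band, summarised by its
  median. At 4 Hz this needs level 10 and deeper, i.e. at least ~1.1 h of
  data; shorter records report the marker missing with a reason code.
  The MODWT pyramid is implemented directly (filters from PyWavelets,
  rescaled by 1/√2) because the undecimated transform PyWavelets ships
  uses a different normalisation; a brute-force convolution oracle in the
  test suite pins the implementation to the defining recursion.

A ratio guard reports LF/HF as missing when HF power is numerically zero.

## Non-linear indices

All non-linear markers operate on the NN sequence in beat domain —
resampling would smooth away the beat-to-beat dynamics they measure. The
O(n²) estimators (correlation dimension, sample entropy) and the
neighbour searches cap the series at `max_points` (default 5000) leading
beats; this bounds cost at roughly a second per marker per record.

* **PRSA (AC/DC).** Anchors are beats whose interval lengthens
  (deceleration) or shortens (acceleration) versus the previous beat,
  excluding changes above 5% of the previous interval (artifact guard)
  and anchors whose ±L window (L = 2) leaves the series. The averaged
  profile X(k), k = −2..1, is summarised by the Haar-like contrast
  (X(0) + X(1) − X(−1) − X(−2)) / 4. On a ramp of +2 ms/beat this equals
  exactly 2 ms.
* **Time lag.** Smallest lag k with sample autocorrelation below 1/e
  (max 50, saturation flagged). For AR(1) with coefficient 0.9 the
  analytic answer is 10.
* **Embedding dimension (Cao).** E1(d) = E(d+1)/E(d) from nearest-
  neighbour distance ratios under the Chebyshev norm; the estimate is the
  smallest d with E1(d) ≥ 0.95 and |E1(d+1) − E1(d)| < 0.05. Two
  safeguards follow Cao's published method: neighbours closer than
  1e−9·SD are skipped (float-identical recurrences of periodic signals
  otherwise produce rounding-noise ratios), and the companion statistic
  E2 gates stochastic series — when E2 stays at 1 for every dimension
  *and* the one-step-ahead neighbour distance E*(1) is on the scale of
  the series SD (i.e. the next value is unpredictable), the series is
  noise-like and the estimate saturates at `max_dim` (15) with a flag.
  The E* condition keeps quasi-periodic signals, whose E2 is also flat
  but whose E* is tiny, on the deterministic path.
* **Correlation dimension (Grassberger–Procaccia D2).** Correlation sums
  over 24 log-spaced radii from 0.01 to 2 SD with a Theiler window
  (default: the time lag); D2 is the least-squares slope of log C(r) vs
  log r over the scaling region, taken as radii with C(r) in
  [0.0025, 0.25] (small enough to probe fine structure, large enough to
  be populated), falling back to populated radii when the band is empty.
* **Sample entropy.** Richman–Moorman SampEn(m = 2, r = 0.2·SD),
  Chebyshev distance, self-matches excluded, −ln(A/B). Zero-variance
  series and zero match counts raise distinct reason codes.
* **Maximal Lyapunov exponent (Rosenstein).** Each embedded point is
  paired with its nearest neighbour within a fixed radius (default
  100 ms, the marker's conventional radius in interval units) outside the
  Theiler window; the exponent is the slope of the mean log divergence
  over iterations 1–10. The logistic map at r = 4 gives ln 2 within
  ±0.07 at n = 10⁴.

Missing markers always carry machine-readable reason codes
(`zero_variance`, `no_anchors`, `no_neighbours`, ...) and are never
encoded as zeros.

## Reference ranges and summaries

Quantiles use linear interpolation between order statistics at position
p·(n−1); the convention is recorded in output metadata. Reference bounds
are the 5th/95th percentiles of each marker among subjects in the healthy
mask (heart-failure stage 0/A, excluding long-standing diet-untreated
diabetes and degenerative/structural neurological disorders), refusing
groups below 20 non-missing values. Classification treats the bounds as
inside; "below"/"above" are strict. Tertiles use the same quantile
convention with groups (−∞, t1], (t1, t2], (t2, ∞).

## Marker selection

The literature track ranks markers by supplied hit counts, descending,
ties broken lexicographically. The data-driven track is a random survival
forest: each tree is grown on a bootstrap sample; at each node `mtry`
(default ⌈√p⌉) markers are sampled and age and sex are always appended;
candidate cut points are the node-level quantiles of each candidate
variable at 10 evenly spaced probabilities (deterministic, bounded
compute); the split maximising the standardized two-sample log-rank
statistic wins. Splitting stops below 15 samples or 3 deaths. Minimal
depth of a variable in a tree is the depth of its shallowest split;
variables never split are assigned the tree's maximal terminal depth
(penalising absence); importance is the mean over trees, ascending. The
quantile-based cut points make tree structure exactly invariant under
strictly monotone transforms of any predictor. The selected set is the
union of the two top-10 lists with per-marker source labels.

## Outcome models

Standardization divides by the sample SD of the modelled sample without
centering; this leaves Cox fits and linear slopes unchanged relative to
centred scaling and keeps values interpretable. The Cox partial
likelihood (Breslow ties; Efron behind a flag) is maximised by
Newton–Raphson with step halving, tolerance 1e−9 on the score norm, at
most 50 iterations; monotone-likelihood separation (|β| > 20) is flagged
as non-convergence. Wald 95% CIs and p-values. The implementation is
cross-checked against lifelines in the test suite and against explicit
risk-set sums on small data. Linear models are OLS (statsmodels) with an
intercept; rank-deficient designs raise an error naming the collinear
columns. Cumulative incidence is 1 − Kaplan–Meier (lifelines) per
stratum. The model battery fits one standardized Cox model per marker per
adjustment tier (age/sex; full), for the continuous per-SD predictor and
for the binary outside-reference-range predictor, skipping markers
missing in more than half the sample.

## Synthetic data

`gen_rr_record` builds beats iteratively: NN(t) = mean ± LF sinusoid
(0.1 Hz) ± HF sinusoid (0.25 Hz) ± 24 h circadian cosine + AR(1) noise;
ectopic events replace an interval with a (0.6×, 1.4×) early/compensatory
pair and artifact events inject a spurious short interval. Healthy
defaults (mean 780 ms; amplitudes 25/15/110 ms; AR(1) coefficient 0.9,
innovation SD 6 ms) were calibrated once, at design time, so that the LF
and HF bands are tone-dominated — the condition under which the band
power ratio recovers the amplitude-squared ratio (a_lf/a_hf)², which is
the generator's defining fidelity invariant — while keeping overall
variability in a physiologic range. The heart-failure group has uniformly
reduced modulation and more ectopy.

Additive beat-domain modulation was chosen over an integral-pulse-
frequency model for analytic tractability: expected band powers are a²/2
and recovery is checkable in closed form. Consequences: respiratory
coupling, non-stationarity beyond the circadian cosine, true chaotic
dynamics, and realistic correlation structure between markers are *not*
emulated. Passing tests therefore establish estimator correctness and
statistical calibration, not physiological realism; absolute marker
levels (e.g. sample entropy, fractal dimension) of synthetic records need
not match any clinical population.

`gen_cohort` has two record modes. `markers` draws marker values from
group-specific normal distributions and is used for statistical
experiments (coverage, selection) that condition on marker values —
hazard depends on the marker z-score under its own group's generating
distribution, times are Weibull (shape 1.2, scale 38 years ≈ 14%
8-year baseline mortality), administratively censored at 8 years, with a
configurable fraction of deaths labelled cardiac and censored at 6 years.
`full` generates an RR recording per subject with subject-level jitter.
Ground truth (coefficients, z-scores, seeds) is emitted as JSON alongside
the data, never re-derived from the pipeline under test.

## Problem sizes and numerical choices

Validation uses: n = 10⁴ logistic-map iterates for the Lyapunov and D2
limits; 22.49 h records (~10⁵ beats) for spectral fidelity; 500 healthy
subjects for reference self-consistency; 1500-subject cohorts (~200
events) for Cox coverage — the nominal 95% CI coverage is measured at
95.3%, and the test evaluates 500 replicates against a 93% floor so
binomial noise cannot mask a real calibration failure; 300-subject
cohorts with 200-tree forests over 20 seeds for selection behaviour.
End-to-end pipeline tests use ~30-minute recordings, long enough for
every marker except the ULF track summaries, which are reported missing
with reasons there.

Ties are broken deterministically everywhere (stable sorts,
lexicographic marker order, seeded generators); identical seeds produce
byte-identical artifacts.

## Known limitations

* The artifact filter and the non-linear estimator settings are stated
  conventions; cohort studies using vendor software will differ in
  detail.
* Welch ULF is nearly degenerate by construction (one bin); use the
  ULF-Fourier/wavelet tracks for slow rhythms.
* The embedding-dimension estimate for strongly stochastic series is the
  saturation value with a flag, not a dimension.
* Per-SD hazard ratios are non-collapsible: a marginal fit of one marker
  attenuates relative to a joint generating model with several active
  markers. Coverage experiments therefore activate one coefficient at a
  time.
* Competing-risk modelling (Fine–Gray) is not implemented; cardiac death
  is handled cause-specifically.
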