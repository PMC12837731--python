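# Methods

`scalphfo` re-implements, as a tested pipeline, a phenotypic analysis of
scalp high-frequency oscillations (HFOs) in pediatric absence epilepsy:
Hilbert-envelope detection of ripple-band (80–250 Hz) events on 10–20
scalp EEG, four morphological features per event, k-means phenotyping
with elbow-based model selection, and cluster-by-epoch association
statistics.  Because the clinical recordings behind the original study
are not publicly deposited, a synthetic-data module generates both
annotated EEG scenes (for the signal stages) and feature-space mixtures
(for the statistical stages) with known ground truth.

## Detection

The detector operates on the 19-channel average montage.  Signals are
band-pass filtered to 80–250 Hz with a linear-phase Kaiser-window FIR
applied forward–backward (zero phase; pass-band ripple < 1 dB, stop-band
≥ 40 dB one transition width beyond the band edges; the filter length
follows from `scipy.signal.kaiserord` at a 10 Hz transition, ~230 taps at
1024 Hz).  The envelope is the magnitude of the analytic signal.

**Threshold.** The detection threshold is *mean + 2 SD* of each
channel's envelope over the entire recording.  The mean offset matters:
the envelope of band-limited noise is Rayleigh-distributed with mean
≈ 1.25 σ and SD ≈ 0.65 σ (σ = in-band noise SD), so a bare 2 × SD level
(≈ 1.31 σ) sits *below* the envelope's own mean and marks ~40% of all
samples — no workable detector thresholds there.  `threshold_mode`
switches to the bare-SD convention if wanted.  The SD is computed per
channel because electrode noise levels differ.

**Candidate events.** Contiguous supra-threshold runs become candidates;
runs separated by less than `merge_gap_ms` (default 3 ms) are merged.
The small default is deliberate: merging heals the 1–2 ms envelope dips
that noise superimposes on a genuine burst, while a 10 ms gap — common in
detector folklore — was measured here to chain independent noise
excursions into > 4-cycle pseudo-events at rates of tens per minute.

**Validity rules.** A candidate is kept only if (a) its crest-interval
frequency lies inside the band and (b) it spans at least `min_cycles`
(default 4) cycles.  The cycle check is evaluated on the envelope's
*half-peak core* (the contiguous region around the envelope maximum
where a lightly smoothed envelope stays above half its peak), at the
crest rate measured within that core.  A naive run-duration × frequency
count systematically overcounts: the supra-threshold footprint outlasts
the oscillation proper through taper fringes, zero-phase filter smear,
and — at high amplitude — background activity that happens to continue
the rhythm at threshold level.  Even so, the rejection of short
transients is statistical, not absolute: a high-amplitude 3-cycle
transient occasionally *realizes* a fourth in-band cycle by
phase-aligning with the background (measured ≈ 3–8% of planted 3-cycle
probes at 8× the in-band noise), and such composites are legitimate
4-cycle events of the realized waveform.  No footprint statistic we
evaluated rejects all of them while keeping ≥ 95% recall of 5-cycle
bursts at SNR 5; the property suite documents this frontier.

Events co-occurring on multiple channels (interval overlap ≥ 50% of the
shorter event) are collapsed onto the channel with the largest envelope
peak.  Events intersecting a ±75 ms window around an annotated spike
(interictal epileptiform discharge) are classified *spike ripple*,
otherwise *ripple*; downstream analysis keeps spike ripples only.
Events take the epoch label of the annotated interval containing their
midpoint.  A peak-to-peak amplitude ceiling (default 1000 µV) stands in
for the visual artifact review of a clinical workflow.

## Features

For each retained event, on the band-passed waveform of its channel:

* **average frequency** — reciprocal mean crest-to-crest interval;
* **duration** — time the envelope stays above the detection threshold
  (the contiguous run containing the envelope maximum), in ms;
* **number of cycles** — duration / mean crest-to-crest interval, so
  `n_cycles = frequency × duration` holds identically;
* **amplitude** — highest peak-to-peak oscillation amplitude as a
  z-score against baseline.  The amplitude estimator is 2 × the
  quadratic-mean envelope over the envelope's half-peak core: exact for
  a clean tone and nearly unbiased under noise (relative bias
  ~ 1/SNR²), whereas a raw max-minus-min picks the two most
  noise-inflated samples and overestimates by ~ 10% at SNR 10.
  Baseline peak-to-peak values come from non-overlapping 100 ms windows
  of the same channel, excluding detected events ± 200 ms.

Events whose recomputed frequency leaves the band or whose cycles fall
below the minimum are dropped here (a consistency re-check of the event
definition).  Measured on 100 planted bursts (90–240 Hz, 30–90 ms,
SNR 10 to isolate estimator error from detection error): median absolute
relative error ≈ 0.5% (frequency), ≈ 8% (duration; the threshold clips
the taper predictably), ≈ 8% (cycles), ≈ 3% (amplitude).

## Phenotyping

Events with a robust z-score (median/MAD, consistency factor 1.4826)
above 3.5 on any transformed feature are excluded in a single pass.
Amplitude and cycle count are log-transformed (natural log; the base
only rescales a standardized column) and all four columns z-scored so
each feature weighs equally in the Euclidean metric.  K-means (Lloyd,
k-means++ starts) is run with 300 random restarts by default, keeping
the lowest within-cluster sum of squares (WSS); the whole procedure is
deterministic given a seed.

The number of clusters is the elbow of the WSS curve over k = 1..8: the
k at which the *rate of decrease* of WSS changes most sharply, i.e. the
maximal second difference of the curve.  We also evaluated the
max-distance-to-chord (Kneedle) variant; on the packaged fixture it is
markedly less stable (86% vs 98% correct selection over 50 draws)
because WSS still falls appreciably from k = 3 to 4 on overlapping
components, flattening the chord geometry.  Ties break toward smaller
k; a linear curve yields the smallest interior k with a "no elbow"
warning.  For k = 3 the clusters are relabelled canonically by ascending
duration centroid (1 = shortest, 3 = longest), matching the published
phenotype naming.

## Statistics

* 3 × 3 cluster-by-epoch contingency table with row percentages;
  Pearson chi-square without continuity correction.
* Multinomial logistic regression of epoch (reference: interictal,
  seizure-free) on dummy-coded cluster (reference: cluster 1), Newton
  maximum likelihood, odds ratios with Wald 95% CIs.  In this saturated
  single-factor design the MLE reproduces empirical cell proportions and
  each OR equals a cross-product ratio of counts — the test suite uses
  this closed form as an independent oracle.  Zero cells are flagged as
  separable rather than silently producing divergent estimates.
* Tukey–Kramer honestly-significant-difference comparisons:
  q = |Δmean| / √(MSE/2 · (1/nᵢ + 1/nⱼ)), adjusted p from the
  studentized-range distribution with N − g df; reduces to Tukey's HSD
  for equal group sizes.
* OLS of each feature on epoch dummies, optionally age-adjusted, with
  t-based 95% CIs and standardized β = β · SD(x)/SD(y).

Events are treated as independent (the original analysis pools events
across patients); no mixed-effects modelling is attempted.

## Synthetic data

**Scenes.** Background is Gaussian 1/f noise (exponent 1, configurable),
10 µV RMS per channel — a typical scalp EEG scale.  Ripple bursts are
Tukey-tapered sinusoids (taper fraction 0.25, keeping a flat envelope
core so the threshold-based duration is well defined); spikes are
biphasic transients (30 ms sharp negative + 40 ms slower positive
phase); ictal intervals carry a periodic spike-plus-slow-wave template
at 3 Hz.  The standard validation scene plants bursts of ≥ 5 planned
cycles (frequencies 90–240 Hz, durations 30–90 ms, rejection-sampled so
the population has no boundary atom) at SNRs drawn from U[5, 10]
against the measured in-band background, plus 8×-amplitude 3-cycle
probes that the cycle rule should reject.  Scenes emulate the
morphology and timing structure the detector assumes — not sleep
spindles, eye blinks, muscle artifact, or realistic seizure dynamics —
so green detector properties demonstrate correctness of the algorithm
under its stated model, not robustness to clinical artifact.

**Feature mixture.** A 3-component mixture in (frequency, duration,
amplitude, cycles) space with component sizes 65/70/28 (n = 163):
frequency and duration normal, amplitude and cycles log-normal
parameterized by median and IQR (location = log median; scale from the
quartile ratio via the normal 0.75-quantile — a log-normal is
geometrically symmetric, so asymmetric printed quartiles are matched in
ratio).  Features are drawn independently within components.  Printed
phenotype statistics fix: component 1 duration 35.3 ± 7.3 ms and
amplitude median 6.2 [5.6–7.4]; component 2 frequency 118.1 ± 10.5 Hz;
component 3 duration 70.2 ± 15.4 ms and cycles median 9.8 [8.8–11.5].
The remaining cells are closed once from the study's epoch-level
statistics and the cluster-by-epoch composition: component 1 frequency
145 ± 18 Hz (epoch-composition closure) and cycles median 5.1 [4.5–5.8]
(frequency × duration consistency); component 2 duration 44.7 ± 12.0 ms
and amplitude median 8.9 [6.9–11.7] (the interictal-active epoch it
dominates); component 3 frequency 140 ± 15 Hz (cycles/duration
consistency) and amplitude median 6.3 [5.3–7.5] (global log-amplitude
closure).  Only printed cells are asserted by tests.  The components
genuinely overlap: the Bayes-optimal classifier built from the true
generating densities reaches only a median adjusted Rand index of ~0.7
against the labels, which bounds what any clustering can achieve at the
event level; centroid-level recovery is the meaningful target and is
accurate to ~1.3 Hz on the low-frequency component.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds by hashing (master seed, stage name).  The test suite
and acceptance script use desk-scale problem sizes chosen for tight
feedback loops: 50 draws of the n = 163 fixture for the clustering
claims, 20 one-minute 19-channel scenes for the detector properties,
and one 100-burst scene for feature recovery.  EDF files are written by
a minimal self-contained 16-bit encoder (one-second records) and read
back through MNE, which also serves as the round-trip oracle in tests.

## Known limitations

* Threshold-footprint cycle counting cannot reject every high-amplitude
  sub-4-cycle transient (see Detection); the property suite asserts the
  ideal and the failure is visible there rather than hidden.
* The amplitude z-score baseline (window length, exclusion pad) is a
  reconstruction; published amplitude z-scores depend on an unstated
  baseline convention and are not directly comparable.
* The printed odds ratios of the original cross-tabulation are not
  reproducible from its own counts under any saturated single-factor
  multinomial model (the counts imply cross-product ratios of
  9.38/0.56/8.33 against printed 2.71/0.33/5.00, likely reflecting an
  unreported adjustment); the statistics stage therefore validates
  against the chi-square worked example and the saturated-model
  identities instead.
* Events are pooled across patients; patient-level correlation is out
  of scope.
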