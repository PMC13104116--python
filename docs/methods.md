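# Methods

This note documents the models, conventions and design choices behind
`craniodyn`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
where the genuinely open choices were made.

## Synthetic session model

A session simulates layer-2/3 calcium imaging during drifting-grating
stimulation. The stimulus protocol is fixed by the study design it
emulates: four orientations (0°, 45°, 90°, 135°), three stimulus sets of
eight repeats per orientation (96 trials), 2-s stimuli, inter-stimulus
intervals drawn uniformly from 8–10 s, 20-Hz acquisition. Orientations
are shuffled within each set.

Each neuron is placed uniformly on a 2 × 2 mm sheet tiled into K = 19
rectangular regions (a stand-in for atlas parcellation; real analyses
would substitute registered region labels). The trace model is

1. **Stimulus drive.** Ground-truth responsive neurons (fraction 0.3 by
   default) receive a boxcar drive during each stimulus window, scaled by
   a von Mises tuning curve on the doubled angle,
   `g(θ) = exp(κ(cos 2(θ − θ_pref) − 1))`, period 180°, peak 1 at the
   preferred orientation. Preferred orientations are drawn from the four
   stimulus orientations. κ (default 3) spans the observed continuum from
   orientation-selective to multi-orientation responders; κ → ∞ yields
   single-orientation responders, κ = 0 untuned ones. No tuning model is
   dictated by the source protocol; the von Mises form is the standard
   circular-tuning choice.
2. **Shared factors.** Correlated activity comes from one Gaussian factor
   per community (amplitude 0.25) plus one global factor shared by all
   neurons (amplitude 0.05). Communities are assigned per *region*
   (contiguous blocks of region ids, 3 communities by default), so the
   community structure is visible in both neuron- and region-level
   networks. Amplitudes are defined as **post-kernel trace standard
   deviations**: the raw white factors are pre-scaled by the inverse
   smoothing gain of the calcium kernel, so pairwise correlations are
   controlled directly by the stated amplitudes rather than by an
   interaction with the kernel bandwidth.
3. **Calcium kernel.** Drive plus shared factors are passed through a
   causal single-exponential kernel with unit steady-state gain
   (`y[t] = (1−a)x[t] + a·y[t−1]`, `a = exp(−1/(τ·rate))`), τ = 0.7 s,
   approximating GCaMP6f decay. A boxcar of amplitude A therefore rises
   toward A with time constant τ; the 2-s window mean of the response is
   ≈ 0.71 A.
4. **Observation noise.** White Gaussian noise (SD 0.1 ΔF/F) is added
   last and must be strictly positive.

Default response amplitude is 1.5 ΔF/F. With the default baseline SD
(≈ 0.27 from shared factors plus observation noise) the preferred-
orientation window mean (≈ 1.07) clears the 3-SD detection threshold
(≈ 0.82) with margin, which is what "high signal-to-noise" means for the
calibration tests. These values are stated in config and are not claimed
to match any particular recording; they are chosen so that the generator
has a well-defined detectable regime and a well-defined null.

### Recovery scenarios

A `RecoveryScenario` bundles one session per post-operative timepoint
(days 1, 4, 7, 10, 14, 21, 28, 56 — eight timepoints) with per-day
parameter overrides, plus per-animal longitudinal morphology series for
three animals per modality. The microglial-intensity ground truth is a
Gaussian bump, baseline 1, amplitude 1, peak day 10, width 6 days; the
neuronal-intensity curve is the same curve delayed by `lag_days`
(default 4 days, so it peaks near day 14). Measurement noise is
multiplicative Gaussian with relative SD 0.05 per animal and timepoint —
a realistic repeat-measurement scatter for normalized fluorescence
intensity. A scenario whose delayed curve would peak beyond day 56 is
rejected.

`disruption_scenario` encodes a designed functional-disruption
trajectory by raising the *global* (between-community) shared-factor
amplitude along a Gaussian profile peaking at the trough day (default
21, amplitude 0.05 → 0.45): stronger global coupling blurs the community
structure, so the region-network modularity dips where the coupling
peaks. A side effect worth knowing: the inflated baseline SD at peak
disruption also suppresses responsive-neuron detection, which is
consistent with the phenomenon being modeled but means the responsive
count is not a flat control in this scenario.

### Star-cell images

`simulate_cell_image` renders a disk soma plus n straight 1-px rays from
the image center to `soma_radius + process_length`, at jittered
equally-spaced angles (jitter ±0.15 of the nominal spacing, guaranteeing
a minimum angular gap of 0.7× the spacing so rays remain resolvable just
outside the soma for up to 12 processes). Rays are rasterized as densely
sampled nearest-pixel polylines — a gap-free rasterization: every point
of the continuous ray has its nearest pixel set. Ray sampling stops half
a pixel short of the nominal tip so rounding never pushes a ray pixel
past the tip radius. The analytic Sholl profile is therefore: 1 inside
the soma (the circle lies wholly in foreground), n between soma edge and
tip, 0 beyond.

## Sholl intersection counting

Circles are not rasterized and intersected with the mask pixel set:
two 8-connected rasterized curves can cross without sharing a pixel (a
diagonal 1-px process steps √2 per pixel and can skip a unit-width
annulus entirely), so pixel-sharing counts are not exact. Instead each
circle is sampled densely in angle (arc step ≈ 0.25 px); a sample is
foreground when any of the four pixels surrounding it is foreground; and
the count is the number of connected foreground runs around the circle,
after closing background runs shorter than 0.75 px of arc (sub-pixel
gaps are rasterization artifacts — distinct 1-px processes are separated
by at least one pixel). This is deterministic, translation-invariant
together with the center, and exact on the analytic star cells.

The soma center is an input (selected manually and blinded in the
emulated protocol); no soma detection is implemented. The positive-area
threshold is either fixed or background-derived (mean + 2 SD of a
declared background region); the reference protocol does not state its
threshold, so it is config. "Normalized" intensity/area means division
by the day-1 value and lives in the longitudinal stage, not in the image
metrics.

## Responsive-neuron criterion

Per neuron and orientation: responsive ⇔ mean ΔF/F over all of that
orientation's stimulus windows **strictly exceeds** the baseline mean
plus `k_sd` (default 3) baseline SDs. Conventions, stated once and used
everywhere:

* Frames are 0-based, half-open, floor-rounded:
  stimulus = `[⌊onset·rate⌋, ⌊(onset+Δt)·rate⌋)`; baseline = the Δt_b
  seconds immediately before onset with the same convention
  (Δt_b defaults to Δt = 2 s).
* The baseline pools the pre-stimulus windows of **all** trials per
  neuron (stabilizes the SD); a per-orientation baseline mode is
  available as config.
* Baseline SD uses the population (divide-by-N) convention.
* Ties resolve to *not responsive*, so a constant trace never passes.

The criterion compares a mean over ~960 frames to a single-frame SD, so
under a white-noise null it is extremely conservative (empirical null
fraction ≈ 0); with realistically autocorrelated traces it remains well
below 1%. Detection is invariant to adding a constant to a trace and
equivariant under positive scaling. Regional summaries count
union-responsive neurons (responsive to ≥ 1 orientation) per region;
the time-normalized table divides each region's day-series by that
region's maximum (all-zero regions stay zero).

## Decoding

Features are per-trial stimulus-window means (trials × neurons). The
classifier is a linear-kernel SVM (C = 1), one-vs-rest, with features
z-scored per fold on training data only, under stratified 4-fold
cross-validation with seeded shuffling; accuracy is pooled over all
held-out trials. The CV scheme, kernel, regularization and
standardization are fixed in config because the emulated protocol does
not specify them; decoding uses all neurons by default with a
responsive-only switch. The LDA embedding (≤ 3 components for four
classes) falls back automatically to the shrinkage-regularized eigen
solver if the within-class scatter is singular (recorded in the result
metadata); fully degenerate inputs embed at the origin.

## Network metrics

Connectivity matrices are pairwise Pearson coefficients (symmetric,
zero diagonal, clipped to [−1, 1]); zero-variance inputs are an error
naming the node. Region-level networks average traces within regions
first; empty regions are dropped and reported.

Modularity and degree centrality are only well defined on nonnegative
graphs, so a negative-weight policy is applied first: **clip to zero**
(default), absolute value, or error. Raw signed weights are retained for
the mean connectivity and weight distributions. Modularity follows the
ordered-pair convention (each edge counted in both orientations, 2m
normalization); Q ≡ 0 for the single-community partition at γ = 1, an
identity used as a self-check. The implementation is vectorized and is
verified in the tests against a literal double-loop oracle to 1e-12.

Spectral partitioning maps weights to affinities via (w + 1)/2 with unit
self-affinity and runs k-means-based spectral clustering (k = 3 by
default); an empty community triggers a bounded reseeded retry. Two
modularity trajectories are reported: against the **day-1 partition**
carried to every later day (the default, reading the cluster structure
of the first post-operative day forward) and against a per-day greedy
(CNM) re-optimization — the emulated analysis is ambiguous between the
two, so both are available and neither is claimed as canonical.

## Longitudinal analysis

Baseline normalization divides every value by the cross-animal mean of
day-1 values **per modality**, so the mean normalized baseline is exactly
1 while inter-animal baseline variability is retained (day 1 is the
first post-operative day; no pre-surgery baseline exists in this
design). Interpolation is piecewise-linear onto integer days 1–56, exact
at knots, with no extrapolation. Normalization and interpolation
commute (both are linear).

### Lag correlation

For window widths w ∈ {7, 14, 21, 28, 35} days and lags L ≥ 0, the
fixed window `[1, w]` of one daily series is correlated with the window
`[1+L, w+L]` of the other. Cells whose windows exceed either series'
coverage are marked unavailable rather than erroring. The **headline
lag maximizes the mean R across available widths** (ties → smallest
lag), and the reported (R, p, width) are those of the best cell at that
lag. This aggregation is a deliberate design choice: a short window that
covers only a monotone segment of a smooth recovery curve correlates
near 1 at many lags, so the single-cell grid argmax is unstable (it
recovers an injected lag within ±1 day in well under half of noisy
runs), while the width-averaged profile peaks at the true offset —
exactly, in the noiseless construction, for lags of 3, 5, 7 and 12 days.
The full (w, L) grid is always reported so per-width maxima remain
inspectable. p-values use the t transform of R with n = w; interpolated
days are not independent measurements, so the effective n is smaller —
this caveat is carried as a field on the result rather than corrected,
since the day grid itself is the object of interest.

### Timepoint statistics

`compare_timepoints` takes a complete animals × days table (paired
design; ≥ 3 animals, ≥ 2 days). Shapiro–Wilk runs per day at α = 0.05;
if every day is consistent with normality the route is
repeated-measures one-way ANOVA (direct sum-of-squares decomposition;
the omnibus F is verified against statsmodels' AnovaRM in the tests)
with Tukey's HSD post hoc using the RM error mean square and
(n−1)(k−1) error df; otherwise the Friedman test with Dunn's post hoc
test on within-subject mean ranks, Bonferroni-corrected
(z = (R̄ₐ − R̄_b)/√(k(k+1)/6n)). The report records the route taken and
the per-day normality decisions. Dunn's test is implemented directly
(no established implementation is available in the dependency set).
With n = 3–4 animals the Shapiro–Wilk test has little power, so the
parametric route is common even for mildly non-normal data — an honest
reflection of small-cohort longitudinal designs.

## Problem sizes and reproducibility

All generators are bit-reproducible for a fixed seed; scenario-level
randomness flows through `numpy.random.SeedSequence` spawning, so each
day's session and the morphology series have independent child streams.
Simulated cohorts use 190–300 neurons per session (and 1000 for the
detection null), chosen as the package's standard desk-scale problem
sizes: large enough that detection, decoding and network statistics are
in their stable regimes, small enough that the full test suite and the
acceptance script each run in a couple of minutes. The real system these
sizes emulate is two orders of magnitude larger (>10⁴ neurons); none of
the calibration conclusions here depend on that scale, but absolute
values of, e.g., the strong-connection ratio do depend on network size
and should not be compared across scales.

## What passing tests do and do not show

The generator produces stationary Gaussian shared factors, exponential
calcium kernels, orientation-locked boxcar drives and smooth
single-bump morphology trajectories. Real recordings add slow drift,
behavioral-state modulation, hemodynamic artifacts, non-Poisson firing,
segmentation errors and vessel occlusion — none of which are modeled.
Passing the calibration suite therefore shows that the *estimators* are
correct and well calibrated under their stated assumptions (detection
thresholds behave as specified, decoders reach their ceiling on
separable data and chance on shuffled labels, modularity and lag
estimators recover designed structure); it does not validate the
biological claims of any particular recovery dataset. Known
limitations: the rectangular atlas is a geometric stand-in; morphology
metrics are strictly 2-D (no surface/volume reconstruction); the
lag-correlation p-values inherit the interpolation caveat above; and
negative-weight handling in modularity is a policy choice, not a
derivation.
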