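# Methods

## Generative model

A session is built from point sources on a fine lattice (~300 sources
covering the 6 × 10-mm grid plus a one-pitch margin). Each source emits, per
trial, two stimulus-driven components added to ongoing noise:

- **Evoked theta** — a 4-Hz oscillation under a Gaussian envelope (peak
  150 ms, SD 100 ms post-onset), phase-locked to stimulus onset up to a
  per-source phase jitter drawn with a category-dependent SD
  (`phase_jitter_by_category`; default 0.15 rad, 0.7 rad for right-view
  faces so that cross-channel phase locking differentiates the views).
- **Induced gamma** — an 80-Hz oscillation under a sigmoid-rise/fall
  envelope (≈120–480 ms), with amplitude tuned by category but phase drawn
  uniformly per source and trial, so it survives in power but cancels in
  trial averages.

Category tuning is multiplicative: each source carries a log-gain for every
label it can express, summed across hierarchy levels and exponentiated.
Log-gain fields are Gaussian random fields over source positions with a
squared-exponential kernel: correlation length 6.0 mm for coarse-category
fields and 0.6 mm for subordinate (species/view/identity) fields, both with
SD 0.45, so coarse and fine tuning are matched in per-channel effect size
and differ only in spatial scale. Coarse fields are shared between the
theta and gamma components (coarse clusters are stable across the response);
subordinate fields are drawn independently per component, so early-theta and
late-gamma subordinate maps decorrelate while coarse maps stay correlated.

A channel is a row-normalized Gaussian spatial average of source activity:
pickup SD 0.25 mm for MUA-like sampling, 0.6 mm for penetrating-electrode
LFP, and 2.5 mm for surface ECoG (the surface grid is offset by half a
pitch). Each source's response gain additionally fluctuates trial-to-trial
(log-normal, SD 0.5). This per-source noise is the mechanistic heart of the
summation dissociation: wide ECoG pickup averages it away while retaining
the long-range coarse signal, whereas local pickup keeps both the fine
signal and the noise. Channels then receive shared white noise (SD 0.6,
common to all channels of an array) — the cross-channel trial covariance
that the trial-shuffle control destroys — and private white noise (SD 1.5).

Spiking is an inhomogeneous Poisson process per channel: rate = 5 Hz
baseline + 8 Hz × the channel's locally mixed gamma-envelope amplitude, so
spike counts are linear in the induced-gamma amplitude in expectation and
spikes inherit the fine-scale tuning of the local gamma drive.
Refractoriness is omitted; no downstream statistic depends on it.

Amplitudes (theta 1.3, gamma 1.0 in private-noise SD units) were chosen so
that default-configuration decoding lands in the ranges reported for real
ITC recordings of this kind — coarse ≈ 80–99% depending on modality,
identity ≈ chance–80% — rather than at ceiling, and so that the
summation-scale orderings (surface array best for coarse, local spiking
best for identity) are expressed reliably across seeds.

## Trial schedule and stimulus set

300-ms presentations separated by 600–900-ms blanks (uniform), 8 trials per
stimulus in shuffled order, 0.8-s/1.3-s session edge margins (sized so the
4-Hz wavelet kernel is fully supported around every trial's analysis span).
The default stimulus set has 39 images: the fixed 15-image human-face block
(3 views × 5 identities), 6 monkey faces, 6 bodies, 6 objects, and the
auxiliary modified-face (3) and body-part (3) groups, which are labelled but
excluded from coarse decoding. Stimuli are labels only; no images exist.

## Feature extraction

All windowed features use the standard grid: −50 to 600 ms relative to
onset, 100-ms windows shifted by 50 ms — 12 windows. Spike rates are
counts/0.1 s per window. "Total power" is the mean over the periodogram
bins of each 100-ms window; the bin grid is the window's FFT frequencies at
10-Hz spacing including the DC bin — 101 bins up to 1000 Hz at a 2-kHz
sampling rate, truncated at Nyquist (51 bins) at the 1-kHz default, flagged
in the feature metadata. Wavelet band power uses complex Morlet kernels at
4/12/24/40/80 Hz with envelope σ equal to one cycle period, truncated at
±2σ, scaled to unit energy so power is comparable across bands; the DC
"band" is the mean squared raw voltage per window. Band responses are
normalized by each channel's mean prestimulus (−200..0 ms) power —
session-mean baseline by default, per-trial optionally — and averaged over
the bins whose centers fall in [50, 450) ms, i.e. the 8 windows starting at
0–350 ms. (The alternative "full extent inside 50–450 ms" rule selects 7
windows; the 8-window center rule is the package convention and is
configurable.)

Spike density functions use a Gaussian kernel whose bandwidth minimizes the
Shimazaki–Shinomoto MISE-based cost over a 40-point log-spaced grid from
half the minimal inter-spike interval to the window span, with a
window/4 fallback below 2 spikes. Spike detection takes upward crossings of
+3.7 × signal SD with a 1-ms dead time.

## Decoding protocol

Per category pair: exemplar-held-out folds (N = smaller category's exemplar
count; the larger category is randomly subsampled to N; every fold tests
all trials of exactly one exemplar per category), then per fold: balance
training classes by subsampling the majority (test sets stay intact),
z-score with training statistics (constant columns centered, not scaled),
rank features by one-way F and keep the top 100 (all, if fewer; ties broken
by feature index for reproducibility), train a linear SVM with C = 1 (the
LIBSVM default), classify the held-out trials. Percent correct is pooled
over folds, with Clopper–Pearson 95% intervals; level accuracies pool the
3/1/3/10 pairs of the coarse/species/view/identity levels trial-weighted.
The time course variant slides the 100-ms window in 25-ms steps over 25
time points (starts −50..550 ms; the final windows extend into the
inter-trial gap, which the session margins guarantee to exist). The
frequency variant decodes each band's channels × 12-window features
separately plus the pooled-band condition, with identical k throughout.
Each exemplar subselection is a single seeded draw; averaging over repeated
draws is available but off by default.

## Shuffle controls

Spatial shuffling tiles the grid into contiguous rectangular blocks whose
shape is the divisor pair of the grid dimensions with channel count closest
to the requested subarea size (ties toward square), then permutes channel
assignments within each block independently per trial — exact tiling, no
remainder channels. The accuracy-versus-size curve is fit with
y = A·exp(−Bx) + C under A > 0, B > 0, C > 50 by bounded least squares with
5 seeded starts; fits with A below half a percentage point are flagged
"no decay". Note that exponential decay constants are weakly identified
from noisy curves: at 1% accuracy noise the median error of B is ~15–20%.
Trial shuffling permutes trials within stimulus independently per channel —
per-channel/per-stimulus marginals are preserved exactly, cross-channel
covariance is destroyed — applied either to training folds only (fresh
permutation per fold) or to the whole data set. Conditions are compared by
2 × 2 chi-squared tests on pooled correct counts, Bonferroni-corrected,
falling back to the continuity-corrected variant (flagged) on zero cells.

## Maps, phase, embeddings

d′ maps use the split-half design: odd trials (session order) choose each
channel's preferred category, even trials give
d′ = (μ_pref − μ_rest)/√((σ²_pref + σ²_rest)/2) with all non-preferred
categories pooled as "rest" (the pooled-SD sensitivity index; an exactly
zero pooled variance raises rather than emitting ±∞). The early regime is
theta power in 100–200 ms, the late regime high-gamma power in 300–500 ms.
Channels failing the evoked-power screen (per-stimulus KS between
prestimulus and evoked power, Bonferroni over stimuli) are flagged and
excluded from selective-channel summaries. PLV is the resultant length of
channel-wise unit phase vectors divided by channel count (so it lies in
[0, 1]; the downstream statistics are rank-based, so the scaling is
inconsequential), taken from the 4-Hz Morlet coefficient at 75 ms
post-onset. Category comparisons use Mann–Whitney U (two groups) or
Kruskal–Wallis with Dunn's tie-corrected pairwise post-hoc and Bonferroni
correction (the post-hoc is implemented in-package). Cross-modality
selectivity correlations are Pearson correlations of trial-averaged
(channel × stimulus) responses, pooled into one vector by default with a
channel-wise averaging mode as an alternative. Embeddings use classical
(Torgerson) MDS — double-centered squared Euclidean distances,
eigendecomposition, sign convention fixing the largest-magnitude coordinate
of each axis positive.

## What the generator does and does not emulate

It emulates the statistical structure the analyses assume: scale-dependent
spatial summation, evoked/induced temporal structure, hierarchy-dependent
tuning-field smoothness, spike–gamma coupling, shared trial noise, and
category-dependent phase dispersion. It does not attempt biophysical
realism: no compartmental neurons or volume-conduction physics, white
rather than 1/f background noise, no recording artifacts, no line noise,
no electrode drift, no refractoriness, and stimuli exist only as labels.
Passing tests therefore demonstrate that the analysis code correctly
recovers known structure of this kind from data that contain it — not that
real cortical recordings contain such structure.

## Numerical and calibration notes

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; sessions are bit-identical per (config,
  seed), and the pipeline derives per-stage child seeds from one master
  seed so stages are individually reproducible.
- Chance calibration by label permutation shares one permutation between
  training and test folds, so chance overlap with the true categories
  induces a small positive bias (≈1–2 percentage points at the default
  312-trial session) on top of binomial noise; permutations are also
  mutually correlated, so the pooled count overstates the effective n.
  The calibration checks should be read with that in mind.
- Test-suite problem sizes: unit and acceptance tests run reduced stimulus
  sets (4 monkey faces/bodies/objects, 2 auxiliary exemplars each) with
  4–8 trials per stimulus, and the summation-dissociation check uses 20
  fixed seeds at 8 trials per stimulus — sizes chosen to make the checked
  orderings statistically resolvable at interactive runtimes.

## Known limitations

- The exemplar subsampling of the larger category uses a single seeded
  draw; level accuracies therefore carry draw-to-draw variance of a few
  percentage points at small exemplar counts.
- The decay-constant B of the spatial-shuffle fit is reported with its
  residuals, but no confidence interval; bootstrap the curve if one is
  needed.
- `spatial_shuffle` and `trial_shuffle` are O(trials × channels) Python
  loops — adequate for 60-channel sessions, not for thousand-channel
  arrays.
- The evoked-power significance gate is computed from band-power epochs,
  not raw spike responsiveness, when applied to field-potential maps; the
  two screens agree on the simulated data but are not interchangeable in
  principle.
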