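# Methods

`cvrconcord` implements a voxel-wise comparison of two fMRI-derived metrics
of cerebrovascular reactivity (CVR): the **breath-hold beta** (amplitude of
a fitted respiratory response in a block-design breath-hold run) and the
resting-state **ALFF** (amplitude of low-frequency fluctuations, used as a
CVR estimate, "CVRe"). Everything is exercised on synthetic BOLD phantoms
with known ground truth; this note records the models, the defaults, and
the design choices that were genuinely open.

## Breath-hold task model

The task is the standard block paradigm: a 4 s equilibration period, four
epochs of 40 s normal breathing / 4 s inhalation / 16 s breath-hold, and a
20 s rest tail — 264 s, 132 volumes at TR = 2 s. Preprocessing removes the
equilibration period plus the next 10 volumes and the final 20 volumes
(the last hold's response is not fully captured), leaving 100 volumes.
Resting runs are 302 volumes; preprocessing removes the 2 equilibration
volumes and keeps the first 210. Each voxel's series is scaled to mean
100 and clipped to [0, 200], so amplitudes are percent-of-baseline units.

## Respiratory response function and initial regressor

The generic respiratory response function is

    RRF(t) = 0.6 t^2.1 e^(−t/1.5) − 0.0023 t^3.54 e^(−t/4.25),   t in s,

a fast positive lobe followed by a slow, deep undershoot. The initial
regressor is the hold-phase indicator convolved with the RRF sampled at
t = 0, TR, 2·TR, … over a 60 s support (long enough for both lobes).
Because the undershoot integrates over the 16 s hold blocks, the convolved
regressor's negative excursion dominates its positive one; the phantom
therefore normalizes the regressor by its maximum *absolute* value, so the
simulated `cvr_amplitude` is the peak response excursion in percent of
baseline.

## Personal waveform estimation

Subjects differ in the latency and shape of their breath-hold response, so
the regressor actually fitted per voxel is estimated from the data:

1. **Selection.** Every VOI voxel is scored by its maximum Pearson
   correlation with the initial regressor over integer delays 0–4 TR
   (positive correlations only; constant voxels are ineligible). The top
   1% (`ceil(pct × n_eligible)`, deterministic ties) are retained.
2. **Alignment.** Per-voxel response delays differ by whole TRs, but the
   delay of the *subject's* response relative to the generic template is
   generally fractional. Integer alignment therefore produces templates
   that are half-sample mixtures. The estimator instead measures
   continuous delays (parabolic interpolation of the cross-correlation
   peak over ±4 TR), aligns each selected series at sub-sample precision
   (linear interpolation, edge replication), and averages — first against
   the strongest selected voxel, then refined against the resulting
   template.
3. **Anchoring.** The template is shifted so that the *earliest* clearly
   responding cohort of the whole VOI (voxels with peak correlation
   ≥ 0.6; cohort located at the 5th percentile of continuous delays and
   summarized by its median, so isolated falsely-early voxels cannot
   shift the waveform) sits at delay 0. The subsequent lag scan then
   reads out each voxel's delay relative to the subject's own earliest
   response. A genuinely early cohort smaller than ~5% of responders
   would be missed, biasing all lags one TR low — a known limitation.
4. **Smoothing.** The averaged series is smoothed with a three-point
   order statistic filter, `y_t = 0.70·median + 0.15·max + 0.15·min` of
   `(x_{t−1}, x_t, x_{t+1})`, edges replicated. The weights sum to 1 so a
   constant signal keeps its scale; a legacy variant with weights
   (0.70, 1.15, 0.15) — which doubles a constant signal — is available as
   `PRINTED_SMOOTHER` for reproduction purposes but is not the default.

Sub-sample arithmetic is internal to waveform estimation only; reported
lags are integer multiples of TR.

## Breath-hold CVR metric

For each VOI voxel and each delay lag ∈ {0,…,4} TR the model
`y[lag:] = intercept + beta · waveform[:T−lag]` is fitted by least squares
on the overlapping samples (the waveform is delayed, its overhang
dropped — no pre-task signal is fabricated). The lag maximizing R² wins,
ties toward the smallest lag, and its beta is the voxel's metric. With
two runs, betas are averaged voxel-wise and the averaged map's lag is the
one maximizing the *sum* of the two runs' R² — pooling fit quality across
runs resolves near-ties that independent per-run choices would split.

## Resting-state CVRe metric

ALFF of a series is the sum of single-sided DFT amplitudes `2|X_k|/N`
over bins with 0.01 ≤ f ≤ 0.08 Hz (inclusive edges; rectangular window,
amplitude sum rather than squared power — the classic estimator). The
series is mean-removed and, by default, linearly detrended first: slow
drift would otherwise leak into the 0.01 Hz bin. Detrending itself leaks
a small broadband residue into the band (a pure in-band sinusoid returns
its amplitude exactly only with `detrend=False`), which is irrelevant for
map contrast but matters for analytic checks. Two runs are combined as
the per-voxel mean of their ALFF maps; single-run mode exists for the
split-run analyses.

## Classification and threshold optimization

A voxel is *responsive* when its metric is ≥ the threshold (one-sided:
vasodilation is modeled as a positive response; metric = θ counts as
responsive). Agreement with a reference labeling is summarized as
TP/TN/FP/FN with accuracy (TP+TN)/total and Dice 2TP/(2TP+FP+FN).

- **1D sweep vs gray matter** (GWM-VOI, reference = gray labels): the
  default grid is the 0th–100th percentiles of the metric in the VOI in
  101 steps, which adapts to any data scaling; explicit grids are
  accepted. The accuracy argmax is returned, ties toward the smallest
  (most inclusive) threshold. On instances up to ~10⁴ voxels the grid
  argmax matches an exhaustive search over all distinct values within
  one grid step.
- **2D cross-metric surface** (GM-VOI, resting as predictor of
  breath-hold): accuracy and Dice matrices over all threshold pairs,
  computed by a single boolean matrix product. Extreme threshold pairs
  force all voxels into one cell, pinning the surface corners at
  accuracy exactly 1 (all-TN, all-TP) or 0 (all-FP, all-FN); the saddle
  value is the accuracy at the pair of independently optimized 1D
  thresholds.
- **Split-run self-concordance**: each run's map is thresholded at its
  own 1D-optimal (vs gray) threshold, then run 1 is cross-classified
  against run 2, by default within cortical gray matter.
- **Unthresholded comparison**: each map's 1st–99th percentile range
  over the GM-VOI is mapped to [0, 1] (clipped), Pearson r is computed
  across voxels, the difference map is normalized resting − breath-hold,
  and scatter data are clipped to the central 95% of voxels.

## The phantom

Geometry is a connected gray-matter ellipsoidal shell around a white-matter
core inside an excluded background — the analysis needs labeled
compartments, not anatomy. Defaults (chosen once as the study
conditions): 32³ grid, TR 2 s, gray fraction 0.55 of the gray+white
volume, baseline 100, gray CVR amplitude 2.0 (i.e., a 2% peak response)
with 10% voxel-to-voxel variability, white CVR amplitude 0 (responsiveness
confined to gray matter; a finite gray:white contrast is configurable, and
voxels with any positive amplitude then count as responsive), per-voxel
response lags uniform on {0,…,4} TR, ALFF amplitude 2.0 in gray and 2.5×
lower in white, white Gaussian noise with SD 0.4 = 20% of the CVR
amplitude (a separate resting-run noise level and an optional spherical
zero-CVR lesion emulating neurovascular uncoupling are available), and
per-subject RRF constants jittered ±20%. `metric_coupling` correlates the
gray-matter CVR and ALFF truth variability (default 0 = independent).

The resting fluctuation is band-limited (0.01–0.08 Hz) Gaussian noise
normalized so its in-band amplitude sum is 1 per unit of truth amplitude.
All randomness descends from a single seed through independent
substreams: identical specs give bit-identical subjects, and the two runs
of each task carry independent noise.

What the phantom does *not* emulate — and hence what passing tests do not
establish about real data: head motion and its artifacts, spatial noise
autocorrelation and physiological (cardiac/respiratory) noise structure,
anatomical tissue geometry and partial-volume effects, EPI distortion,
and scanner drift beyond a linear trend. Recovery rates measured here are
upper bounds for real acquisitions.

## Reporting

The per-subject report mirrors the conventional table layout: TP/TN/FP/FN
and accuracy as integer percent, Dice to one decimal, with full-precision
values in a JSON summary alongside sweeps, the surface, corner values,
concordance, and the configuration hash (sha256 of the canonical config)
recorded in every output. Multi-subject tables gain an "Ave ± SD" row
(mean and sample SD to one decimal). Report bundles are byte-reproducible
for a fixed seed and configuration.

## Problem sizes

Tests run phantoms of 16³–20³ voxels (~1–2 s per full pipeline);
the acceptance script uses the default 32³ grid (~10⁴ gray+white voxels,
a few seconds end to end). These sizes were chosen so the whole suite
iterates quickly while every VOI is large enough for the 1%-selection and
percentile-grid machinery to behave as at realistic scale.

## Known limitations

- The earliest-cohort anchor assumes ≥ ~5% of responsive voxels share the
  earliest delay; rarer early cohorts bias all lags one TR late.
- ALFF amplitude calibration is exact for the untruncated series; the
  210-volume truncation changes bin spacing, so recovered CVRe tracks the
  truth amplitude proportionally rather than identically.
- With `cvr_contrast=None` white matter carries no true response, so
  breath-hold false positives arise only from noise — real white matter
  shows weak but genuine reactivity.
- The worked-example tables are percentages rounded to integers;
  quantities recomputed from them inherit that rounding (Dice to ~±0.1,
  the cross-metric mean accuracy to ~±0.1).
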