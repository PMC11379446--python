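# Methods

This note documents the models, conventions and numerical choices behind
`emgspace`, and what the synthetic validation does and does not show.

## Coordinate frame and grid model

The electrode grid is a row×column lattice with physical coordinates
`ft = col · ied_ft`, `fp = row · ied_fp` in mm (FT = fiber-transverse,
FP = fiber-parallel). Row 0 is taken as the cranial end and column 0 as
the medial edge; since no anatomical registration is performed, this is
a labelling convention — every metric is invariant to translating the
frame, and the resultant metrics to rotating it. The reference montage
fuses two 13×5 grids into a single 26×5 matrix processed as one; the
missing orientation electrode of each constituent grid defaults to
(row 0, col 4) and (row 13, col 4) and is overridable in the sidecar.
Missing and bad electrodes are *undefined* map cells (NaN), never zeros:
they carry neither weight nor coordinates in any centroid.

## Conditioning

All filters are Butterworth, order 3, applied forward–backward
(`sosfiltfilt`), because group delay would shift centroid timing between
the torque and EMG streams; the effective order therefore doubles and
the effective attenuation is the squared magnitude response. The notch
is a 2nd-order IIR at 50 Hz with Q = 30. Zero-phase filtering is exactly
time-reversal symmetric only away from the record edges; the analysis
region excludes the edges by construction (quasi-zero windows), so edge
transients never enter a segment.

Bad-channel screening: when a quasi-zero reference exists (torque below
10 % MVT before the ramp), per-channel SNR = 20·log10(RMS_hold /
RMS_reference) and channels under `snr_floor_db` (default 3 dB) are
dropped; otherwise a robust fallback flags channel RMS beyond
5 scaled-MAD above the grid median or below 0.2× the median. Flagging
more than 20 % of the grid emits a warning rather than failing: with a
focal source on a long grid, genuinely noise-dominated far channels are
expected and their exclusion does not move the thresholded centroid.

## Segmentation and endurance

Transient marks are placed automatically at the crossings of 50 % MVT
(first on the ascent, last above it before sustained failure on the
descent); manually supplied marks take precedence. This automates what
is otherwise a manual annotation step; the 50 %-MVT level was chosen so
that the descending mark coincides with the task-failure definition.
Quasi-zero windows are mark ± 2 s (4 s total); the analysis region is
the open interval between them. T1 starts at the region start, T3 ends
at the region end, T2 is centered at the midpoint; each segment is 10 s.
Regions shorter than 30 s produce overlapping segments with a warning;
shorter than 10 s is an error. Endurance time runs from hold onset
(first sample at ≥ 99 % of the target level) to the first instant
opening a ≥ 3 s run below 50 % MVT; brief dips recover, and a record
that never fails is reported censored at end of record.

Segment statistics use half-open intervals `[start, end)` on the frame
timebase so adjacent segments never share a frame, and the population
(1/N) standard deviation throughout — these are descriptive statistics
over fixed windows, not inferential estimates.

## Features

The RMS envelope is `sqrt(moving average of x²)` with a centered 500 ms
window truncated at the record edges, sampled at the 10 Hz map rate
(both configurable). The AIF is realised as the power-weighted mean
frequency (spectral centroid) of non-overlapping 500 ms Hann periodogram
frames restricted to 20–450 Hz; at this frame length the centroid is the
conventional stationary surrogate for instantaneous-frequency tracking
(an analytic-signal estimate was considered and not adopted — at 0.5 s
resolution the two agree for band-limited signals while the centroid is
far cheaper and has no unwrapping pathologies). Frames with no in-band
power are undefined. Grid-level AIF averages frames within a channel
first, then across good channels; the order matters only when channels
have unequal defined-frame counts, and it is fixed and documented rather
than configurable.

## Topography and centroids

The RoA of a map is the amplitude-weighted centroid of the cells at or
above 70 % of the map maximum (ties included, so boundary handling is
deterministic); the maximum is taken over the whole fused grid, giving a
single activation region. The CoG is the same centroid with threshold 0.
For an all-zero map the active set carries no weight and the unweighted
centroid of the defined cells is returned. Interpolation of bad channels
(4-neighbour mean) exists for visualisation only and is never used in
centroid extraction.

## Spatial metric suite

The suite transplants the classical center-of-pressure posturography
statistics onto the per-segment RoA trajectory: MDIST→AID, TOTEX→AIP,
MVELO→AIV, RDIST→AIS, AREA-CE→AEZ, AREA-CC→ACZ, AREA-SW→AMZ. Formulas
are centralised in `spatial_metrics` and config-exposed so alternates
can be swapped.

Two deliberate choices:

* **AID reference.** The AID family measures displacement from the
  *initial position*: the reference is the mean RoA over the first
  second of the analysis region (`reference_policy="baseline"`,
  `baseline_s=1.0`). The strict posturographic convention (per-segment
  mean) is available as `reference_policy="window_mean"`. With the
  baseline policy AID grows as the center migrates; with the window-mean
  policy it reduces to within-segment scatter. Spread and area metrics
  are always mean-centered within the segment, per the CoP convention.
* **Resultant AID.** The resultant is the mean Euclidean deviation
  (1/N) Σ √(x²+y²), not √(AID_FT²+AID_FP²); the components are reported
  alongside so either reading can be reconstructed.

AEZ uses the population covariance of the mean-centered samples and the
F(1−α; 2, N−2) quantile: the ellipse `dᵀS⁻¹d ≤ 2F` has area
2πF√det S and contains ≈ 95 % of bivariate-normal samples. ACZ uses the
one-sided normal quantile z = 1.645 on the resultant distances; for an
isotropic Gaussian its nominal containment is ≈ 93.5 % (a known property
of the confidence-circle construction, inside the 93–97 % acceptance
band). AIV and AMZ are normalised by the nominal segment duration when
computed per segment (so AIV·T = AIP exactly), or by the spanned frame
time when called standalone.

Missing trajectory frames are dropped, not interpolated, before
differencing — interpolation inflates path length across gaps; a gap
longer than 1 s invalidates the segment's path metrics (AIP, AIV, AMZ)
with a warning. Maxima across T1–T3 are taken per variable (element-wise)
and feed the endurance regression; window-level maxima were considered
and rejected as more sensitive to single-frame outliers.

## Statistics

Two-sided tests throughout. Friedman χ² uses mid-ranks with the standard
tie correction; Kendall's W = χ²/(N(k−1)) with Cohen bands small < 0.3,
moderate < 0.5, large ≥ 0.5. For tie-free tables with k ≤ 4 an exact
permutation p is computed by dynamic programming over the column
rank-sum distribution (equivalent to enumerating all (k!)^N rankings but
polynomial); the χ² approximation tracks the exact p to ≈ 0.01–0.02 in
the rejection region (p ≲ 0.1) while being conservative in the far upper
tail, which is why the exact value is reported alongside. Wilcoxon
signed-rank post-hocs run only when Friedman clears the gate (α = 0.05
by default, configurable), drop zero differences, use the exact
signed-rank distribution for n ≤ 25 without ties, and are
Bonferroni-adjusted by the fixed factor 3 (the three T1/T2/T3 pairs),
capped at 1. Under a 2000-replicate null simulation the family type-I
error of the gated pipeline is ≈ 0.03. The endurance regression is
per-metric simple OLS with R² and the slope t/F-test p.

## Synthetic data generator

Each channel records `spatial gain × carrier × amplitude + noise`:

* **Spatial gain**: a 2-D Gaussian kernel (σ_FT, σ_FP in mm) centered on
  a piecewise-linear path — the ground truth the tracker must recover.
  Defaults σ_FT = 12, σ_FP = 40 mm roughly match a focal source on the
  200×32 mm montage.
* **Carrier**: per-channel independent Gaussian noise band-limited to
  20–450 Hz whose power spectrum is re-tilted every second so its
  centroid declines linearly (`f_med0` = 260 Hz, slope ≈ −0.28 Hz/s →
  ≈ 25 Hz over a 90 s contraction). A linear spectral tilt is the
  simplest spectrum with a controllable centroid; it is *not* a
  physiological motor-unit spectrum, and is sufficient exactly because
  the AIF claim being exercised is a monotone decline.
* **Amplitude**: multiplicative growth (1 + 0.005·t) on top of an
  activation profile that is silent at rest and ramps with the torque —
  so quasi-zero windows genuinely contain near-zero myoelectric
  activity, giving the SNR screen a real reference.
* **Noise**: independent white floor per channel (≈ −34 dB relative to
  the kernel peak by default); optional common-mode 50 Hz hum to
  exercise the notch.
* **Torque**: linear ramp to 60 % MVT over 2 s after a 2 s rest, a hold
  with multiplicative low-pass (< 5 Hz) noise whose CoV rises linearly
  from 1 %, then a noiseless linear decline crossing 50 % MVT exactly at
  the configured failure time and staying below it — so endurance
  recovery can be verified to the sample.

What the simulator does **not** emulate: motor-unit recruitment and
firing statistics, volume conduction and electrode-skin impedance,
inter-channel correlation of the myoelectric carrier, non-stationary
artifacts (movement, ECG), or torque–EMG coupling beyond the activation
ramp. Passing the recovery tests therefore demonstrates that the
*estimators* are correct and well-conditioned at realistic SNR, not that
the physiological effect sizes of real muscle are reproduced.

## Problem sizes and numerical notes

The default generator conditions are fs = 2048 Hz, a 26×5 grid and a
≈ 90 s contraction. The test suite and the acceptance script run
scaled-down instances — fs = 1024 Hz, 13×5 or 16×5 grids, ≈ 40 s holds
(region ≈ 34 s, still three non-overlapping 10 s segments) — chosen so
the whole validation runs in minutes while every estimator operates in
the same regime (hundreds of frames per segment, 64–128 channels'
worth of geometry is not needed for any centroid property).

Known quantitative behaviours, measured by the validation itself:

* RoA frame-to-frame jitter at the default SNR is well under 0.5 IED;
  displacement recovery of a 20 mm drift is accurate to ≈ 0.5 mm.
* The zero-phase band-pass attenuates the band edges (|H|⁴ power
  weighting after forward–backward filtering), which compresses
  spectral-centroid excursions by ≈ 9 %: an injected 25 Hz AIF decline
  is measured as ≈ 22.8 Hz. This is a property of the analysis chain,
  inside the 10 % recovery tolerance, and common-mode offsets cancel in
  the T1−T3 difference.
* Path-length metrics (AIP) are noise-floored: centroid jitter
  contributes a baseline path per segment, so AIP differences, not
  absolute values, carry the drift signal — mirroring how sway path
  lengths behave in posturography.
* CSV outputs are written with 9 significant digits and a configuration
  hash; identical seeds reproduce byte-identical artifacts.

## Limitations

Single-peak activation is assumed (one RoA per map; multi-peak splitting
is out of scope). The AIF is a grid-average status indicator and is not
meant to localise regional spectral change. The confidence-region
coverages are exact only under approximate bivariate normality of the
within-segment trajectory scatter; for strongly drifting segments AEZ
inflates with the drift, which is intended (it is a dispersion measure,
not a stationary-error estimate). The statistics module implements the
non-parametric route only (no repeated-measures ANOVA or mixed models).
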