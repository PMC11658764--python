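# Methods

This note documents the models and estimators implemented in `nanocal`,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical edge cases.

## Calibration and conventions

Images are T×C×Y×X stacks with a physical pixel size (µm) and frame
interval (s). Pixel indexing is 0-based (row, col); the physical
coordinate of a pixel center is `index × pixel_size_um` with x = col,
y = row. Time windows are half-open `[start, end)` seconds so each frame
belongs to exactly one window; the default summary windows are minutes
0–1, 5–6 and 9–10 of a 10-minute recording. Defaults assume 0.284 µm/px
and a 0.44 s or 2 s frame interval — the acquisition settings of the
confocal experiments the pipeline was built around. All outputs are tidy
CSV, one row per (cell, frame-or-window); missing values propagate as
empty cells, never as zeros.

## Nanocluster segmentation

The integrin channel is thresholded automatically (Otsu by default,
computed per frame; the method and per-frame/per-movie scope are
configurable because the choice is not canonical). The mask is pixels
strictly above threshold; a constant frame yields an empty mask with a
warning rather than an exception, so movie loops never abort. Connected
components use 8-connectivity; a component is a nanocluster iff
`pixel_count × pixel_size² ≥ min_cluster_area_um2` (default 0.15 µm²,
i.e. a 2-pixel minimum at 0.284 µm/px). Centroids are unweighted means of
pixel centers — clusters are treated as ROI locations, not
intensity-weighted emitters. Clusters are segmented independently per
frame; there is no inter-frame tracking, because every downstream summary
averages per time window rather than per cluster lifetime.

The cell mask comes from the cytosolic reporter channel: automatic
threshold, keep the largest connected component, fill holes. The
"cluster-negative" compartment is the set difference cell AND NOT
cluster; together with (cluster AND cell) it partitions the cell mask
exactly, which makes the area-weighted recombination of compartment MFIs
equal the whole-cell MFI to machine precision (tested).

"Intensity normalized to the mask area" is implemented as mean intensity
per pixel (sum/area). This is the only reading that keeps cells of
different sizes comparable; any alternative differs only by the constant
pixel_size².

## Ripley's K and the aggregation index

For a pattern of N nanocluster centroids, K(r) = N⁻¹ ΣᵢΣⱼ≠ᵢ 1[dist ≤ r]
with Euclidean distance, ordered pairs (each unordered pair counts
twice) and an inclusive boundary. N is literally the number of points —
no area or N(N−1) factor — so K(r) is the mean neighbour count within r.
Patterns with fewer than two points have K ≡ 0. A classical
variance-stabilized K is deliberately not the default; the envelope
normalization below makes curves comparable across cells without it.

No analytic edge correction is applied. Instead, a Monte-Carlo envelope
is built per cell: `n_envelope_sims` (default 100) patterns of the same
number of points are drawn uniformly from the cell mask's pixel centers —
the same grid observed centroids are quantized to — and the pointwise
min/max of their K(r) curves form the lower/upper bounds. Because the
envelope lives on the same support as the data, boundary effects cancel
by construction. K is then rescaled affinely per radius:

    normalized = 2·(K − lower)/(upper − lower) − 1,

so the upper bound maps to exactly +1 and the lower bound to −1. Values
above 1 are classified aggregated, below −1 dispersed, and anything in
[−1, 1] (boundaries included) is indistinguishable from randomness. A
degenerate radius (upper == lower) maps to 0 when K equals the common
value, otherwise to a flagged sentinel ±(1+ε). The radii grid defaults
to 0.5–5.5 µm in 0.5 µm steps (the step is configurable; only the range
is canonical).

The aggregation index summarizes many (cell, timepoint) curves: patterns
with fewer than 10 points are excluded, each remaining curve contributes
the count of radii with normalized value > 1, and the index is the mean
count. With min/max envelopes over 100 simulations, a random pattern
exceeds the envelope at a given radius with probability ≈ 1/101, so CSR
cohorts score near 0 while genuinely aggregated cohorts score well above.

## Calcium flicker detection

Per-cell traces are the mean Ca²⁺-channel intensity within the cell mask
at each frame. Detection works on the z-score of the trace against a
robust local baseline:

* baseline: running median, 180 s window. The window must be long
  against the widest transient of interest (≈ 30 s FWHM); a median over
  ≥ 3× the event support leaves event amplitudes unbiased, which the
  half-width recovery tests verify across FWHM 2–30 s.
* noise scale: 1.4826 × MAD of the detrended trace, falling back to the
  standard deviation when the MAD degenerates to zero on (near-)noiseless
  traces. A trace with zero spread yields no events, not a division
  error.
* candidate events: maximal runs of at least 3 samples with z ≥ 1.5
  containing at least one sample with z ≥ `z_threshold` (default 3;
  one-sided normal tail 0.0013 < 0.01). The run-length and extension
  thresholds suppress isolated noise crossings, which the bare z-gate
  admits at ~0.4 per 600 s trace; with them, false detections stay below
  0.1 per trace while 10σ transients are recovered with recall ≥ 0.95.
  These two constants are package choices — the analysis tradition this
  follows defers them to an external pipeline's unpublished defaults —
  and both are exposed as arguments.
* boundaries are extended outward to the baseline crossings (z ≤ 0), so
  the reported amplitude, FWHM (linear interpolation at half amplitude)
  and AUC (trapezoidal, baseline-subtracted) describe the full transient.

Superimposed events are merged through a graph whose nodes are events
and whose edges join events with overlapping closed [onset, offset]
intervals; connected components become groups, and frequency summaries
(flickers·min⁻¹ = groups / minutes) count groups, not raw detections.
Grouping is idempotent. Whether a per-minute flicker count should use
raw detections or merged groups is ambiguous in the tradition this
implements; merged groups is the implemented reading, since the graph
exists precisely to identify superimposed detections.

## Shape metrics

Area is `pixel_count × pixel_size²`. The perimeter is the length of the
pixel-edge ("crack") boundary polygon after Douglas–Peucker
simplification with tolerance 1.2 px. The two-step estimator is chosen
over the common alternatives because it is exact for axis-aligned
shapes and nearly unbiased for smooth ones: straight edges and their
corners are polygon vertices with zero deviation, so an n×n square
measures exactly 4n (circularity exactly π/4), while the one-pixel
staircase of a curved boundary collapses onto chords, removing the raw
crack length's systematic overestimate (up to 4/π ≈ 27% for a disk —
rasterized disks of radius ≥ 20 px measure within 5% of 2πR). A
marching-squares contour was considered and rejected: its corner-cutting
biases the square closed form by ~3% and it still overestimates disk
perimeters by ~6%. Circularity is 4π·area/perimeter²; solidity is
area / convex-hull area with the hull computed on the pixel grid.
Disconnected masks are reduced to the largest component with a warning;
empty masks are an error.

## Kinetic trace metrics

For a ratio trace (e.g. Ca²⁺-bound/unbound emission), the baseline is
the mean over [0, 30) s; the peak is searched only after the baseline
window, so pre-stimulus noise cannot win; the half-life time is the
first post-peak time at which the trace falls to baseline + amplitude/2
(linear interpolation); the AUC integrates (trace − baseline) from the
peak to the half-life time. The AUC is invariant under constant shifts
of the whole trace, while the peak ratio is not (both tested). A trace
that never decays to half amplitude reports the AUC up to the trace end
with an explicit flag.

## Synthetic data: what it emulates, and what it does not

The generator produces single-cell crops (default 128 px at 0.284 µm/px,
i.e. a 36 µm field holding a spread cell of ~7 µm radius; full-chip
512×512 frames scale identically) over 10 minutes at a 2 s interval.
Cell outlines are disks modulated by low-order Fourier modes
(`irregularity` 0–1). Nanocluster positions follow one of three point
processes on the mask:

* **csr** — uniform over mask pixel centers, Poisson count;
* **clustered** — Thomas-type parent/offspring: parents uniform
  (`parent_intensity` per µm²), offspring displaced by an isotropic
  Gaussian (`offspring_sd_um`), resampled until inside the mask;
* **dispersed** — sequential inhibition with a hard minimum distance.

An optional object-level hard core (`hard_core_um`, off by default)
thins points closer than one nanocluster diameter; the movie renderer
uses it (1.0 µm) because two sub-resolution locations closer than the
optical spot size would segment as a single cluster anyway. With the
hard core off, realized counts are exactly Poisson-calibrated (tested
against binomial sampling error over 200 seeds).

Spots are rendered as isotropic Gaussians (σ 0.25 µm ≈ the confocal
PSF; a thresholded spot then covers ≥ 2 px, surviving the size gate)
over a constant background with additive Gaussian noise clipped at
zero. The calcium channel is a flat cytosolic baseline, scaled by the
enrichment factor within a 0.5 µm footprint of each nanocluster, plus
cell-wide transients; transient waveform is a Gaussian-in-time bump
whose FWHM is the controlled property (the analysis reports FWHM, so
the waveform's exact shape is immaterial). 1-D traces are baseline +
pulses + Gaussian noise.

The demo cohorts instantiate "WT-like" (clustered, parent intensity
0.04 µm⁻², offspring sd 0.8 µm, hard core 1.0 µm, Poisson mean 100
pre-thinning → ~20 resolvable clusters per frame; 2× Ca²⁺ enrichment;
F-actin level 40) versus "KO-like" (CSR, Poisson mean 15 → ~12 clusters;
no enrichment; F-actin 25). Published imaging of this system reports no
numeric cluster counts, so these are plausible settings chosen once for
a clear, stable contrast, not measured values.

Not emulated: realistic PSF tails, Poisson shot noise, photobleaching,
cell motility and deformation over time, cluster birth/death, and 3-D
effects. Passing tests therefore demonstrate the correctness of the
estimators under the stated noise model, not robustness to every
artifact of real microscopy.

Every stochastic call takes an explicit seed (no global state); the
pipeline derives independent per-cell, per-stage streams from one root
seed via seed sequences, so full runs are byte-identical across reruns.

## Problem sizes

Default problem sizes (4 cells per cohort, 300-frame movies on 128 px
crops, 100 envelope simulations, 50-seed recovery suites) were chosen so
the full test suite and the demo each complete in well under a minute on
a laptop core while keeping all statistical margins comfortable.

## Known limitations

* The envelope min/max over 100 simulations is a conservative test;
  weakly aggregated patterns (or few points) often score 0. This matches
  the per-experiment normalization it implements, but cohort-level
  contrasts are the intended use.
* Touching nanoclusters are not split (no watershed); dense scenes
  undercount clusters and bias centroids toward patch centers.
* The flicker detector's baseline/noise constants are robust defaults,
  not fits to any particular indicator's kinetics.
* Tracks, chemotaxis indices and group-level inferential statistics are
  out of scope; the CSV outputs are designed to feed standard stats
  packages directly.
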