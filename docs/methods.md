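# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each sporetrack module.

## Single-particle mobility model

Enzymes acting on the peptidoglycan (PG) sacculus are orders of magnitude
smaller than their substrate: under the microscope the sacculus is
effectively stationary while unbound enzymes diffuse. Binding therefore
shows up as a loss of particle mobility, and sptPALM of
PAmCherry-tagged enzymes gives a per-molecule readout of PG engagement.
The package models a tracked particle as being in one of two states:

* **immobile (bound)** — a fixed position observed with isotropic
  Gaussian localization noise (default sd 15 nm per axis, a typical PALM
  localization precision);
* **mobile (free)** — 2D Brownian motion with per-frame Gaussian
  increments of variance 2 D Δt per axis.

State switching within a track is not simulated, but the classifier is
designed so that mixed-behaviour tracks are called mobile (see below).

### Immobile classification

A trajectory is immobile iff both its x and y bounding-box spans over the
classification window are strictly below one pixel (0.16 μm). The window
is the first min(duration, 1.2 s) of the track, anchored at the track
start; anchoring is a deterministic choice where a sliding window would
also have been defensible, and it is recorded in the output metadata.
Tracks shorter than 0.4 s (fewer than 5 points at 10 Hz, i.e. 4
intervals) cannot be classified and are removed by `trajectory_filter`.
A free particle at the smallest studied D (1.8 × 10⁻² μm²/s) leaves a
160-nm box within ~1 s with high probability, so misclassification of
mobile tracks inflates the recovered immobile fraction by only ~1–3
percentage points at 12-frame track lengths; the simulation-recovery
tests quantify this.

### Diffusion estimation

Per-track time-averaged MSD with overlapping pairs,
msd(kΔt) = meanᵢ |r(i+k) − r(i)|², fitted on the first four lags.
The default fit is least squares **through the origin** (D = Σ msdₖ·lagₖ /
4Σ lagₖ²), matching the intercept-free law MSD = 4DΔt; static
localization noise adds a constant 4σ² to every lag and therefore biases
this estimator upward by σ²·Σlagₖ/Σlagₖ² (≈ 3.3 σ² at 10 Hz) — about
+0.3% of D at σ = 5 nm (fitted-spot precision in rendered movies) and
+3% at σ = 15 nm. The `free_intercept` mode absorbs the offset and
removes that bias at the price of higher variance; both behaviours are
asserted in the tests. Per-track estimates ≤ 0 (possible on short noisy
tracks in free-intercept mode) are retained in population means:
truncating them would bias the mean upward.

The population mean D is the mean of per-track estimates over mobile
tracks, each computed from the entire trajectory; an ensemble-MSD fit
would weight long tracks differently and is not the default. Bootstrap
uncertainty resamples trajectories (not localizations), 1,000 resamples
by default, with the seed recorded in the output.

### Population comparison

Two populations are compared by the difference of bootstrap replicate
vectors (mean D, and immobile percentage via resampled class labels),
reporting a two-sided percentile-bootstrap tail probability. The
significance threshold is read as p < 0.005; this interpretation is
flagged in the result because the convention could also be stated as a
difference magnitude, and the choice matters only at the margin.

## Synthetic data

The generator's defaults *are* the measurement conditions the analysis
assumes: 0.16 μm pixels, 10 Hz frames, 12-frame tracks, 15 nm
localization noise, immobile fractions and mobile D values set per
scenario preset (`MOBILITY_PRESETS`). Brownian steps are exact Gaussian
increments — no spatial discretization, exact for free diffusion at any
Δt. Track lengths are fixed by default (recovery benchmarks need
controlled lengths); a geometric-length mode driven by a per-frame
bleaching probability models irreversible photobleaching. Optional
confinement reflects steps at a rod/sphere/spherocylinder cell outline.

Movies are rendered with a symmetric Gaussian PSF **integrated over each
pixel** (default σ = 0.13 μm), Poisson shot noise on signal plus uniform
background, Gaussian read noise and a constant camera offset. The
localization fit uses the same pixel-integrated model, so noiseless
render→refit round trips recover centers to < 0.02 px.

What the generator does not emulate — and what passing tests therefore do
not demonstrate about real data: motion blur within exposures, fluorophore
blinking, out-of-focus light from 3D motion, heterogeneous backgrounds
inside cells, state switching within tracks, and cell movement (PG-related
enzymes move about two orders of magnitude faster than the cell itself,
justifying a static cell frame over these timescales).

## Localization, linking

Candidate spots are local maxima above median + SNR × (1.4826·MAD), with
non-maximum suppression over a square window (half-width 3 px). The
pixel-integrated symmetric Gaussian fit runs over a 7×7 window; fits are
rejected when σ leaves [0.5, 4] px, the center leaves the window, or the
optimizer fails — the σ gate implicitly discards the blurry background of
fast cytoplasmic fluorophores. Coordinate convention everywhere: origin
at the top-left frame corner, x along columns, pixel (i, j) center at
((j + 0.5)·px, (i + 0.5)·px).

Linking solves each consecutive frame pair as an optimal bipartite
assignment (scipy's Hungarian solver) on squared displacement with a hard
gate, maximizing the number of matches within the gate and then
minimizing total cost; a brute-force enumeration oracle verifies this on
small instances. Defaults: gate 0.4 μm (≈ 3.9 per-axis step sd at the
largest studied D, accepting > 99.9% of true steps), no gap closing
(PAmCherry bleaching is irreversible, so a missed frame ends the track).

## Morphometry

Length and width come from the medial axis with its Euclidean distance
map. The skeleton is pruned to pixels whose boundary distance is ≥ 0.75
of the object maximum — this removes the corner spurs a skeleton grows at
flat ends while keeping the full axis of constant-width rods. The cell
axis is the longest geodesic through the pruned skeleton (two Dijkstra
sweeps on the 8-connected pixel graph), measured as a polyline through
every 8th node to suppress the staircase inflation of discrete paths
(up to ~40% on straight axes otherwise). Length = geodesic + the
boundary radius at each end, so a spherocylinder of tip-to-tip length L
measures L. Width is solved from the pixel area A via the
spherocylinder relation A = (L − W)W + πW²/4 — exact for capped rods
*and* disks — rather than averaging the distance map along the axis,
which is quantised to ~±0.5 px and too coarse at realistic cell widths
(a 0.7 μm rod is 4.4 px wide at 0.16 μm/px). Near-circular objects whose
pruned axis is shorter than max(2 px, 0.75 × the summed end radii) fall
back to equivalent-ellipse major/minor axes.

Accuracy, validated against generator ground truth: disks L/W = 1 within
2%, 50×10 rectangles 5.0 within 5%, rendered spherocylinders with
L/W = 10 within 5%. A caveat: a thin rod aligned exactly with the pixel
grid at an unfavourable sub-pixel offset rasterizes to an integer width
(e.g. 4.375 px → 5 px), an irreducible ~10% width quantisation; any tilt
dithers the boundary and restores sub-pixel accuracy, and real cells are
arbitrarily oriented.

## Chromatogram quantification

Baseline: grey-scale opening (rolling minimum then maximum) with a 1-min
structuring element, which passes linear drift unchanged and removes
peaks much narrower than the window; the signal is pre-smoothed over
0.05 min so the minimum filter tracks the local mean, not the noise
floor. Peaks: prominence-gated local maxima of the subtracted signal;
boundaries extend to the valley shared with a neighbour or to 0.5% of
apex height (±3.25σ on a Gaussian, capturing 99.9% of its area);
overlapping peaks split at the valley, with no deconvolution. Areas are
trapezoidal integrals; species labels come from user-supplied
retention-time windows (identities are prior chemical knowledge, not
inferred here), with `Anh` in a label marking anhydro species. Relative
abundance = peak area / total area within the sample; total-PG
comparison divides each sample's total baseline-subtracted area by its
biomass normalization factor and reports ratios to a reference sample
across replicates. The default run window is 0–25 min.

## Numerical and degenerate-input choices

* Fixed seeds make every simulator bit-reproducible; all stochastic
  tests and the benchmark script derive their seeds explicitly.
* Flat fit windows, empty movies, blank images, flat chromatograms and
  zero-area peak tables return empty results or raise explicit errors,
  as exercised in the tests.
* Assignment ties in linking resolve deterministically through the
  Hungarian solver's ordering; ties have probability zero for
  continuous positions.
* The immobile-span comparison is strict (< one pixel), so a span of
  exactly 0.16 μm is mobile.

## Problem sizes

The recovery benchmarks use the study's population scales: 1,000 tracks
per diffusion scenario, 2,000 per immobile-fraction scenario, 1,000
bootstrap resamples. The end-to-end image-pipeline check renders 600
particles (12 frames each, staggered activation every 2 frames) in a
96×96-pixel field — about 1,200 frames — which bounds the mean-D
sampling error near 3% so the 10% end-to-end tolerance tests the
pipeline rather than sampling noise.
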