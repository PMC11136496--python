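# Methods

This note records the models, numerical choices and limitations behind each
module, and what the synthetic phantoms do and do not establish about real
data.

## Aortic-wall cartography (`ehtkit.unwrap`)

**Model.** The dorsal aorta is treated as a generalized cylinder whose axis
is the image x axis: each axial slice shows one closed wall cross-section
in the (z, y) plane. A ring contour per slice, sampled at arc-length steps,
defines a bijection between wall locations and a 2D map (X = axial
position, Y = arc length from the ventral reference line), so distances
along Y are true distances along the wall. Branching or strongly curved
vessels violate the one-ring-per-slice assumption and are out of scope.

**Ring refinement.** A discrete closed snake: radial rays from the current
center locate the wall-intensity peak inside a search band (default
±6 µm), with parabolic sub-step interpolation of the peak position; a
circular moving average (window 7 of 360 angles) regularizes curvature; the
center relaxes toward the contour centroid with damping 0.8. The first
slice runs 12 relaxation iterations from the user's circle; propagated
slices start at the previous ring and run 3. Rays whose peak stays below
10% of the slice maximum are marked invalid and bridged by periodic
interpolation; a slice with under 30% valid rays raises `NoRingFound`
(failure on the first slice aborts; later failures stop propagation with a
partial result and a warning). Centroid-based recentring is biased when the
center is far off (equal-angle sampling from an offset point weights the
near side), which is why the first slice gets the deep iteration budget;
phantom tests show sub-half-voxel center accuracy from 2 µm initial offset.

**Projection.** Per arc position the intensity is reduced over a radial
band of ±1.5 µm — maximum by default, because the junction reporter forms a
thin bright sheet and the maximum is insensitive to small ring-localization
error; mean is selectable. Whether the original analyses used a band
maximum or a single-contour sample is not stated in their description; both
are implemented and the default documented here. Columns are padded with
NaN to the longest perimeter so the cartography is rectangular. The arc
step defaults to min(pixel, z-step). A `valid_arc_fraction` mask is carried
because in real acquisitions only about two-thirds of the circumference
(floor-centred) is segmentable; phantoms default to 1.0.

**Perimeter.** Sum of contour segment lengths in physical µm. On analytic
rings the error is dominated by the polygonal-chord deficit, O(1/n²) at 360
angles (≈0.001%), and by the snake's smoothing; measured phantom error is
≈0.03%, well inside the 2% acceptance band.

## Morphometry and typing (`ehtkit.morphometry`)

**Descriptors.** The "best fitting ellipse" is realized as the equivalent
ellipse sharing the polygon's second central moments. These are computed in
closed form from the polygon vertices (Green's theorem), not by
rasterization: exact, resolution-free, and cheaper. Elongation is the
major/minor diameter ratio (≥1), orientation the major-axis angle to the
flow axis folded into [0, 180), and the length "in the longest axis" is the
polygon's extent projected onto the major-axis direction (for a 40 × 10
rectangle this gives 40, as intended, where the maximal caliper would give
the 41.2 diagonal).

**Paving refinement.** Seed polygons are rasterized as markers and expanded
by a marker-controlled watershed on the junction-intensity image (borders
are bright, so basins meet on the cell-boundary crests), restricted to the
seeds dilated by 4 µm. Ridge pixels grabbed as one-pixel strips by a single
basin are removed by a binary opening before contours are polygonized.
Seeds overlapping by more than 5% of the smaller area raise `PavingError`.
On phantoms with seeds eroded 1 µm from truth, every refined cell overlaps
its true polygon with Jaccard ≥ 0.9; residual error concentrates on the
narrow (≈6 µm) floor cells where the ~1 µm junction band is proportionally
widest.

**Neighbors.** Two cells are neighbors iff their boundaries share positive
length; vertex-only contact is excluded. Non-paving input degrades to an
overlap-based adjacency with a warning.

**Classification.** Region comes from the geometric center's arc angle:
floor = reference ± 60°, roof = opposite ± 60°, lateral = remainder (the
sector bounds are configurable; the source analyses give no numbers).
The rule cascade is: roof → endothelial; floor + inward bending → EHT pol+;
floor + outward-round + major length < 10 µm → EHT pol−; floor/lateral +
elongation ≥ 2.0 + thick nucleus → hemogenic; flat nucleus → endothelial;
else uncharacterized. Elongation threshold 2.0 and short-axis threshold
10 µm are configurable defaults — the original classification was done by
eye. The 3D shape flags (inward bending, outward roundness, nucleus
thickness) are **inputs** (from ledgers or manual annotation), never
inferred from the 2D outline; missing flags yield a low-confidence label.
Whole-segment summaries can optionally fold uncharacterized emerging cells
into the hemogenic count, as whole-aorta numerations do.

## FRAP kinetics (`ehtkit.frap`)

**Model.** Single-exponential recovery F(t) = A(1 − e^(−tτ)) fitted to the
fully-scaled signal I_fsn; A is the mobile fraction, T₁/₂ = ln 2/τ, and the
early slope is the OLS slope of I_fsn over [0, 30] s. No immobile-fraction
offset is fitted: the scaling forces F(0) = 0. Diffusion-geometry
corrections and multi-exponential models are out of scope.

**Normalization.** The minimum in the full-scale step is taken over
post-bleach samples only — prebleach noise must not set the scale floor.
The chain is exactly invariant to common positive scaling and common
offsets of ROI and background. Prebleach samples are carried unscaled and
excluded from fitting. A drift-flagged recording keeps only prebleach +
fast phases (early-recovery analysis only). Known limitation: with noisy
traces the empirical minimum is a biased floor estimate (the minimum of
~200 noisy samples near the floor sits ≈2σ below it), which inflates
fitted amplitudes by up to ~10–20% for slow recoveries at σ = 0.05. This
is a property of the published normalization chain itself; the
parameter-recovery study therefore adds noise on the scaled signal, which
isolates the fitter and leaves the chain's bias documented here rather
than silently absorbed.

**Fitting.** For fixed τ the model is linear in A, so A is profiled out in
closed form and the search is one-dimensional: a 40-point log-spaced τ scan
over [1e−5, 1] s⁻¹ followed by a bounded Brent polish of the profiled SSE
(variable projection). This replaces a 2-D multistart grid: it is
strictly more robust (the 1-D profiled objective is scanned globally) and
~25× faster. Bounds A ∈ [0, 1.5] (overshoot tolerated), τ ∈ [1e−5, 1] s⁻¹.
On noise-free model traces the estimates match the generating parameters to
solver tolerance (<1e−10).

**Accuracy at the design limit.** At the hardest studied grid point
(A = 0.3, τ = 0.005 s⁻¹, σ = 0.05, the 30/180/21-sample design) the
Fisher information gives a median |relative error| floor of ≈4.7% for Â —
single-trace amplitude estimates are intrinsically that uncertain because
the slow recovery leaves the plateau constrained only by the 21 slow-phase
samples. Aggregating by the median over 100 traces (as group analyses do)
recovers A within ≈1–2% everywhere on the grid.

## Spot spatial statistics (`ehtkit.spots`)

Distance is surface distance: the Euclidean distance transform of the
complement of the target-cell mask (0 inside a cell, boundary inclusive),
sampled at each spot's voxel — matching "distance from hemogenic/EHT
cells" rather than centroid-to-centroid. d50/d75 use the lower empirical
quantile (smallest observed distance reaching the fraction), with no
interpolation, so small-n results are exactly reproducible and equal a
sort-based oracle. Cumulative curves are evaluated on a common 0–50 µm
grid at 0.5 µm steps so per-segment curves can be averaged. Extra-aortic
spots are excluded by default, mirroring the manual curation to aortic
tissue. Spot detection itself is out of scope — spots arrive as
coordinates.

## Hematopoietic cell counting (`ehtkit.counter`)

**Transient removal.** Circulating cells outrun the acquisition and appear
in exactly one plane; non-moving cells span 15–20 z-sections. The rolling
median (window 20 ≈ one cell depth, centered, edge-truncated) is applied in
*replace* mode by default: the described subtraction of a rolling median
would remove the persistent component and keep the outliers, whereas the
stated goal is to remove them — replace matches the goal, subtract is
provided for fidelity, and this is the module's principal interpretation
risk. With an odd window the plane median is a single order statistic and
the filter is exactly idempotent on objects spanning ≥ the window; even
windows average the two central values and leave half-amplitude edge
planes.

**Segmentation.** White top-hat (spherical element, radius 6 px default),
global threshold (fixed or Otsu), then touching objects are split by a
watershed on the negated distance transform. Markers come from h-maxima of
the *smoothed top-hat intensity* (σ = 1 px, depth 5 intensity units —
scale-dependent, configurable) rather than of the distance transform:
deeply overlapping blobs whose distance saddle is shallow still seed
separately, while plateau tops do not oversplit. Objects under 50 voxels
are dropped. Intensities are always measured on the raw, unfiltered data;
background correction subtracts mean(background ROI) × voxel count.
Classification: green⁺red⁺ → hemogenic, green⁺red⁻ → HSPC, else other;
thresholds are manual per channel with an Otsu-based suggestion, and
raising a threshold can only shrink that channel's positive count.

## Statistics (`ehtkit.stats`)

The rank-sum test enumerates the exact null via the Gaussian-binomial
recurrence when both samples are tie-free and min(n) ≤ 8 (cutoff chosen
for auto-mode tractability; exact mode can be forced at any n). Otherwise
a normal approximation with midranks, tie-corrected variance, continuity
correction and an Edgeworth kurtosis term
(κ₄ = −n₁n₂(N+1)(n₁²+n₂²+n₁n₂+N)/120, exact for tie-free data) is used;
the two code paths agree within 1e−4 at n = 50 per group. Dixon's gate
uses the r10 ratio (gap/range of the most extreme value) with the
two-sided critical value 0.970 (n = 3, α = 0.05) behind an SD gate of 0.3
cycles, and removes at most one value. ΔΔCt assumes amplification
efficiency exactly 2 and normalizes to the mean control ΔCt per gene;
Pfaffl-type efficiency correction is out of scope.

## Synthetic phantoms (`ehtkit.synthetic`)

All generators draw from one `numpy` Generator seeded by the config, so
identical configs give bit-identical outputs, and every phantom's ledger is
a sufficient statistic for downstream scoring.

**Tube phantom.** Geometry follows the study's acquisitions: 0.27 µm xy
pixels, 0.3 µm z-steps, segments up to 330 µm; the default 25 µm radius is
a typical embryonic dorsal-aorta value (configurable — the radius is
inferred anatomy, not a reported constant). The wall is a Gaussian shell
(σ = 0.5 µm); cells tessellate the unrolled wall as rows of rectangles:
floor rows (±60° of the ventral line) hold narrow, axially elongated
hemogenic-type cells, other rows wider endothelial cells, with cell
lengths jittered ±15%. This row tessellation was chosen over centroidal
Voronoi relaxation because it gives analytic ground-truth morphometrics
(exact rectangles with known elongation and orientation) and a seam-free
paving; the price is that cell shapes are more regular than real
segmentations. Noise is additive Gaussian clipped at zero (Poisson mode
optional); optics are limited to the shell profile — no PSF convolution,
flow physics or bleaching chemistry. Passing phantom tests therefore
demonstrates geometric and statistical correctness of the pipeline, not
robustness to real-microscope artifacts (depth-dependent attenuation,
anisotropic PSF, motion).

**FRAP traces.** The generator inverts the fitted model: post-bleach
normalized intensity floor + (1 − floor)·A(1 − e^(−tτ)) plus noise, raw
traces add background and scale by the prebleach level (default 100, noise
given as a fraction of it). The default bleach floor is 0 (complete
bleach), under which the chain recovers A exactly on noise-free traces. A
variant (`make_scaled_recovery_traces`) adds noise directly on the scaled
signal for estimator studies (see the FRAP section).

**Spot scenes.** Voxel size 1 µm; the aorta is a cylinder, roof cells on
the dorsal inner wall, hemogenic/EHT cells on the floor, sub-aortic cells
below; spots are drawn uniformly in the aorta or with acceptance weight
e^(−d/scale) around hemogenic cells (default scale 3 µm), with a
configurable extra-aortic fraction (default 0.2).

**Flow time-lapse.** Persistent objects are flat-z Gaussian disks
(σ = 2 µm) spanning 15–20 planes; transients span exactly 1. Objects sit
on a jittered grid so ledger scoring is unambiguous; default stack
48 × 120 × 120 at SNR amplitude/noise = 10 for counting studies.

**Ct tables.** Technical triplicates around a reference Ct of 15, gene ΔCt
of 5, treated shifted by −log₂(fold); injected outliers add +5 cycles to
one replicate of randomly chosen triplicates and are marked in the table.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: a 3 × 3 (A, τ) grid
with 100 traces per point for FRAP recovery; 1,000 traces for the
normalization-invariance sweep; a 25 µm-radius tube with the axial length
reduced 4× (82.5 µm, 306 slices) for the unwrap round trip; 100 random
15-cell Voronoi pavings for the neighbor oracle; 1,000 random 12³ spot
scenes for the attraction-distance oracle; 10 phantoms each for transient
removal (5+5 objects) and the counting pipeline (12 double- + 20
single-positive at SNR 10); and 100 repetitions of the two-group junction
comparison (n = 30 traces per group, amplitudes 0.50 vs 0.39). These sizes
give stable statistics on a single CPU in well under a minute per stage.
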