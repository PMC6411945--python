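# Methods

cytoquant quantifies four cytoskeletal/motility phenotypes from
fluorescence microscopy of epithelial monolayers, plus the two pieces of
numerical bookkeeping that usually accompany them (mean ± SEM summaries
with a two-sample test, and qPCR fold changes). Every pipeline is
validated by parameter recovery on the bundled synthetic generators;
this note records the models, the parameters that matter, and the
numerical choices behind them.

## Image model and conventions

Images are non-negative intensity arrays with named axes (`t`, `z`,
`c`, `y`, `x`), a pixel size in μm and a frame interval in seconds,
carried on the `ImageStack` object so unit conversions happen in one
place. Pixels are indexed 0-based with pixel centres at integer
coordinates; `y` grows downward. TIFF round-trips embed axes and
calibration in the image description and are lossless for integer
dtypes.

## Preprocessing

**Maximum projection** is the per-pixel max over `z`.

**Rolling-ball background subtraction** defines the background as the
grayscale morphological opening of the image by a non-flat spherical
cap of radius *r* (height `sqrt(r² − d²)` over the disc `d ≤ r`), with
edge-clamped boundaries, and subtracts it with clipping at zero. This
is an exact, oracle-testable definition — no legacy 8-bit
shrink/enlarge approximation. The radius is the only parameter;
defaults are 50 px for tubulin projections and 15 px for 3×-upscaled
comet images. The operation is invariant to constant offsets and never
returns negatives.

**Upscaling** is integer-factor bilinear interpolation (factor 3 for
comet morphometry, dividing the carried pixel size).

**Stabilization** estimates a pure translation per frame by windowed
phase correlation with Fourier-upsampled sub-pixel refinement.
Registration is sequential — each frame against its predecessor, with
corrections accumulated to frame 0 — because inter-frame motion is
small, and large-shift correlation against a distant reference can lock
onto correlation sidelobes. A second pass against frame 0 corrects the
slow drift of accumulated estimates and is gated to residuals ≤ 1.5 px
so it can never override the sequential result. Corrected frames are
resampled bilinearly with zero fill. Recovery on textured scenes:
integer drifts exact after rounding (float error < 0.2 px at 15 px
cumulative shift); 0.5 px/frame sub-pixel drift recovered within
0.03 px/frame.

**Temporal running average** is a centred, truncated-window mean
(window default 50 frames); no data are invented at the sequence ends,
so the first and last `window/2` frames average fewer frames.

## Ridge detection

Bright curvilinear structures are localized by Hessian eigenanalysis of
the Gaussian-smoothed image at scale σ: at a line point the principal
eigenvalue is strongly negative, its eigenvector spans the line normal,
and the first directional derivative along the normal vanishes within
the pixel. The sub-pixel correction is accepted up to 0.75 px per
component (clamped to ±0.5 px), which keeps centre-line pixels whose
true line runs near a pixel boundary. Strength is the magnitude of the
principal second directional derivative (intensity/px²).

Linking is hysteresis-based: points with strength ≥ `upper_threshold`
seed lines; growth continues through neighbouring line points with
strength ≥ `lower_threshold`. The walk is steered by the local Hessian
tangent, sign-aligned with the travel direction, and considers only the
3 pixel neighbours nearest that tangent; the candidate minimizing
(sub-pixel distance + normal-angle change) is taken. Steering by the
local tangent rather than the last quantized step matters: step
quantization can otherwise rotate the walk onto the line's width and
strand it. Lines split at junctions (first line to reach a pixel keeps
it); crossings are not re-joined, which is irrelevant for density
rendering. Polylines shorter than `min_length` are dropped.

Parameter conventions: σ for an expected full line width *w* is
`w/(2√3) + 0.5`; `thresholds_from_contrast` converts an expected line
peak into strength units using the closed form
`h·s_l/(s_l² + σ²)^(3/2)` (cross-section sd `s_l = w/2`), seeding at
40% and continuing to 12% of that ideal response by default.

Measured performance on synthetic filament fields (Gaussian
cross-section sd 1.5 px, peak 100): noiseless straight lines localize
with interior RMS error ≤ 0.04 px at any orientation; at SNR 8
(noise sd 12.5), 20-filament fields give point precision ≥ 0.95 and
recall ≥ 0.91 at 2 px matching. Detected lines overrun true endpoints
by ~2σ into the blur cap; tests measure localization on the interior.

**Microtubule density** renders all detected polylines as 1-px white
(255) Bresenham lines on a black canvas and reports the canvas mean:
exactly `255 × rendered pixels / total pixels`, an unbiased
length-per-area proxy in the 0–255 "a.u." scale. Width-1 rendering
keeps the score linear in total filament length until lines start to
overlap.

## Comet morphometry

Cells are segmented from a junction-stained channel (bright cell-cell
boundaries) by marker-based watershed: the smoothed junction image is
quantized to 64 grey levels so flat cell interiors form connected
minima plateaus; plateau components with area ≥ `min_cell_area` become
markers. Quantization is what makes the marker definition robust — on
a noisy image, exact local minima are isolated pixels. Frame-touching
regions are flagged and can be excluded.

The comet channel (3×-upscaled, background-subtracted) is thresholded
(Otsu by default; fixed threshold for regression tests), 8-connected
components below `min_area` are discarded, and each particle's ellipse
comes from the central second moments of its member pixel coordinates
(full axes `4·sqrt(eigenvalue)`); AR = major/minor. Particles are
assigned to the cell containing their centroid; centroids on the
background label are discarded. ARs are averaged per cell, cells with
zero comets are excluded (AR is undefined), and conditions are
summarized as mean ± SEM over cells.

Two practical notes, both visible in the validation suite:

* `min_area` should scale with the expected comet size. The default
  (4 px² at upscaled resolution) only rejects single-pixel speckle; for
  the synthetic conditions used in the recovery tests (comet minor
  sd 2 px, i.e. ~250 px² masks after upscaling) the tests use ~¼ of the
  smallest true comet area, which removes the noise-blob population
  that otherwise dilutes per-cell means.
* The binary-mask moment ellipse has a noise floor for near-isotropic
  particles: the thresholded contour is ragged over a band of width
  ~noise/gradient, the ordered eigenvalue ratio is ≥ 1 by construction,
  and at SNR 10 an isotropic spot therefore measures AR ≈ 1.09–1.11
  regardless of its size (we verified size-independence at minor
  sd 2–4 px; the bias falls to ~+5% at SNR 20 and ~+2.5% at SNR 40).
  Anisotropic recoveries are unaffected (AR 1.5–3 recover within 3%),
  and the bias is common to both arms of any comparison, so condition
  *differences* remain detectable — the study-scale sensitivity test
  separates true ARs 1.93 vs 1.97 (Δ = 2%) with the correct sign in
  20/20 seeded replicates at ~300 cells per condition.

## Comet tracking

Spots are local maxima of the scale-normalized negated
Laplacian-of-Gaussian response above a prominence threshold, refined to
sub-pixel by per-axis quadratic interpolation. Linking is mutual
nearest neighbour between consecutive frames under a displacement gate;
no gap closing and no merge/split handling — plus-end comets are
short-lived, near-linear movers, and the simplest defensible linker is
preferred. Tracks need ≥ 3 frames (speed from fewer points is
noise-dominated). Metrics: duration = (n−1)·Δt; path length = sum of
Euclidean steps in μm; mean speed = path length / duration (the mean
frame-to-frame speed, the convention of common tracking software);
displacement = net start→end, always ≤ path length. Constant-velocity
recovery is within 2% for speeds 0.05–0.20 μm/s noiseless and within
3% at SNR 10 with 0.3 px localization jitter.

## Kymograph motility

A rectangular region inside an island is sliced row-by-row and
column-by-column; each line becomes a kymograph (rows = time, columns =
position), so a stationary feature is a vertical streak and a feature
moving at *s* px/frame along the line is a streak at atan(*s*) from
vertical. Streaks are traced with the ridge detector and each trace is
scored by the absolute deviation of its Feret (maximum-caliper) angle
from vertical, clipped to [0°, 90°]; deviations are pooled over a
region's kymographs and averaged. The Feret search runs over convex
hull vertices and equals an all-pairs search exactly.

The temporal running average (default 50 frames) removes fast zero-mean
jitter, but it also smears each feature *along its own motion
direction*. Two consequences shape the pipeline:

* A feature moving obliquely to the sampled line decorrelates from the
  line and, once smeared, becomes quasi-self-sliding — its kymograph
  trace underestimates the motion. Sampling along the motion component
  is exact, however: for drift along x, the x-kymograph's averaged
  profile is a rigid translation of a smoothed profile at exactly the
  drift speed. The `axes` option therefore restricts slicing to one
  direction when the motion direction is known; pooling both
  directions (the default) averages the along-line components of
  heterogeneous motion.
* Smearing turns thin streaks into ribbons of perpendicular width
  `window·s/√(1+s²)`. `streak_ridge_params` matches the tracing scale
  and minimum trace length to that width from a pilot speed estimate
  (iterate once from a guess in practice). Frames whose averaging
  window was truncated at the sequence ends are dropped before slicing
  (`trim_boundary`): their content is not yet moving at steady-state
  rate and produces spurious vertical structure. Trace points within
  one σ of the kymograph border are excluded before the Feret — the
  smoothing boundary bends trace ends toward vertical.

Recovery under these rules (axis-aligned drift, matched-axis slicing,
2 px jitter, 50-frame window): static ≤ 0.3°, drift 0.5/1.0/2.0
px/frame recovered at 26.5°/43.9°/61.5° against expected
26.6°/45.0°/63.4°. Drift-recovery simulations use 150-frame movies so
that ~100 full-window frames remain after boundary trimming.

## Island fractions and statistics

The epithelial/mesenchymal classification of peripheral cells is a
manual, morphology-based call and stays an input; the package
implements only the exclusion rule (islands with < 5 scored cells are
dropped, configurable) and aggregation: per-island percent mesenchymal
(by cell count, or by perimeter length when segments are provided),
summarized as mean ± SEM over islands.

`summarize` reports mean, SEM (n−1 sd over √n) and n. The two-sample
test is Welch's unequal-variance t (two-sided,
Welch–Satterthwaite df), computed from the closed form with only the
t-distribution CDF taken from scipy, so the test suite can check it
against an independent implementation; a Mann-Whitney U alternative is
exposed for the non-parametric reading. Degenerate zero-variance
inputs: equal means give p = 1 by convention.

qPCR fold changes use 2^−ΔΔCt: per condition, ΔCt = mean Ct(target) −
mean Ct(reference); ΔΔCt = ΔCt(treated) − ΔCt(control). The result is
invariant to constant Ct offsets. A per-replicate mode pairs
replicates by index within condition and reports the SEM of replicate
folds; condition-mean ΔΔCt is the default because replicate pairing is
not always meaningful.

## Synthetic data

The generators emulate the four input classes at desk scale with
serialized ground truth; all randomness flows from a mandatory seed and
regeneration is bit-identical.

* **Filament fields**: unit-step random walks with Gaussian heading
  increments (sd 0.06 rad/step — gently curved, microtubule-like),
  steered back at borders; rendered by splatting impulses every 0.25 px
  along the centre line and blurring to a Gaussian cross-section
  (sd = width/2), which makes the centre-line peak exact. Truth:
  polylines and total arc length.
* **Comet fields**: Voronoi tessellation of Poisson-disc seeds; the
  junction channel is the blurred boundary map. Comets are anisotropic
  Gaussians (minor sd default 2 px — a ~0.5 μm comet width at a 63×
  /~0.1 μm-pixel acquisition; major = AR × minor) at uniform random
  orientations, placed with a global minimum separation of
  4.5·AR·σ_minor so that thresholded components never merge even when
  major axes align (the saddle between two peaks stays well below
  plausible thresholds). Cells that cannot fit their quota are
  reported in truth warnings; the generator errors only if fewer than
  80% of requested comets fit. Optional per-comet AR dispersion
  (`ar_sd`, truncated normal) makes between-cell variability realistic
  for sensitivity simulations (per-cell sd ≈ ar_sd/√comets ≈ 0.1,
  matching SEM·√N of typical fixed-cell datasets).
* **Comet movies**: spots nucleate at random times/positions, move
  ballistically in a random direction for a random lifetime (default
  10–25 frames) and vanish; defaults 2 s frames, 45 frames.
  `position_jitter_px` adds localization jitter to rendered positions
  to emulate detection-level noise.
* **Drift movies**: a band-passed-noise + Gaussian-blob base scene,
  translated by cumulative drift plus per-frame zero-mean uniform
  jitter with bilinear resampling; the base canvas is padded so content
  never wraps. Defaults 120 frames at 15 s (a 30-min acquisition);
  recovery tests use 150 frames (see above). Truth: drift vector and
  the jitter series.

Imaging model: isotropic Gaussian PSF, additive Gaussian noise with
SNR = peak/noise-sd. What this does *not* emulate: Poisson shot noise,
photobleaching, uneven illumination, out-of-focus haze, motile
sub-structure within cells, or biological heterogeneity of comet
shapes beyond the AR dispersion — so passing recovery tests shows the
estimators are correct under their stated model, not that real images
of arbitrary quality will yield unbiased values.

## Known limitations

* Mask-moment AR carries the isotropic noise floor described above;
  absolute AR values near 1 are inflated at low SNR even though
  condition comparisons remain valid.
* The kymograph score measures the motion component along the sampled
  line; isotropically moving features pooled over both axes score
  below the full speed (aperture effect inherent to line sampling).
* The tracker has no gap closing: a single missed detection splits a
  track. At the densities and SNRs tested this is rare.
* Stabilization assumes rigid translation; rotation or deformation is
  not corrected.
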