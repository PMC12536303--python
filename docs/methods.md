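# Methods

## Overview

`octamorph` implements the analysis chain of inter-frame OCT angiography
(OCTA) for layered skin/mucosa, together with a synthetic speckle phantom
used to validate every stage against known ground truth:

1. **phantom** — seedable synthetic repeated-B-scan volumes with exact
   vessel masks, layer boundaries and summary values;
2. **angiography** — the intensity-based Doppler variance (IBDV) statistic,
   volume assembly with an intensity (noise) mask, and en-face
   maximum-intensity projection;
3. **quantify** — Mexican-hat vessel enhancement, binarization, vessel
   density and skeleton/distance-transform diameters; surface and
   dermal–epidermal junction (DEJ) detection and epithelial thickness;
4. **pipeline / cli** — per-subject, per-site orchestration into a
   morphometry report, plus summary statistics; a packaged clinical
   reference table ships in the same report format.

## The IBDV statistic

At each slow-axis position, J = 6 B-scans are acquired at the same location
with inter-frame interval ΔT = 5 ms.  Per voxel, with |A_j| the amplitude of
repeat j at depth z,

    σ² = 1 − Σ_{j=1}^{J−1} |A_j||A_{j+1}| / Σ_{j=1}^{J−1} (|A_j|² + |A_{j+1}|²)/2

σ² is 0 for perfectly repeating frames, ≈ 1 − π/4 ≈ 0.215 in expectation for
fully decorrelated Rayleigh speckle, and is invariant under global amplitude
scaling.  The denominator is the arithmetic mean of consecutive-pair
intensities; this is the only reading consistent with σ² = 0 for identical
frames and σ² ∈ [0, 1] (the published rendering of the denominator is
typographically garbled, which we note here for provenance of the form
implemented).  "Number of averaged A-lines" is disentangled into two
parameters: `J` counts *repeated frames* (6), while lateral averaging over
`2·window + 1` A-lines (default `window = 2`, i.e. 5 A-lines) is applied to
numerator and denominator separately before the ratio, which suppresses
single-voxel speckle noise without biasing the ratio.  An optional 1-voxel
depth window exists and is off by default.  Amplitude-only input suffices;
complex input is accepted and its magnitude taken.

Voxels whose mean amplitude over the J repeats falls at or below a volume
quantile (default 0.25) are masked to NaN: the additive noise floor
decorrelates between frames and would otherwise read as flow.  A voxel with
zero amplitude in the whole averaging window is defined as σ² = 0 (no signal
carries no measurable flow).  With `threshold_quantile = 0` every voxel is
kept; otherwise keeping is *strictly above* the quantile value.

En-face angiograms are the per-(y, x) maximum of σ² over a half-open depth
range, ignoring NaN (all-NaN columns project to 0).  The default range runs
from the median detected surface to the bottom of the volume.

## The phantom

The generator emulates exactly the statistical structure the IBDV analysis
assumes, so that every downstream measurement has a known true value.

* **Speckle.**  Each voxel's complex field is circular Gaussian, giving
  Rayleigh amplitudes (fully developed speckle).  Temporal correlation
  between the J repeats is imposed per voxel by AR(1) mixing of the complex
  field, E_j = ρ·E_{j−1} + √(1−ρ²)·G_j.  ρ is the *complex-field*
  correlation; the resulting amplitude (envelope) Pearson correlation is
  ≈ 0.915·ρ², which agrees with ρ at the endpoints 0 and 1 and is strictly
  monotone in between — sufficient for every contract the package makes.
  Static tissue uses `static_correlation` (default 0.99, giving a static
  σ² ≈ 0.004); vessel voxels use their own `flow_correlation` (default 0).
* **Geometry.**  z grows with depth, x is the fast axis, y the slow axis;
  indices are 0-based, ranges half-open; the slow axis reuses the lateral
  pixel pitch so en-face images are isotropic.  The default grid is 128
  lateral × 256 depth × 64 positions × J = 6, i.e. a 5 mm fast-axis field at
  39.06 µm pitch (matching a 40 µm lateral resolution) and a ~1 mm depth at
  4 µm per pixel; a full default phantom builds in about two seconds.
* **Layers.**  A sinusoidal surface (base depth 160 µm, undulation
  amplitude 40 µm, period 2 mm by default) over an epithelium of constant
  thickness (default 250 µm) over dermis.  Backscatter defaults are 0.5
  (epithelium) and 1.0 (dermis); `dej_contrast` ∈ [0, 1] scales the
  reflectivity step, with 0 reproducing the sclerosis-like loss of layer
  contrast in which no boundary exists to detect.  Amplitude decays as
  exp(−µ·d) with d the optical depth below the *local* surface
  (µ default 0.002 µm⁻¹), so undulation is physically consistent.
* **Vessels.**  Tubes around polyline centerlines; a voxel is vessel iff its
  centre lies within the radius (no anti-aliasing), keeping ground-truth
  counting exact.  Choosing radii at half-integer multiples of the pixel
  pitch makes the discrete footprint width equal the true diameter exactly.
* **Noise.**  An additive Rayleigh noise floor (default amplitude scale
  0.02), independent between frames — the decorrelating background the
  intensity mask exists to remove.

What the phantom does **not** model: beam propagation and defocus, bulk
motion, polarization, refraction, multiple scattering, projection tails
below vessels, and spatially correlated speckle.  Passing recovery tests on
phantoms therefore demonstrates the correctness of the *computational*
chain, not robustness to every artifact of in-vivo acquisition.

## Vessel morphometry

The en-face angiogram is enhanced with a multi-scale Mexican hat (negated
Laplacian of Gaussian): for each scale s (a vessel diameter in µm),
σ_px = s / (2·pitch), responses are scale-normalized by σ², the per-pixel
maximum over scales is clipped at 0 and rescaled to [0, 1].  The filter
kernel is truncated at 8σ so its DC leakage stays at floating-point epsilon
(a constant image maps to exactly zero response).

Binarization is Otsu by default, with a fixed-threshold alternative.  Otsu
maximizes inter-class separation and is robust for visualisation, but on a
clipped ridge response it systematically erodes vessel borders by roughly
σ/2 per side.  For *width-accurate* morphometry the fixed threshold 0.2 (of
the normalized response) sits just above the background response and close
to the LoG zero-crossing, which coincides with the vessel edge; on phantoms
it recovers density within ~1 percentage point and mean diameter within one
pixel.  Components smaller than `min_area_px` (default 5) are removed.

Vessel density is the percentage of ROI pixels that are vessel (full field
of view by default — the 5 × 5 mm region analog).  Diameters automate the
manual multi-point calliper protocol: the mask is skeletonized, and every
`sample_step_px`-th skeleton pixel (default 10) contributes
(2·EDT − 1) px × pitch, where EDT is the Euclidean distance transform.  The
−1 corrects the half-pixel-per-side overshoot of centre-to-centre distances;
odd drawn widths are read exactly and even widths 1 px low, both within the
±1 px accuracy claimed.  Samples within one local radius of a skeleton
endpoint are excluded (tip readings are not diameters).  Mean, SD (ddof 1)
and the sample count are reported.

## Layer detection and thickness

**Surface.**  Per A-scan, the first depth at which the depth-median-filtered
intensity strictly exceeds background mean + k·SD (k default 4; background
from the shallowest 16 pixels, assumed above the tissue).  A median filter
preserves step locations exactly, so a noiseless edge is located without
bias.  The surface map is then median-filtered across A-scans with odd
(linear-extrapolating) reflection padding — plain edge padding biases the
estimate up the ramp wherever the surface slopes at the image border.
A-scans with no crossing are missing, not errors.

**DEJ.**  Each A-scan is flattened (shifted so its surface sits at depth 0)
before the log-intensity B-scan is Gaussian-smoothed laterally (σ = 4 px)
and axially (σ = 2 px); without flattening, lateral smoothing across an
undulating surface mixes air and tissue.  The axial gradient is detrended
per A-scan by its median over the search window (removing the attenuation
slope), and the search runs 8–120 px below the surface.  Detection is
two-stage:

1. a *B-scan gate*: the strongest extremum of the laterally averaged
   detrended gradient marks the candidate layer, and its slope-corrected
   log-amplitude step (window mean below minus above, 10 px windows) must
   reach `min_contrast` (default 0.3 natural-log units ≈ a 1.35× amplitude
   ratio).  A per-A-scan maximum over ~100 depths of speckle noise is an
   extreme-value statistic that would regularly exceed any threshold a true
   boundary reliably clears; gating on the lateral mean first separates "no
   boundary exists" from "boundary locally weak".
2. *per A-scan*: the boundary is re-localized as the sub-pixel centroid of
   the gradient magnitude within ±2 px of the consensus depth (a centroid
   averages localization noise an argmax would amplify), and the A-scan's
   own contrast must clear `min_contrast / 2`; otherwise that A-scan is
   missing.

On default phantoms this yields a found-fraction of exactly 1 at full layer
contrast and exactly 0 at zero contrast, with boundary errors ≲ 1.3 px.
Limitation: the B-scan gate assumes the boundary, where present, exists
across most of the scan at a roughly constant depth below the surface; a
boundary present in only a small lateral fraction of a B-scan would be
gated away.

**Thickness.**  Per A-scan, (dej − surface) × axial pitch / `group_index`,
summarized by the median over defined A-scans (robust to detector
outliers).  `group_index` defaults to 1.0 — raw *optical* thickness, so
values are comparable with conventionally reported ones — and can be set to
≈ 1.4 (soft tissue) to obtain geometric thickness.  A DEJ at or above the
surface is set missing with a warning.  Missing summaries propagate as
empty CSV cells and render as an em-dash.

## Pipeline, seeds and determinism

A single YAML config drives a subject: per site either a phantom spec or an
HDF5 frame series, plus angiography/vessel/thickness parameters (all
defaults are written to the run log).  Per-site phantom seeds derive from
the master seed by a fixed offset of 1000 per site index, so one config +
seed pair reproduces the CSV report byte for byte.  Stage failures at one
site are logged and leave cells missing; only a fully empty report aborts.

## Reference table and its internal ranges

The packaged reference table (8 subjects, 3 vulvar sites; density and
diameter measured on the labia minora, thickness per site, with missing
values where the DEJ was not distinguishable) is stored verbatim in the
report CSV format.  `summarize` performs exact arithmetic on it; the
prose ranges quoted alongside the original table disagree with the table's
own extrema for three quantities (density minimum, diameter maximum, labia
minora thickness maximum), so all package outputs and tests use the
table-derived values.

## Problem sizes used in tests

Test and acceptance phantoms use the default 128 × 256 grid with 2–64
slow-axis positions depending on what the check needs (thickness checks use
single-position phantoms; vessel recovery uses the full 64-position
volume).  These sizes give ≥ 10⁴ voxels to every Monte-Carlo estimate while
keeping the whole suite under a minute.
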