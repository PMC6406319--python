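# Methods

`histoflux` quantifies antibody delivery in multi-channel fluorescence
images of tumor cryosections: a DAPI channel (nuclei), a rhodamine-lectin
channel (perfused "functional" vessels, labelled in vivo), and a FITC
channel carrying a fluorophore-conjugated antibody (e.g.
Alexa-488-trastuzumab).  This note records the models, estimators,
parameter choices and known limitations.

## Section model and region sampling

A section is three co-registered 2-D intensity arrays plus a physical
pixel size (µm/px).  Intensities are arbitrary units (AU), kept as loaded
— no rescaling, no background subtraction (none is applied by default
because autofluorescence levels are acquisition-specific; callers can
subtract before analysis).

The tumor extent is a binary mask.  When none is supplied it is derived
from the nuclear channel: a Gaussian blur (σ = 12 px) merges individual
nuclei into a contiguous tissue signal, Otsu's threshold separates tissue
from background, and the largest hole-filled component is kept.  This
assumes whole-section tumor tissue with nuclei distributed across it.

Regional sampling follows a 12-ROI layout: four square ROIs in each of
three bands at 25%, 50% and 75% of the tumor's apex-to-base extent.  The
apex direction is defined along the mask's principal axis (largest
eigenvector of the coordinate covariance), oriented so the apex is the
image-top end; ties resolve to image-left.  ROIs are 0-based, row-major,
half-open rectangles, placed by seeded rejection sampling among band
pixels where the full square fits inside the mask, with non-overlap
enforced by a Chebyshev-distance criterion.  Placement is deterministic
per seed and translates rigidly with the mask.

## Vessel segmentation and vascular density

The vessel channel is segmented by fuzzy c-means (FCM) over pixel
intensities: minimize Σᵢⱼ uᵢⱼᵐ (xᵢ − vⱼ)² with Σⱼ uᵢⱼ = 1, alternating
the closed-form membership and centroid updates.  Defaults c = 2, m = 2,
tol = 1e−5 (largest centroid move), max_iter = 300 — standard FCM
practice for bimodal intensity histograms.  Initial centroids are c
distinct data values drawn with a fixed seed, which makes runs
deterministic and the result equivariant under affine intensity maps.
Degenerate inputs (fewer than c distinct values) raise.  The objective is
recorded per iteration and is non-increasing.

Clustering uses intensity only — no spatial or texture features — because
perfused-vessel lumina are bright and compact and the sole downstream
quantity is an area fraction.  Pixels are hard-assigned to the cluster of
maximal membership, with ties broken toward non-vessel (conservative
vessel calls); the higher-centroid cluster is the vessel class.

Vascular density is reported as vessel pixels / tumor pixels, which is
bounded in [0, 1]; the vessel/non-vessel ratio is exposed as a secondary
field since both conventions appear in the literature.  An optional
minimum-object-size cleanup is off by default and recorded on the result
when used.

## Penetration and accumulation

Depth into tissue is the Euclidean distance transform of the vessel mask
(or of the tumor-mask complement, for the tumor-surface reference),
scaled to µm.  The penetration profile is the mean antibody intensity in
uniform depth bins (default 1 µm — fine enough to resolve peak-depth
differences of ~10 µm); vessel pixels themselves (depth 0) are excluded
by default since intravascular signal is not penetration.  Empty bins are
flagged and linearly interpolated by default (droppable or fatal by
configuration).

The AUC over 0–80 µm uses the trapezoidal rule across bin centers plus
rectangular end caps to the interval bounds; the caps make the AUC
additive across sub-intervals split at bin edges and reduce the half-bin
truncation at both ends.  "~80 µm" is implemented as an inclusive 80 µm
bound, configurable.  On a noise-free exponential phantom the AUC matches
A·λ·(1 − e^(−80/λ)) to well under 2% at 1 µm bins.

Peak depth is the center of the argmax bin of a 3-bin moving-average
smoothed profile (single-bin noise spikes would otherwise set the peak);
the raw argmax is reported alongside.  Accumulation is total antibody
intensity inside the tumor mask divided by mask area in µm² (AU/µm²).
Percent change between groups is 100·(treated − reference)/reference.

An exponential fit (nonlinear least squares with a log-linear initial
guess) recovers a decay length from a measured profile; it is used to
verify the generator's ground truth and is available for real profiles
that look exponential.

## Nuclear morphology

Nuclei are delineated by a Laplacian-of-Gaussian edge finder (σ = 2 px
default; the stated method gives no parameters, and 2 px matches
nucleus-scale blobs at ~0.65 µm/px).  Inside a bright blob the LoG
response is negative in a closed band along the boundary — the zero
crossing is the edge — so thresholding the response at a small negative
fraction of its extreme (−0.001·max|LoG|) and filling holes recovers blob
interiors.  Components below `min_size_px` (which measures the LoG
interior, slightly larger than the raw object for small specks) are
discarded and the discard count is loggable by the caller.

Fragments of an apoptotic nucleus can be grouped into one object: all
components are dilated by half a merge radius and connectivity is read
off the dilated image, so components whose masks lie within the radius
edge-to-edge merge.  Edge-to-edge distance separates the two relevant
scales — the thin gaps between fragments of one nucleus versus the larger
spacing between neighboring nuclei — where centroid distance does not
(fragment centroids of adjacent nuclei can be closer than two fragments
of one large nucleus).  Merged objects get summed area, summed perimeter
and the union of boundary points, so fragmentation lowers circularity and
raises the fractal dimension of the grouped object, matching per-nucleus
group statistics.  No merging happens by default.

Circularity is 4πA/P² (disk = 1).  Area is the pixel count.  The
perimeter is the length of the marching-squares boundary contour smoothed
along arc length by a periodic Gaussian of σ = 1 contour sample: raw
digital boundaries overestimate smooth perimeters by up to ~8% (staircase
excess), while σ = 1 smoothing removes the staircase with ~1% corner
rounding on true right angles.  Calibration: digital disk of radius 50 px
→ 0.984; 80 px square → 0.799 vs π/4 ≈ 0.785; rotated squares 0.78–0.79.
Discretization can push the value slightly past 1, so reports are capped
at 1.05.

The fractal dimension is the box-counting dimension of the boundary point
set (the edge contour, not the filled region): FD = −slope of the
least-squares fit of log N(ε) against log ε.  N(ε) is the minimum box
count over ≥ 4 grid offsets — the minimal-cover definition; averaging
over offsets inflates coarse-scale counts and biases a 4th-order Koch
prefractal from its theoretical log 4/log 3 ≈ 1.262 down to ~1.20,
whereas the minimum cover gives 1.26–1.27.  Default box sizes are dyadic
from 2 px to a quarter of the bounding-box diagonal; scales where counts
saturate (N > n_points/4, i.e. near one point per box) or go sparse
(N < 8) are excluded from the fit when at least three scales remain, and
the fit range plus R² are reported.  The estimator returns ~0.99 on
straight lines and smooth circles and is stable within ±0.05 across grid
offsets.

Analysis can be restricted to perivascular nuclei (object centroid within
80 µm of the vessel mask, boundary inclusive), where antibody exposure is
the relevant covariate.

## Group statistics

Per-section metrics are aggregated per treatment group as mean ± sample
standard deviation (n−1 denominator; single observations raise), percent
change of group means against a reference group, and an omnibus one-way
ANOVA (F = MS_between/MS_within, p from the F distribution) across
groups per metric.  Stars annotate the omnibus p at the reporting
convention * p < 0.05, ** p < 0.005; no post-hoc procedure is applied
because the downstream reporting uses starred thresholds only.  Caliper
tumor volume is width² × length × 0.4 (mm³).

## Synthetic data: what it emulates and what it does not

The generator produces the three channels with known ground truth:

- **Tumor**: an ellipse inset from the border by `surface_margin_um`
  (default 15 µm), standing in for the sectioned tissue extent.
- **Vessels**: constant-radius line-segment tubes (default 5 µm radius,
  6 tubes) with random placement and orientation — the tubular geometry
  of lectin-positive structures without branching.
- **Antibody**: A·exp(−d/λ) with d the distance to the nearest vessel
  pixel (defaults A = 1000 AU, λ = 20 µm).  The exponential is the
  simplest monotone single-parameter model consistent with decaying
  penetration histograms; λ is recoverable from the binned profile within
  10% at ≤ 5% noise.
- **Nuclei**: intact nuclei are discrete disks (default radius 5 µm);
  fragmented nuclei split a disk Voronoi-style around three interior
  seeds (minimum seed separation 0.7 r so lobes survive) with an erased
  boundary band whose half-width grows with severity (floored at 2 px,
  capped at 0.25 r), plus high-frequency radial boundary roughness
  (harmonics 10–31, amplitude 0.14·severity capped at 0.45 r).  Severity
  0 reduces exactly to the intact disk.  Over a severity grid of 0.5–3,
  mean circularity decreases and mean boundary FD increases monotonically
  (Spearman |ρ| ≥ 0.9 on batches of rendered nuclei).  Nucleus centers
  keep a minimum spacing of 3.4 r so fragment gaps (intra-nucleus) and
  nucleus spacing (inter-nucleus) remain separable scales for merging.
- **Noise**: i.i.d. Gaussian per pixel, clipped at zero.  Identical spec
  and seed give bit-identical images.

Defaults emulate a 10× widefield acquisition at 0.65 µm/px over a
512 × 512 field; the acquisition this mirrors states no pixel
calibration, so the value is a configurable convention, not an inference.
Not modelled: optics (PSF, defocus), 3-D structure, photobleaching,
autofluorescence gradients, vessel branching or perfusion heterogeneity,
intensity variation between nuclei.  Passing tests on this generator
therefore demonstrate correctness of the estimators under known ground
truth, not robustness to every artifact of real microscopy.

## Problem sizes and determinism

Synthetic benchmarks use 512 × 512 sections (640 × 640 for the
200-nucleus morphology cohorts) — large enough for stable statistics
while keeping the full suite fast.  All stochastic steps (generator, FCM
initialization, ROI placement, box-count grid offsets) take explicit
seeds; reruns are reproducible bit for bit.

## Known limitations

- FCM on intensity alone assumes a bimodal vessel channel; heavy vignetting
  or stain gradients would need spatial features or prior flat-field
  correction.
- The LoG extractor does not split touching nuclei (no watershed); dense
  clumps merge.  The synthetic generator avoids heavy overlap, real
  sections may not.
- Box-counting FD on small nuclei (boundary < ~100 px) has few usable
  scales; values are comparable within a cohort processed identically but
  are not absolute dimensions.
- The tumor-surface reference treats the mask boundary as the surface;
  sectioning artifacts (folds, tears) would corrupt it.
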