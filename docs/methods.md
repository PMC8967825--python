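# Methods

## Coordinate conventions

All arrays are ordered (z, y, x) = (planes, rows, cols); all physical
quantities are micrometres. Voxel index *i* along an axis maps to
physical coordinate *i*·spacing, with the origin at the centre of the
first voxel. Anisotropic spacing is carried everywhere; no operation
assumes isotropy. Latitude φ ∈ (−90°, 90°) is measured from the
equatorial plane of the fitted sphere with +90° at the +z pole;
longitude λ ∈ [0°, 360°) from +x toward +y. The map's polar axis is the
volume z axis by default; embryos whose animal–vegetal axis is not
aligned with z should be rotated upstream (the alignment is
acquisition-specific and is not estimated here).

## Surface estimation

1. **Binning.** Block-mean downsampling, default factor 4 per axis,
   configurable per axis for anisotropic data. Mean (not sum) binning
   keeps intensities on the same scale, so threshold settings are
   comparable across binning factors; trailing partial blocks are
   averaged over the voxels they contain. Binning by factor *f* places
   binned voxel 0 at the centre of its block — (f−1)/2 original voxels
   in — and `estimate_sphere` adds that constant shift back to the
   fitted centre (exact, because the fit is translation-equivariant).
2. **Adaptive binarization.** Foreground ⇔ I ≥ c·⟨I⟩_window with
   c = 2(1−sensitivity), window odd per axis (default: smallest odd
   integer ≥ axis/8 — local statistics at embryo scale), edge-replicated
   borders, ties counted as foreground. This fixed formula makes the
   behaviour testable and monotone: the foreground set can only grow as
   sensitivity increases. Sensitivity 0.4 (c = 1.2) marks voxels 20%
   brighter than their neighbourhood — the embryo rim against mounting
   medium. Widely used adaptive-threshold routines follow the same
   direction but do not document their exact constant; this package pins
   one.
3. **Surface extraction.** The largest 26-connected foreground component
   is kept (stray noise voxels form tiny components and are discarded);
   its boundary voxels — foreground with at least one background
   6-neighbour, volume border counting as background — form the point
   cloud. Boundary voxels rather than a triangulated isosurface: the
   sphere fit needs only points, and voxel boundaries avoid
   mesh-extraction parameters. No outlier rejection is applied before
   the fit by default.
4. **Sphere fit.** Linear least squares on the algebraic sphere
   equation x²+y²+z² = 2ax+2by+2cz+d (points are centred first for
   conditioning; the shift is restored exactly). Exact on noiseless
   samples; degenerate inputs (fewer than 4 points, coplanar clouds,
   non-positive squared radius) raise a named error. The rms of
   (|p−centre| − radius) is reported as the fit residual. For a shell of
   cells the boundary cloud contains inner and outer faces roughly
   symmetric about the cell layer, so the radius estimate is centred on
   the layer radius rather than biased to one face.

## Mercator unwrapping

Rows are placed uniformly in Mercator northing y(φ) = R·ln tan(π/4+φ/2)
(computed as R·asinh(tan φ), the same function but exactly odd and
exactly zero at the equator); columns uniformly in longitude, column j
centred at (j+0.5)·360°/n_cols. Uniform-in-y row placement is what makes
the map conformal — the property that justifies Mercator for migration
analysis — whereas uniform-in-latitude rows (the `equirect` mode,
provided for comparison and able to reach ±90°) are not. Mercator is
singular at the poles, so the map is truncated at a configurable
latitude, default ±85°.

The reference radius scaling y is the *fitted* sphere radius for every
layer, so all layers of a multi-layer stack are pixel-aligned. Default
grid size puts one column per finest-voxel-pitch of equatorial arc
(n_cols = round(2πR/d)) and sizes rows at the same scale.

Each map pixel is mapped through standard spherical-to-cartesian
conversion at radius (fitted + offset) and sampled by trilinear
interpolation in physical coordinates (nearest-neighbour available for
label volumes); points outside the voxel-centre bounding box return the
fill value (default 0) rather than erroring. Layer offsets default to an
arithmetic sequence with 2 µm step — matching the radial extent of a
cell layer relative to typical sampling — spanning a configurable depth
inward/outward. The maximum-intensity map is the pixelwise maximum over
layers.

Validated properties (all computed by the test suite and
`scripts/acceptance.py`): y(60°, R=1) equals ln tan 75° to 1e−9 and the
inverse round-trips to 1e−9; an analytic uniform shell projects flat to
within 1% away from the truncation rows; geodesic discs painted on the
shell at 0°/30°/60° latitude project with aspect ratio 1 within 5% and
linear size growing as sec φ within 5%; a disc straddling the 0°/360°
seam conserves total intensity within 1%; the layer of maximal total
intensity identifies the true shell offset to within one 2 µm step.

For the uniformity check the analytic shell is given a 4 µm radial
Gaussian profile: trilinear interpolation has a curvature bias of order
f″·h²/8 at the profile peak, ≈ 3% for a 2 µm profile on a 1 µm grid but
< 0.8% at 4 µm, so the phantom is made thick enough that the map
geometry — not interpolation bandwidth — is what the check measures.

## Spot counting

Baseline subtraction: a Gaussian blur with σ given in µm (converted per
axis to voxels; reflective boundaries) is subtracted and the result
clipped at zero. A blur with σ_bg ≫ spot width leaves isolated spot
peaks essentially intact (attenuation (σ_b²/(σ_b²+σ_bg²))^{3/2}) while
removing yolk glow and slowly varying background — the standard
baseline-and-background step before spot rendering in commercial
packages, here with every parameter explicit and reproducible.

Detection: 26-neighbourhood local maxima (plateaus included) with
baseline-subtracted value ≥ threshold are visited in descending
intensity (ties by lexicographic (z,y,x) index) and accepted when at
least min_separation (µm, physical) from every previously accepted peak.
Accepted peaks are refined by an intensity-weighted centroid over a
±2·expected_spot_sigma window; because refinement can nudge two
centroids slightly closer, a final pass re-checks the separation
invariant and drops the dimmer offender, so the reported set always
satisfies pairwise distance ≥ min_separation exactly.

Counting: ROIs are axis-aligned physical boxes, inclusive-low /
exclusive-high, so boxes that tile the volume partition the spots
exactly. A `whole` ROI spanning the volume is always reported; counts
are per embryo, never pooled. Detected counts are exact (equal to ground
truth) for noiseless volumes with cells separated by ≥ 4 blob widths;
under shot noise at peak SNR 10, recall and precision exceed 0.95.

## Synthetic embryos

The generator emulates a fused light-sheet volume of a spherical embryo:
cells uniformly distributed on a spherical shell (surface progenitors) at
a signed radial offset from the surface, rendered as analytic isotropic
Gaussians through the anisotropic voxel grid (no kernel truncation
ambiguity; mass is evaluated to 5σ, truncating < 1e−6 of a blob);
optional yolk autofluorescence as a soft-edged interior ball
(super-Gaussian, 60% of the embryo radius); flat background; then camera
noise — Poisson on photon counts via a configurable gain, Gaussian read
noise after. Cell placement is rejection sampling with a pairwise
minimum separation and a documented attempt budget; overcrowded shells
raise an error naming the achievable density. A single seeded generator
with fixed draw order makes identical specs produce bit-identical
volumes; time-course volumes derive per-(timepoint, condition) seeds by
hashing, so each series element is independently reproducible.

Default study conditions (chosen once as a realistic early-embryo
scenario; the intensity statistics of real fused volumes vary by
instrument and are not asserted): 256³ voxels at (1.5, 1.0, 1.0) µm —
z-anisotropy typical of stage-scanned stacks — a 100 µm-radius embryo,
1500 cells of σ = 3 µm at amplitude 100 over background 5, Poisson noise
at gain 1 plus read noise σ = 1, giving peak SNR ≈ 10
(105/√110 variants are used where a test pins SNR exactly). Time courses
default to 1/2/3 dpf with control multipliers (1, 2, 3) and perturbed
(1, 1, 1) — a control series whose cell count grows versus a knockdown
whose count fails to keep pace.

What the generator does **not** emulate: non-spherical geometry (tail
extension, yolk bulge), optical PSF anisotropy beyond Gaussian blobs,
depth-dependent attenuation or scattering, stitching seams, and
intensity variation between cells. Passing tests therefore demonstrate
correctness of the geometry and counting logic under the stated noise
model, not robustness to every artifact of real SPIM data; on real
volumes the adaptive-threshold sensitivity, baseline σ and detection
threshold are the knobs to adjust, and all are exposed in the config.

## Numerical choices and edge cases

- Sphere-fit design matrix is centred before solving; rank < 4 raises a
  degeneracy error rather than returning a garbage sphere.
- `mercator_y` rejects |φ| ≥ 90°; grid construction in Mercator mode
  rejects truncation ≥ 90° with a message naming the singularity.
- Out-of-volume map samples fill with a constant (default 0); sampling
  never errors on geometry.
- Binning factors larger than the axis, even threshold windows, empty
  masks, non-positive sampling radii, and duplicate time-course labels
  all raise explicit errors.
- Baseline σ smaller than one voxel on every axis logs a warning (the
  baseline then nearly equals the image) instead of erroring.
- Problem sizes in the tests and the acceptance script (256³ end-to-end
  volume, 160³ projection phantoms, 128³ counting volumes, 100-replicate
  fit Monte Carlo, 20-seed detection study) were chosen to exercise
  realistic embryo scales while keeping a full run fast on a laptop.

## Pipeline

`run_pipeline` composes simulate (optional) → sphere fit → multi-layer
projection → maximum-intensity map → spot counting. Physical spacing is
mandatory throughout — a missing-spacing TIFF is an error, never a
silent default — because every stage (2 µm steps, µm thresholds) is
unit-bearing. The manifest records the config snapshot, package version,
per-stage timings, input checksums and output list; identical config +
seed reproduce outputs byte-for-byte. The input is resolved before any
output is written, so a missing input path aborts with no partial
artifacts.
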