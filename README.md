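# embryomap

Analysis of whole-embryo light-sheet fluorescence volumes of
approximately spherical embryos (e.g. zebrafish up to early
somitogenesis): estimate the embryo's bounding sphere, unwrap concentric
spherical shells onto 2D **Mercator map projections**, and count
reporter-positive cells in 3D with physical regions of interest, over
developmental time.

The package is aimed at microscopists and image analysts who have fused
SPIM/light-sheet stacks (TIFF/OME-TIFF with µm voxel spacing) and want to
visualize and quantify cells that migrate across the embryo surface —
for example lateral plate mesoderm progenitors or *hand2*-expressing
mesothelial cells.

## What it computes

**Sphere fit.** The volume is mean-binned (default ×4 per axis),
binarized with a local-mean adaptive threshold (voxel is foreground when
I ≥ 2(1−s)·⟨I⟩_local, default sensitivity s = 0.4), and the boundary
voxels of the largest connected component are fit by algebraic linear
least squares:

    x² + y² + z² = 2ax + 2by + 2cz + d,
    centre = (a, b, c),  radius = √(a² + b² + c² + d).

**Mercator unwrapping.** With latitude φ and longitude λ defined on the
fitted sphere, each shell (radius + offset, default 2 µm steps) is
sampled onto a map whose rows are uniform in Mercator northing

    y(φ) = R · ln tan(π/4 + φ/2),

the conformal (angle-preserving) placement — small circles on the embryo
surface stay circles on the map, which is what makes the projection
usable for migration analysis. A pixelwise maximum across layers gives
the maximum-intensity Mercator map. Rows are truncated at ±85° by
default (Mercator is singular at the poles); an equirectangular mode
reaching ±90° is available.

**Spot counting.** A wide Gaussian baseline is subtracted, 26-neighbour
local maxima above threshold are greedily suppressed to a physical
minimum separation, centroids are refined by intensity-weighted means,
and counts are reported per embryo × timepoint × ROI (axis-aligned µm
boxes, half-open so tiling boxes count each cell exactly once).

**Synthetic embryos.** A first-class generator renders spherical embryos
with known ground truth — cells on a spherical shell, optional yolk
autofluorescence, Poisson + Gaussian camera noise, anisotropic voxels,
and growing time courses in control vs perturbed conditions — so every
stage is validated against exact answers.

## Worked example

```python
import numpy as np
import embryomap as em

spec = em.EmbryoSpec(seed=1)           # 256³ volume, 100 µm embryo, 1500 cells
volume, truth = em.generate_volume(spec)

sphere = em.estimate_sphere(volume)    # bin ×4 → binarize 0.4 → fit
print(f"centre (µm): {np.round(sphere.center, 2)}   true: {spec.center}")
print(f"radius (µm): {sphere.radius:.2f}   true: {spec.sphere_radius}")

grid = em.default_grid(sphere, min(volume.spacing))
stack = em.project_multilayer(volume, sphere, em.layer_offsets(2.0, 10.0, 4.0), grid)
mercator_map = em.max_project_layers(stack)
print(f"map: {mercator_map.shape[0]} rows x {mercator_map.shape[1]} cols, "
      f"{len(stack)} layers")

params = em.SpotParams(background_sigma=15.0, detection_threshold=20.0,
                       min_separation=4.0, expected_spot_sigma=2.0)
spots = em.detect_spots(volume, params)
print(f"spots detected: {len(spots)}   true cells: {truth.n_cells}")
```

prints

```
centre (µm): [191.25 127.52 127.48]   true: (191.25, 127.5, 127.5)
radius (µm): 100.28   true: 100.0
map: 628 rows x 630 cols, 8 layers
spots detected: 1532   true cells: 1500
```

The fitted sphere matches the ground truth to a fraction of a voxel and
0.3% in radius despite shot noise; the map grid is sized so the equator
is sampled at the voxel pitch; the detected count is within ~2% of truth
at this noise level and cell density (counts are exact when cells are
separated by ≥ 4 blob widths and noise is off).

## Command line

```bash
embryomap simulate  --out run/ --n-cells 500 --seed 1
embryomap fit-sphere run/volume.ome.tif --out run/sphere.json
embryomap project   run/volume.ome.tif --sphere run/sphere.json \
                    --step-um 2 --depth-um 10 --out run/layers.tif
embryomap count     run/volume.ome.tif --threshold 20 \
                    --roi trunk:0,380,0,255,120,255
embryomap run-all   --config examples/pipeline.yaml --out run/
```

`run-all` writes the simulated volume + ground truth, `sphere.json`,
the layer stack and maximum-intensity map, `counts.csv`, a `run.log`,
and a `manifest.json` with the config snapshot, timings and checksums;
re-running with the same config and seed reproduces the outputs exactly.

## Documentation

See `docs/methods.md` for the model and procedure details, parameter
meanings and defaults, what the synthetic generator does and does not
emulate, and numerical choices.
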