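# Example embryomap pipeline configuration.
#
# Run with:
#   embryomap run-all --config examples/pipeline.yaml --out my_run
#
# Omit `simulate` and set `input_path` (plus `spacing` if the TIFF lacks
# metadata) to process a real fused light-sheet volume instead.

seed: 0

# --- surface estimation -----------------------------------------------
# Volumes are mean-binned x4 per axis before binarization: enough to keep
# the embryo outline while cutting the voxel count 64-fold.
binning: [4, 4, 4]
# Adaptive local-mean threshold sensitivity; a voxel is foreground when
# its intensity >= 2*(1 - sensitivity) * local mean.
sensitivity: 0.4
# Local-mean window per axis; null = smallest odd integer >= axis/8.
window: null

# --- map projection ---------------------------------------------------
# Concentric shells are unwrapped every 2 µm, from 10 µm inside the
# fitted radius to 4 µm outside, bracketing a surface cell layer.
step_um: 2.0
depth_in_um: 10.0
depth_out_um: 4.0
# Mercator rows cannot reach the poles; the map is truncated at ±85°.
# grid_mode: equirect gives rows uniform in latitude (reaches ±90°).
truncation_latitude: 85.0
grid_mode: mercator
sampler: trilinear        # nearest for label volumes

# --- spot counting ----------------------------------------------------
spots:
  background_sigma: 15.0      # µm, Gaussian baseline scale
  detection_threshold: 20.0   # intensity above baseline
  min_separation: 4.0         # µm between accepted spots
  expected_spot_sigma: 2.0    # µm, approximate cell-blob width
# Physical counting boxes, e.g. a trunk region; "whole" is always added.
rois: []
# rois:
#   - name: trunk
#     lo: [0.0, 0.0, 120.0]     # µm (z, y, x), inclusive
#     hi: [382.5, 255.0, 255.0] # exclusive

# --- input ------------------------------------------------------------
input_path: null    # set to a TIFF/OME-TIFF path to skip simulation
spacing: null       # µm (z, y, x) override when metadata is missing
simulate:           # default synthetic embryo (ignored when input_path set)
  volume_shape: [256, 256, 256]
  voxel_spacing: [1.5, 1.0, 1.0]   # anisotropic, as in stage-scanned stacks
  sphere_center: null              # null = volume centre
  sphere_radius: 100.0
  shell_offset: 0.0                # cell layer right on the surface
  n_cells: 1500
  cell_sigma: 3.0
  cell_amplitude: 100.0
  yolk_amplitude: 0.0
  background: 5.0
  noise: {kind: poisson+gaussian, gaussian_sigma: 1.0, gain: 1.0}
  min_cell_separation: 6.0
  seed: 0

output_dir: embryomap_out
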