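"""Embryo surface estimation: binning, adaptive binarization, boundary
point cloud extraction and algebraic least-squares sphere fitting.

The pipeline mirrors the standard pre-processing of fused light-sheet
embryo volumes: the volume is mean-binned (default ×4 per axis) for
speed, binarized with a local-mean adaptive threshold (default
sensitivity 0.4), the boundary voxels of the largest connected
foreground component form the surface point cloud, and a sphere is fit
by linear least squares on the algebraic equation

    x² + y² + z² = 2ax + 2by + 2cz + d,

giving centre (a, b, c) and radius √(a² + b² + c² + d).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "BinaryMask",
    "SurfacePointCloud",
    "SphereModel",
    "DegenerateGeometryError",
    "bin_volume",
    "default_window",
    "adaptive_binarize",
    "extract_surface",
    "fit_sphere",
    "estimate_sphere",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised when a sphere fit is impossible (too few / coplanar points)."""


@dataclass
class BinaryMask:
    """3D boolean foreground mask with its (post-binning) spacing in µm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class SurfacePointCloud:
    """Physical µm coordinates of surface points."""

    points: np.ndarray  # (n, 3), (z, y, x) µm
    provenance: Literal["boundary_voxels", "mesh_vertices"] = "boundary_voxels"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SphereModel:
    """Fitted embryo surface: centre and radius in µm."""

    center: tuple[float, float, float]
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "center_um": list(self.center),
                    "radius_um": self.radius,
                    "rms_residual_um": self.rms_residual,
                    "n_points": self.n_points,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SphereModel":
        d = json.loads(Path(path).read_text())
        return cls(
            center=tuple(d["center_um"]),
            radius=float(d["radius_um"]),
            rms_residual=float(d["rms_residual_um"]),
            n_points=int(d["n_points"]),
        )


def _bin_axis(a: np.ndarray, factor: int, axis: int) -> np.ndarray:
    n = a.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(a, starts, axis=axis)
    counts = np.diff(np.append(starts, n)).astype(float)
    shape = [1] * a.ndim
    shape[axis] = len(starts)
    return sums / counts.reshape(shape)


def bin_volume(volume: VoxelVolume, factor: int | Sequence[int] = (4, 4, 4)) -> VoxelVolume:
    """Downsample by block averaging.

    Each output voxel is the mean of its ``factor``-block; a trailing
    partial block is averaged over the voxels it actually contains, so
    intensities stay on the same scale (mean, not sum, binning — local
    thresholds remain comparable across binning factors). Output spacing
    is input spacing × factor.
    """
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    factor = tuple(int(f) for f in factor)
    for f, n in zip(factor, volume.data.shape):
        if f < 1:
            raise ValueError(f"binning factor must be >= 1, got {f}")
        if f > n:
            raise ValueError(f"binning factor {f} exceeds axis length {n}")
    data = volume.data.astype(float, copy=False)
    for axis, f in enumerate(factor):
        if f > 1:
            data = _bin_axis(data, f, axis)
    spacing = tuple(s * f for s, f in zip(volume.spacing, factor))
    return VoxelVolume(data=np.ascontiguousarray(data), spacing=spacing,
                       timepoint=volume.timepoint)


def default_window(shape: Sequence[int]) -> tuple[int, ...]:
    """Per-axis adaptive-threshold window: smallest odd integer >= length/8,
    clipped to [3, axis length] (and kept odd)."""
    win = []
    for n in shape:
        w = max(3, int(np.ceil(n / 8.0)))
        if w % 2 == 0:
            w += 1
        if w > n:
            w = n if n % 2 == 1 else n - 1
        win.append(max(w, 1))
    return tuple(win)


def adaptive_binarize(
    volume: VoxelVolume,
    sensitivity: float = 0.4,
    window: int | Sequence[int] | None = None,
) -> BinaryMask:
    """Local-mean adaptive threshold.

    A voxel is foreground iff its intensity is >= c · local_mean with
    c = 2·(1 − sensitivity); the local mean is computed over ``window``
    (odd, per axis) with edge replication. Equality counts as foreground,
    which makes the foreground set monotone non-decreasing in
    sensitivity.
    """
    if volume.data.size == 0:
        raise ValueError("cannot binarize an empty volume")
    if not (0.0 <= sensitivity <= 1.0):
        raise ValueError(f"sensitivity must be in [0, 1], got {sensitivity}")
    if window is None:
        window = default_window(volume.data.shape)
    elif np.isscalar(window):
        window = (int(window),) * 3
    window = tuple(int(w) for w in window)
    for w, n in zip(window, volume.data.shape):
        if w % 2 == 0:
            raise ValueError(f"window must be odd per axis, got {window}")
        if w < 3 and n >= 3:
            raise ValueError(f"window must be >= 3, got {window}")
        if w > n:
            raise ValueError(f"window {w} exceeds axis length {n}")
    c = 2.0 * (1.0 - sensitivity)
    local_mean = ndimage.uniform_filter(
        volume.data.astype(float, copy=False), size=window, mode="nearest"
    )
    return BinaryMask(data=volume.data >= c * local_mean, spacing=volume.spacing)


def extract_surface(mask: BinaryMask) -> SurfacePointCloud:
    """Boundary voxels of the largest 26-connected foreground component.

    A boundary voxel is a foreground voxel with at least one background
    6-neighbour; the volume border counts as background. Coordinates are
    returned in physical µm.
    """
    fg = mask.data
    if not fg.any():
        raise ValueError("mask has no foreground voxels")
    labels, n_labels = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    if n_labels > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_labels + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
    else:
        comp = fg
    interior = ndimage.binary_erosion(
        comp, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    boundary = comp & ~interior
    points = np.argwhere(boundary) * np.asarray(mask.spacing)
    return SurfacePointCloud(points=points, provenance="boundary_voxels")


def fit_sphere(cloud: SurfacePointCloud | np.ndarray) -> SphereModel:
    """Algebraic linear least-squares sphere fit.

    Solves ``x² + y² + z² = 2ax + 2by + 2cz + d`` for (a, b, c, d);
    centre = (a, b, c), radius = √(a² + b² + c² + d). Exact on noiseless
    sphere samples and invariant under rigid translation. Needs at least
    four non-coplanar points.
    """
    pts = cloud.points if isinstance(cloud, SurfacePointCloud) else np.atleast_2d(
        np.asarray(cloud, dtype=float)
    )
    n = pts.shape[0]
    if n < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {n}")
    # centre the data for numerical conditioning; the fit is translation-
    # equivariant so the shift is added back exactly
    shift = pts.mean(axis=0)
    q = pts - shift
    A = np.column_stack([2.0 * q, np.ones(n)])
    b = np.einsum("ij,ij->i", q, q)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "degenerate point cloud: points are coplanar or otherwise "
            "rank-deficient; a sphere is not determined"
        )
    center_local, d = sol[:3], sol[3]
    rad2 = float(center_local @ center_local + d)
    if rad2 <= 0:
        raise DegenerateGeometryError(
            f"sphere fit produced non-positive squared radius ({rad2:.3g}); "
            "the point cloud does not describe a sphere"
        )
    radius = float(np.sqrt(rad2))
    center = center_local + shift
    residuals = np.linalg.norm(pts - center, axis=1) - radius
    return SphereModel(
        center=tuple(float(c) for c in center),
        radius=radius,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        n_points=n,
    )


def estimate_sphere(
    volume: VoxelVolume,
    binning: int | Sequence[int] = (4, 4, 4),
    sensitivity: float = 0.4,
    window: int | Sequence[int] | None = None,
) -> SphereModel:
    """End-to-end surface estimation: bin → binarize → boundary cloud → fit.

    The fitted centre is reported in the coordinates of the *unbinned*
    volume: binning by factor f places binned voxel 0 at the centre of
    its block, (f−1)/2 voxels into the original grid, so that constant
    shift is added back after the fit (the fit is translation-
    equivariant, so this is exact).
    """
    if np.isscalar(binning):
        binning = (int(binning),) * 3
    binned = bin_volume(volume, binning)
    mask = adaptive_binarize(binned, sensitivity=sensitivity, window=window)
    cloud = extract_surface(mask)
    logger.info(
        "surface estimation: %d boundary points from %s binned volume",
        len(cloud), "x".join(map(str, binned.data.shape)),
    )
    model = fit_sphere(cloud)
    origin_shift = [(f - 1) / 2.0 * s for f, s in zip(binning, volume.spacing)]
    return SphereModel(
        center=tuple(c + o for c, o in zip(model.center, origin_shift)),
        radius=model.radius,
        rms_residual=model.rms_residual,
        n_points=model.n_points,
    )
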