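"""Mercator map projection of concentric spherical shells of a volume.

A fitted sphere (see :mod:`embryomap.surface`) defines latitude/longitude
on the embryo surface, with the map's polar axis along the volume's z
axis. Each shell — the fitted radius plus a signed radial offset — is
unwrapped onto a 2D image whose columns are uniform in longitude and
whose rows are uniform in Mercator y

    y(φ) = R · ln(tan(π/4 + φ/2)),

the placement that makes the map conformal (locally angle-preserving),
which is the point of using Mercator for migration analysis on a sphere.
True Mercator cannot reach the poles, so the grid is truncated at a
configurable latitude (default 85°); an equirectangular mode (rows
uniform in latitude, reaching ±90°) is available for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

if TYPE_CHECKING:  # pragma: no cover
    from .surface import SphereModel

__all__ = [
    "ProjectionGrid",
    "MapLayerStack",
    "mercator_y",
    "inverse_mercator_latitude",
    "make_grid",
    "default_grid",
    "latlon_to_cartesian",
    "cartesian_to_latlon",
    "sample_volume",
    "project_layer",
    "project_multilayer",
    "max_project_layers",
    "layer_offsets",
]

GridMode = Literal["mercator", "equirect"]
Sampler = Literal["trilinear", "nearest"]


def mercator_y(latitude: float | np.ndarray, radius: float) -> float | np.ndarray:
    """Mercator northing ``R·ln(tan(π/4 + φ/2))`` in µm.

    ``latitude`` is in degrees and must satisfy ``|φ| < 90`` — the
    projection is singular at the poles. Odd in φ.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("Mercator projection is singular at |latitude| >= 90°")
    phi = np.deg2rad(lat)
    # asinh(tan φ) ≡ ln(tan(π/4 + φ/2)), but exactly 0 (and exactly odd) at φ=0
    out = radius * np.arcsinh(np.tan(phi))
    return float(out) if np.isscalar(latitude) else out


def inverse_mercator_latitude(y: float | np.ndarray, radius: float) -> float | np.ndarray:
    """Latitude (degrees) whose Mercator northing is ``y``: φ = 2·atan(e^{y/R}) − π/2."""
    yy = np.asarray(y, dtype=float)
    phi = 2.0 * np.arctan(np.exp(yy / radius)) - np.pi / 2.0
    out = np.rad2deg(phi)
    return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class ProjectionGrid:
    """Latitude/longitude sampling of the map image.

    Row 0 is the top of the map (the +truncation_latitude side); rows are
    uniform in Mercator y (``mercator`` mode) or in latitude
    (``equirect`` mode). Columns are uniform in longitude on [0°, 360°).
    ``reference_radius`` is the µm radius that scales Mercator y; the
    fitted sphere radius is used for all layers so layers stay
    pixel-aligned.
    """

    n_rows: int
    n_cols: int
    truncation_latitude: float
    reference_radius: float
    mode: GridMode = "mercator"
    latitudes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    longitudes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "n_rows": self.n_rows,
                    "n_cols": self.n_cols,
                    "truncation_latitude_deg": self.truncation_latitude,
                    "reference_radius_um": self.reference_radius,
                    "mode": self.mode,
                    "latitudes_deg": self.latitudes.tolist(),
                    "longitudes_deg": self.longitudes.tolist(),
                },
                indent=2,
            )
        )
        return path


def make_grid(
    n_rows: int,
    n_cols: int,
    truncation_latitude: float = 85.0,
    reference_radius: float = 1.0,
    mode: GridMode = "mercator",
) -> ProjectionGrid:
    """Build the map sampling grid.

    Column ``j``'s centre maps to longitude ``(j + 0.5)·360/n_cols``; row
    ``i``'s centre is placed uniformly in Mercator y over
    ``[−y(φmax), +y(φmax)]`` (or uniformly in latitude in ``equirect``
    mode) and row 0 is the +φmax side.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid needs n_rows >= 2 and n_cols >= 2")
    if mode == "mercator":
        if not (0.0 < truncation_latitude < 90.0):
            raise ValueError(
                "truncation latitude must lie in (0°, 90°): the Mercator "
                "projection has a pole singularity at ±90°"
            )
        ymax = mercator_y(truncation_latitude, reference_radius)
        y = ymax * (1.0 - (2.0 * np.arange(n_rows) + 1.0) / n_rows)
        lats = inverse_mercator_latitude(y, reference_radius)
    elif mode == "equirect":
        if not (0.0 < truncation_latitude <= 90.0):
            raise ValueError("truncation latitude must lie in (0°, 90°]")
        lats = truncation_latitude * (1.0 - (2.0 * np.arange(n_rows) + 1.0) / n_rows)
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    lons = (np.arange(n_cols) + 0.5) * 360.0 / n_cols
    return ProjectionGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        truncation_latitude=float(truncation_latitude),
        reference_radius=float(reference_radius),
        mode=mode,
        latitudes=np.asarray(lats, dtype=float),
        longitudes=lons,
    )


def default_grid(
    sphere: "SphereModel",
    min_spacing: float,
    truncation_latitude: float = 85.0,
    mode: GridMode = "mercator",
) -> ProjectionGrid:
    """Grid sized so the equator is sampled at roughly the voxel pitch.

    ``n_cols = round(2πR/d)`` with ``d`` the finest voxel spacing
    (Nyquist-ish at the equator); rows follow at the same scale.
    """
    R = sphere.radius
    n_cols = max(2, round(2.0 * math.pi * R / min_spacing))
    pixel = 2.0 * math.pi * R / n_cols
    if mode == "mercator":
        span = 2.0 * mercator_y(truncation_latitude, R)
    else:
        span = 2.0 * math.radians(truncation_latitude) * R
    n_rows = max(2, round(span / pixel))
    return make_grid(n_rows, n_cols, truncation_latitude, R, mode)


def latlon_to_cartesian(
    latitude: float | np.ndarray,
    longitude: float | np.ndarray,
    radius: float | np.ndarray,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Spherical → cartesian, returning ``(..., 3)`` µm points in (z, y, x).

    Latitude φ is measured from the equatorial plane (+90° = +z pole),
    longitude λ from the +x axis toward +y.
    """
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    lam = np.deg2rad(np.asarray(longitude, dtype=float))
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    cz, cy, cx = (float(c) for c in center)
    z = cz + r * np.sin(phi)
    y = cy + r * np.cos(phi) * np.sin(lam)
    x = cx + r * np.cos(phi) * np.cos(lam)
    return np.stack(np.broadcast_arrays(z, y, x), axis=-1)


def cartesian_to_latlon(
    points: np.ndarray, center: Sequence[float] = (0.0, 0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`latlon_to_cartesian`.

    Returns ``(latitude°, longitude° in [0, 360), radius µm)`` for
    ``(..., 3)`` points in (z, y, x) order.
    """
    p = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    dz, dy, dx = p[..., 0], p[..., 1], p[..., 2]
    r = np.sqrt(dz * dz + dy * dy + dx * dx)
    if np.any(r == 0):
        raise ValueError("point coincides with the sphere centre")
    lat = np.rad2deg(np.arcsin(np.clip(dz / r, -1.0, 1.0)))
    lon = np.rad2deg(np.arctan2(dy, dx)) % 360.0
    return lat, lon, r


def sample_volume(
    volume: VoxelVolume,
    points: np.ndarray,
    sampler: Sampler = "trilinear",
    fill_value: float = 0.0,
) -> np.ndarray | float:
    """Sample intensities at physical µm points.

    Trilinear interpolation in physical coordinates honours anisotropic
    spacing; points outside the voxel-centre bounding box return
    ``fill_value`` (out-of-bounds is a fill, never an error).
    """
    if sampler not in ("trilinear", "nearest"):
        raise ValueError(f"unknown sampler {sampler!r}")
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    coords = pts / np.asarray(volume.spacing)
    shape = np.asarray(volume.data.shape)
    inside = np.all((coords >= 0.0) & (coords <= shape - 1), axis=-1)
    order = 1 if sampler == "trilinear" else 0
    values = ndimage.map_coordinates(
        volume.data.astype(float, copy=False),
        coords.reshape(-1, 3).T,
        order=order,
        mode="nearest",
    ).reshape(coords.shape[:-1])
    values = np.where(inside, values, fill_value)
    return float(values[0]) if scalar else values


def project_layer(
    volume: VoxelVolume,
    sphere: "SphereModel",
    radial_offset: float,
    grid: ProjectionGrid,
    sampler: Sampler = "trilinear",
    fill_value: float = 0.0,
) -> np.ndarray:
    """Unwrap one spherical shell onto the map grid.

    ``image[i, j]`` is the volume sampled at the cartesian position of
    (grid row i latitude, grid col j longitude) at radius
    ``sphere.radius + radial_offset``.
    """
    r = sphere.radius + radial_offset
    if r <= 0:
        raise ValueError(
            f"sampling radius {r:.3f} µm (fitted radius {sphere.radius:.3f} "
            f"+ offset {radial_offset:+.3f}) is not positive"
        )
    lat = grid.latitudes[:, None]
    lon = grid.longitudes[None, :]
    pts = latlon_to_cartesian(lat, lon, r, sphere.center)
    return np.asarray(sample_volume(volume, pts, sampler, fill_value))


def layer_offsets(step: float = 2.0, depth_in: float = 10.0, depth_out: float = 0.0) -> np.ndarray:
    """Arithmetic radial offsets (µm) from ``−depth_in`` to ``+depth_out``.

    The 2 µm default step matches the shell spacing used for multi-layer
    embryo unwrapping.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_in = int(round(depth_in / step))
    n_out = int(round(depth_out / step))
    return step * np.arange(-n_in, n_out + 1, dtype=float)


@dataclass
class MapLayerStack:
    """Per-shell projected images indexed by radial offset (µm)."""

    offsets: np.ndarray
    layers: np.ndarray  # (n_layers, n_rows, n_cols)
    grid: ProjectionGrid
    sphere: "SphereModel"
    sampler: Sampler = "trilinear"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.layers = np.asarray(self.layers)
        if self.layers.ndim != 3 or len(self.offsets) != self.layers.shape[0]:
            raise ValueError("layers must be (n_layers, n_rows, n_cols) matching offsets")
        if self.layers.shape[1:] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("layer images must share the grid shape")

    def __len__(self) -> int:
        return self.layers.shape[0]


def project_multilayer(
    volume: VoxelVolume,
    sphere: "SphereModel",
    offsets: Sequence[float] | np.ndarray,
    grid: ProjectionGrid,
    sampler: Sampler = "trilinear",
    fill_value: float = 0.0,
) -> MapLayerStack:
    """Unwrap a stack of concentric shells, one layer per radial offset."""
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("at least one radial offset is required")
    layers = np.empty((offsets.size, grid.n_rows, grid.n_cols), dtype=float)
    for k, off in enumerate(offsets):
        try:
            layers[k] = project_layer(volume, sphere, float(off), grid, sampler, fill_value)
        except ValueError as exc:
            raise ValueError(f"layer at radial offset {off:+.3f} µm: {exc}") from exc
    return MapLayerStack(offsets, layers, grid, sphere, sampler, fill_value)


def max_project_layers(stack: MapLayerStack) -> np.ndarray:
    """Pixelwise maximum across all layers (maximum-intensity Mercator map)."""
    if len(stack) == 0:
        raise ValueError("empty layer stack")
    return stack.layers.max(axis=0)
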