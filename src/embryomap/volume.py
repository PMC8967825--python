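"""Voxel volumes with physical spacing, and TIFF/OME-TIFF I/O.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` = (planes, rows, cols);
* all physical coordinates and spacings are in micrometres (µm);
* voxel index ``i`` along an axis maps to physical coordinate
  ``i * spacing`` — the origin sits at the centre of the first voxel.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "VolumeIOError", "read_volume", "write_volume"]


class VolumeIOError(RuntimeError):
    """Raised when a volume cannot be read or lacks physical spacing."""


@dataclass
class VoxelVolume:
    """A 3D intensity array with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of non-negative intensities, axes ``(z, y, x)``.
    spacing
        Physical voxel spacing in µm per axis, same order as ``data``.
    timepoint
        Optional acquisition label (e.g. ``"1dpf"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values (µm), got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Coordinate of the last voxel centre per axis (µm)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as OME-TIFF with voxel spacing in the metadata."""
    path = Path(path)
    sz, sy, sx = volume.spacing
    try:
        tifffile.imwrite(
            path,
            volume.data,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeZ": sz,
                "PhysicalSizeY": sy,
                "PhysicalSizeX": sx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
            },
        )
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise VolumeIOError(f"cannot write volume to {path}: {exc}") from exc
    return path


def _spacing_from_ome(xml_text: str) -> tuple[float, float, float] | None:
    root = ET.fromstring(xml_text)
    ns = root.tag.split("}")[0].strip("{")
    px = root.find(f".//{{{ns}}}Pixels")
    if px is None:
        return None
    try:
        return (
            float(px.get("PhysicalSizeZ")),  # type: ignore[arg-type]
            float(px.get("PhysicalSizeY")),  # type: ignore[arg-type]
            float(px.get("PhysicalSizeX")),  # type: ignore[arg-type]
        )
    except (TypeError, ValueError):
        return None


def _spacing_from_imagej(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tf.imagej_metadata or {}
    if "spacing" not in meta:
        return None
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        sx = xres[1] / xres[0]
        sy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    return (float(meta["spacing"]), float(sy), float(sx))


def read_volume(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    timepoint: str | None = None,
) -> VoxelVolume:
    """Read a TIFF/OME-TIFF volume.

    Spacing resolution order: explicit ``spacing`` argument, then OME
    metadata, then ImageJ metadata. A plain TIFF without spacing and
    without an override is an error — spacing is never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"input volume not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_spacing = None
            if spacing is None:
                if tf.ome_metadata:
                    meta_spacing = _spacing_from_ome(tf.ome_metadata)
                if meta_spacing is None:
                    meta_spacing = _spacing_from_imagej(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise VolumeIOError(f"cannot read volume from {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    final = spacing if spacing is not None else meta_spacing
    if final is None:
        raise VolumeIOError(
            f"{path}: no voxel spacing in TIFF metadata; pass an explicit "
            "spacing override (µm per axis, z/y/x)"
        )
    return VoxelVolume(data=data, spacing=final, timepoint=timepoint)
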