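"""End-to-end orchestration: simulate → fit sphere → project → count.

A :class:`PipelineConfig` (YAML-serializable, round-trip exact) holds
every parameter the stages use — the defaults are the standard embryo
processing settings: ×4 binning, adaptive sensitivity 0.4, 2 µm layer
step, 85° Mercator truncation. A run writes all intermediate artifacts
(simulated volume + ground truth, sphere JSON, layer TIFF stack,
maximum-intensity map, counts CSV, spot JSON) plus a :class:`RunManifest`
recording the config snapshot, per-stage timings, input checksums and
output list. Runs are fully deterministic given (config, seed, inputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
import yaml

from . import __version__
from .projection import (
    MapLayerStack,
    default_grid,
    layer_offsets,
    max_project_layers,
    project_multilayer,
)
from .spots import ROIBox, SpotParams, quantify_timecourse
from .surface import SphereModel, estimate_sphere
from .synthetic import EmbryoSpec, NoiseModel, generate_volume, write_fixture
from .volume import VolumeIOError, VoxelVolume, read_volume, write_volume

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline",
           "write_map_stack"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _tupled(x: Any) -> Any:
    return tuple(x) if isinstance(x, (list, tuple)) else x


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate→fit→project→count pipeline."""

    seed: int = 0
    # surface estimation
    binning: tuple[int, int, int] = (4, 4, 4)
    sensitivity: float = 0.4
    window: tuple[int, int, int] | None = None
    # projection
    step_um: float = 2.0
    depth_in_um: float = 10.0
    depth_out_um: float = 4.0
    truncation_latitude: float = 85.0
    grid_mode: str = "mercator"
    sampler: str = "trilinear"
    # quantification
    spots: SpotParams = field(default_factory=SpotParams)
    rois: tuple[ROIBox, ...] = ()
    # input: either a volume on disk or a simulation spec
    input_path: str | None = None
    spacing: tuple[float, float, float] | None = None
    simulate: EmbryoSpec | None = field(default_factory=EmbryoSpec)
    output_dir: str = "embryomap_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain lists/scalars only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("binning", "window", "spacing"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("spots") is not None and not isinstance(d["spots"], SpotParams):
            d["spots"] = SpotParams(**d["spots"])
        if d.get("rois"):
            d["rois"] = tuple(
                r if isinstance(r, ROIBox)
                else ROIBox(name=r["name"], lo=tuple(r["lo"]), hi=tuple(r["hi"]))
                for r in d["rois"]
            )
        else:
            d["rois"] = ()
        sim = d.get("simulate")
        if sim is not None and not isinstance(sim, EmbryoSpec):
            sim = dict(sim)
            for key in ("volume_shape", "voxel_spacing", "sphere_center"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            if sim.get("noise") is not None and not isinstance(sim["noise"], NoiseModel):
                sim["noise"] = NoiseModel(**sim["noise"])
            d["simulate"] = EmbryoSpec(**sim)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Provenance record written exactly once per pipeline run."""

    config: dict
    version: str
    timings_s: dict[str, float]
    input_checksums: dict[str, str]
    outputs: list[str]
    completed: bool

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def write_map_stack(stack: MapLayerStack, path: str | Path) -> Path:
    """Write layers as a multi-page TIFF with per-layer offsets in the
    image description; the grid goes to a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.layers.astype(np.float32),
        photometric="minisblack",  # 3-layer stacks must not be guessed as RGB
        description=json.dumps(
            {"radial_offsets_um": stack.offsets.tolist(), "sampler": stack.sampler}
        ),
    )
    stack.grid.to_json(path.with_suffix(".grid.json"))
    return path


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; see the module docstring for artifacts."""
    out = Path(config.output_dir)
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    outputs: list[str] = []
    handler = None

    def _stage(name: str):
        logger.info("stage: %s", name)
        return time.perf_counter()

    # -- resolve input BEFORE creating any outputs, so a missing path
    #    leaves nothing behind
    t0 = _stage("input")
    if config.input_path is not None:
        volume = read_volume(config.input_path, spacing=config.spacing)
        checksums[str(config.input_path)] = _sha256(Path(config.input_path).read_bytes())
        truth = None
    elif config.simulate is not None:
        spec = replace(config.simulate, seed=int(config.seed))
        volume, truth = generate_volume(spec)
        checksums["simulated_volume"] = _sha256(np.ascontiguousarray(volume.data).tobytes())
    else:
        raise PipelineError("stage 'input': no input_path and no simulation spec")
    timings["input"] = time.perf_counter() - t0

    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("embryomap").addHandler(handler)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        timings_s=timings,
        input_checksums=checksums,
        outputs=outputs,
        completed=False,
    )
    try:
        if truth is not None:
            paths = write_fixture(volume, truth, out)
            outputs.extend(str(p) for p in paths)
        elif config.input_path is None:  # pragma: no cover
            pass

        t0 = _stage("fit-sphere")
        logger.info(
            "parameters: binning=%s sensitivity=%s window=%s",
            config.binning, config.sensitivity, config.window,
        )
        sphere = estimate_sphere(
            volume, binning=config.binning, sensitivity=config.sensitivity,
            window=config.window,
        )
        outputs.append(str(sphere.to_json(out / "sphere.json")))
        timings["fit-sphere"] = time.perf_counter() - t0

        t0 = _stage("project")
        logger.info(
            "parameters: step=%s µm, depth_in=%s µm, depth_out=%s µm, "
            "truncation=%s°, mode=%s, sampler=%s",
            config.step_um, config.depth_in_um, config.depth_out_um,
            config.truncation_latitude, config.grid_mode, config.sampler,
        )
        grid = default_grid(
            sphere, min(volume.spacing), config.truncation_latitude, config.grid_mode
        )
        offsets = layer_offsets(config.step_um, config.depth_in_um, config.depth_out_um)
        stack = project_multilayer(volume, sphere, offsets, grid, config.sampler)
        outputs.append(str(write_map_stack(stack, out / "layers.tif")))
        outputs.append(str(out / "layers.grid.json"))
        maxmap = max_project_layers(stack)
        tifffile.imwrite(out / "max_projection.tif", maxmap.astype(np.float32))
        outputs.append(str(out / "max_projection.tif"))
        timings["project"] = time.perf_counter() - t0

        t0 = _stage("count")
        logger.info("parameters: %s, %d ROIs", config.spots, len(config.rois))
        label = volume.timepoint or "t0"
        table = quantify_timecourse(
            [("embryo1", "na", label, volume)], config.spots, config.rois
        )
        table.to_csv(out / "counts.csv", index=False)
        outputs.append(str(out / "counts.csv"))
        timings["count"] = time.perf_counter() - t0
        manifest.completed = True
    except Exception as exc:
        manifest.completed = False
        manifest.to_json(out / "manifest.json")
        raise PipelineError(f"pipeline aborted: {exc}") from exc
    finally:
        if handler is not None:
            logging.getLogger("embryomap").removeHandler(handler)
            handler.close()
    manifest.to_json(out / "manifest.json")
    outputs.append(str(out / "manifest.json"))
    return manifest
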