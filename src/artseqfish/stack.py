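"""The 5-axis image container shared by all pipeline stages.

An :class:`ImageStack` holds intensities indexed (round, channel, z, y, x)
plus the physical calibration (lateral pixel size and 0.5-um z-step by
default) and the channel labels.  An optional per-round nuclear-stain volume
(round, z, y, x) travels with the stack so segmentation and registration can
use the nuclei as fiducials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    data: np.ndarray  # (round, channel, z, y, x), non-negative
    pixel_size_um: float
    z_step_um: float = 0.5
    channels: tuple[str, ...] = ("ATTO488", "TAMRA", "CY5")
    dapi: np.ndarray | None = None  # (round, z, y, x) nuclear stain
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 5:
            raise ValueError(f"expected (round, channel, z, y, x) data, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"channel axis ({self.data.shape[1]}) does not match labels {self.channels}")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel size and z-step must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_rounds(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def volume(self, round_index: int, channel: int | str) -> np.ndarray:
        """The 3D (z, y, x) volume of one hybridisation round and channel."""
        if isinstance(channel, str):
            channel = self.channels.index(channel)
        return self.data[round_index, channel]

    def with_data(self, data: np.ndarray, **meta) -> "ImageStack":
        new = replace(self, data=data)
        new.metadata = {**self.metadata, **meta}
        return new

    def voxel_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert (z, y, x) voxel coordinates to micrometres."""
        zyx = np.asarray(zyx, dtype=float)
        scale = np.array([self.z_step_um, self.pixel_size_um, self.pixel_size_um])
        return zyx * scale

    def um_to_voxel(self, um: np.ndarray) -> np.ndarray:
        um = np.asarray(um, dtype=float)
        scale = np.array([self.z_step_um, self.pixel_size_um, self.pixel_size_um])
        return um / scale


def write_stack(stack: ImageStack, out_dir: str | Path) -> Path:
    """Write one multi-page TIFF per (round, channel) plus a manifest JSON.

    The manifest maps each (round, channel) to its file and records the
    calibration, so a run never has to parse microscope filename patterns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for r in range(stack.n_rounds):
        for ci, ch in enumerate(stack.channels):
            name = f"round{r:02d}_{ch}.tif"
            tifffile.imwrite(out_dir / name, stack.data[r, ci])
            files[f"{r}:{ch}"] = name
    dapi_files = {}
    if stack.dapi is not None:
        for r in range(stack.dapi.shape[0]):
            name = f"round{r:02d}_DAPI.tif"
            tifffile.imwrite(out_dir / name, stack.dapi[r].astype(np.float32))
            dapi_files[str(r)] = name
    manifest = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "channels": list(stack.channels),
        "n_rounds": stack.n_rounds,
        "shape_zyx": list(stack.shape_zyx),
        "files": files,
        "dapi_files": dapi_files,
        "metadata": {k: v for k, v in stack.metadata.items()
                     if isinstance(v, (str, int, float, bool, list))},
    }
    manifest_path = out_dir / "stack_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_stack(manifest_path: str | Path) -> ImageStack:
    manifest_path = Path(manifest_path)
    m = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    channels = tuple(m["channels"])
    shape = tuple(m["shape_zyx"])
    data = np.zeros((m["n_rounds"], len(channels)) + shape, dtype=np.float32)
    for key, name in m["files"].items():
        r_str, ch = key.split(":", 1)
        data[int(r_str), channels.index(ch)] = tifffile.imread(base / name)
    dapi = None
    if m.get("dapi_files"):
        dapi = np.stack([tifffile.imread(base / m["dapi_files"][str(r)])
                         for r in sorted(int(k) for k in m["dapi_files"])])
    return ImageStack(data=data, pixel_size_um=m["pixel_size_um"],
                      z_step_um=m["z_step_um"], channels=channels, dapi=dapi,
                      metadata=m.get("metadata", {}))
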