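"""File formats: TIFF stacks with voxel-size metadata, CSV tables,
JSON transforms.

Stacks are written as plain TIFF plus a JSON sidecar
(``<name>.tif.meta.json``) recording voxel size (µm), axis order and
channel names; on read the sidecar takes precedence, falling back to
ImageJ-style TIFF metadata.  A stack without any voxel-size source is
an error — isotropy is never silently assumed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .registration import RigidTransform
from .stack import ImageStack3D

__all__ = [
    "save_stack",
    "load_stack",
    "save_labels",
    "load_labels",
    "save_transform",
    "load_transform",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def save_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Write a stack as TIFF with a JSON voxel-size sidecar."""
    path = Path(path)
    axes = "CZYX" if stack.voxels.ndim == 4 else "ZYX"
    dz, dy, dx = stack.voxel_size_um
    data = np.asarray(stack.voxels, dtype=np.float32)
    if stack.voxels.ndim == 3:
        # ImageJ-compatible metadata so the stack opens with correct spacing
        tifffile.imwrite(
            path, data, imagej=True, resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "um", "axes": axes},
        )
    else:
        # multi-channel: plain TIFF, the sidecar is authoritative
        tifffile.imwrite(path, data, resolution=(1.0 / dx, 1.0 / dy))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_um": list(stack.voxel_size_um),
                "axes": axes,
                "channel_names": list(stack.channel_names),
            }
        )
    )


def load_stack(path: str | Path) -> ImageStack3D:
    """Read a TIFF stack; voxel size from sidecar or ImageJ metadata.

    Raises if the file is 2D (no z axis) or if no voxel size can be
    found in either source.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim < 3:
        raise ValueError(f"{path.name}: 2D image has no z axis; expected a 3D stack")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = tuple(meta["voxel_size_um"])
        channels = tuple(meta.get("channel_names", ()))
    else:
        with tifffile.TiffFile(path) as tif:
            ij = tif.imagej_metadata or {}
            page = tif.pages[0]
            try:
                xres = page.tags["XResolution"].value
                yres = page.tags["YResolution"].value
                dx = xres[1] / xres[0]
                dy = yres[1] / yres[0]
            except KeyError:
                dx = dy = None
            dz = ij.get("spacing")
        if dz is None or dx is None:
            raise ValueError(
                f"{path.name}: no voxel size found (no sidecar, no ImageJ metadata); "
                "voxel size must be explicit"
            )
        voxel_size = (float(dz), float(dy), float(dx))
        channels = ()
    if data.ndim == 4 and not channels:
        channels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack3D(data, voxel_size, channels)


def save_labels(labels: np.ndarray, voxel_size_um, path: str | Path) -> None:
    labels = np.asarray(labels)
    # ImageJ TIFFs accept uint16; fall back to float32 for huge label counts
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.float32
    stack = ImageStack3D(labels.astype(dtype), voxel_size_um)
    path = Path(path)
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path, stack.voxels, imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar_path(path).write_text(
        json.dumps({"voxel_size_um": list(stack.voxel_size_um), "axes": "ZYX",
                    "channel_names": []})
    )


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    stack = load_stack(path)
    return stack.voxels.astype(np.int32), stack.voxel_size_um


def save_transform(transform: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=2))


def load_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))
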