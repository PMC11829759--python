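"""In-memory container for 3D multi-channel image stacks.

Axis order is fixed as ``(channel,) z, y, x``; physical spacing is carried
per axis in micrometres so that anisotropic confocal stacks (coarse z,
fine xy) are handled explicitly everywhere.  Positions follow the
voxel-centre convention: the centre of voxel ``(0, 0, 0)`` sits at the
physical origin and voxel ``(i, j, k)`` is centred at
``(i*dz, j*dy, k*dx)`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack3D"]


@dataclass
class ImageStack3D:
    """A 3D (or multi-channel 4D) intensity volume with physical spacing.

    Parameters
    ----------
    voxels:
        Non-negative intensity array, shape ``(z, y, x)`` for a single
        channel or ``(c, z, y, x)`` for multiple channels.
    voxel_size_um:
        Spacing ``(dz, dy, dx)`` in micrometres, all strictly positive.
    channel_names:
        One name per channel; unique.  Optional for single-channel data.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"voxels must be 3D (z,y,x) or 4D (c,z,y,x), got ndim={self.voxels.ndim}"
            )
        self.voxel_size_um = tuple(float(s) for s in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"voxel_size_um must be 3 positive reals, got {self.voxel_size_um}")
        self.channel_names = tuple(self.channel_names)
        if self.voxels.ndim == 4:
            if len(self.channel_names) != self.voxels.shape[0]:
                raise ValueError(
                    f"{self.voxels.shape[0]} channels but "
                    f"{len(self.channel_names)} channel names"
                )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel names must be unique: {self.channel_names}")

    # -- structure ---------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0] if self.voxels.ndim == 4 else 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape[-3:])

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array of a named channel."""
        if self.voxels.ndim == 3:
            if self.channel_names and self.channel_names != (name,):
                raise KeyError(name)
            return self.voxels
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None
        return self.voxels[idx]

    def single_channel(self, name: str) -> "ImageStack3D":
        """A new single-channel stack holding the named channel."""
        return ImageStack3D(self.channel(name), self.voxel_size_um, (name,))

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack3D":
        """Same geometry/channels, different intensity data."""
        return replace(self, voxels=voxels)

    def map_channels(self, func) -> "ImageStack3D":
        """Apply ``func`` independently to every channel's 3D array."""
        if self.voxels.ndim == 3:
            return self.with_voxels(func(self.voxels))
        out = np.stack([func(self.voxels[c]) for c in range(self.n_channels)])
        return self.with_voxels(out)
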