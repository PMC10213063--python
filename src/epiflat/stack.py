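"""Core image-stack container shared by the generator, reader, and pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical axis order for voxel data: (channel, z, y, x).
AXIS_ORDER = ("c", "z", "y", "x")

DEFAULT_CHANNELS = ("junctional", "morphogen", "reference", "factin")


@dataclass
class ImageStack:
    """Multi-channel 3D voxel array with physical voxel dimensions.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)``.  Single-channel stacks
        use ``n_channels == 1``.
    dx, dy, dz
        Voxel size in micrometres along x, y, z.
    channel_names
        One name per channel, in data order.
    """

    data: np.ndarray
    dx: float = 0.21
    dy: float = 0.21
    dz: float = 0.45
    channel_names: tuple[str, ...] = field(default=DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 3D or 4D, got shape {self.data.shape}"
            )
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel dimensions must be positive")
        self.channel_names = tuple(self.channel_names)[: self.data.shape[0]]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def nz(self) -> int:
        return self.data.shape[1]

    @property
    def ny(self) -> int:
        return self.data.shape[2]

    @property
    def nx(self) -> int:
        return self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(nz, ny, nx)`` volume for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def plane(self, name: str, y: int) -> np.ndarray:
        """Return the x-z plane (shape ``(nz, nx)``) of a channel at row y."""
        return self.channel(name)[:, y, :]

    def crop(
        self, x0: int = 0, x1: int | None = None, y0: int = 0, y1: int | None = None
    ) -> "ImageStack":
        """Crop in x and y, keeping the full z-extent and all channels."""
        return ImageStack(
            self.data[:, :, y0:y1, x0:x1].copy(),
            dx=self.dx,
            dy=self.dy,
            dz=self.dz,
            channel_names=self.channel_names,
        )

    def quantize_uint16(self) -> np.ndarray:
        """Optional 16-bit quantization of the float data (clipped to [0, 1])."""
        return (np.clip(self.data, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
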