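"""Stack reading/writing (multi-page TIFF / OME-TIFF + JSON sidecar)."""
from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .stack import DEFAULT_CHANNELS, ImageStack

logger = logging.getLogger("epiflat")


class StackIOError(RuntimeError):
    """Unreadable stack or channel-layout mismatch."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, ome: bool = True) -> Path:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar.

    OME mode embeds axes and physical voxel size in the TIFF itself; the
    sidecar is always written so channel names and voxel size survive plain
    TIFF round trips too.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ome:
        tifffile.imwrite(
            path,
            stack.data,
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeX": stack.dx,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.dy,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": stack.dz,
                "PhysicalSizeZUnit": "µm",
            },
        )
    else:
        tifffile.imwrite(path, stack.data)
    sidecar = {
        "axes": "CZYX",
        "dx": stack.dx,
        "dy": stack.dy,
        "dz": stack.dz,
        "channel_names": list(stack.channel_names),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _ome_voxel_size(tif: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    if not tif.ome_metadata:
        return None
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:  # pragma: no cover - malformed metadata
        return None
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            try:
                return (
                    float(pixels.attrib["PhysicalSizeX"]),
                    float(pixels.attrib["PhysicalSizeY"]),
                    float(pixels.attrib["PhysicalSizeZ"]),
                )
            except KeyError:
                return None
    return None


def read_stack(
    path: str | Path,
    dx: float = 0.21,
    dy: float = 0.21,
    dz: float = 0.45,
    channel_names: Optional[tuple[str, ...]] = None,
    expected_channels: Optional[int] = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack into canonical (c, z, y, x) order.

    Voxel size priority: embedded OME metadata, then the JSON sidecar, then
    the supplied config values (an override by metadata is logged).  3D files
    are treated as single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"stack file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            ome_voxels = _ome_voxel_size(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise StackIOError(f"cannot read {path}: {exc}") from exc

    sidecar_file = _sidecar_path(path)
    sidecar = (
        json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    )
    if ome_voxels is not None:
        if (dx, dy, dz) != ome_voxels:
            logger.info(
                "%s: OME voxel size %s overrides configured (%g, %g, %g)",
                path.name, ome_voxels, dx, dy, dz,
            )
        dx, dy, dz = ome_voxels
    elif sidecar:
        dx = sidecar.get("dx", dx)
        dy = sidecar.get("dy", dy)
        dz = sidecar.get("dz", dz)

    if channel_names is None:
        channel_names = tuple(
            sidecar.get("channel_names", [])
        ) or DEFAULT_CHANNELS

    data = np.asarray(data)
    if data.ndim == 3:
        data = data[np.newaxis]
        channel_names = channel_names[:1] or ("channel0",)
    if data.ndim != 4:
        raise StackIOError(
            f"{path}: expected a 3D or 4D stack, got shape {data.shape}"
        )
    if expected_channels is not None and data.shape[0] != expected_channels:
        raise StackIOError(
            f"{path}: expected {expected_channels} channels, found "
            f"{data.shape[0]}"
        )
    if len(channel_names) < data.shape[0]:
        channel_names = tuple(channel_names) + tuple(
            f"channel{i}" for i in range(len(channel_names), data.shape[0])
        )
    return ImageStack(
        data, dx=dx, dy=dy, dz=dz, channel_names=channel_names[: data.shape[0]]
    )


def average_stacks(stacks: list[ImageStack]) -> ImageStack:
    """Simple average of repeated registered acquisitions of one field."""
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    for s in stacks[1:]:
        if s.data.shape != first.data.shape:
            raise ValueError("stacks to average must share a shape")
    mean = np.mean([s.data for s in stacks], axis=0)
    return ImageStack(
        mean, dx=first.dx, dy=first.dy, dz=first.dz,
        channel_names=first.channel_names,
    )
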