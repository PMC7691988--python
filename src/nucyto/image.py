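"""Multi-channel image container and TIFF round-trip.

Images are indexed ``(row, column)`` with 0-based pixel coordinates;
physical coordinates are ``pixel index x pixel_size`` (micrometres).
A channel may be a single 2-D plane or a 3-D z-stack ``(planes, rows,
columns)``; stacks are summed before quantification (see
:func:`nucyto.quantify.zstack_project_sum`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = ["MultiChannelImage", "read_tiff", "write_tiff"]


@dataclass
class MultiChannelImage:
    """Named fluorescence channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"dna"``, ``"marker"``,
        ``"actin"``, ``"pattern"``) to a 2-D plane or 3-D z-stack.
    pixel_size
        Physical pixel size in micrometres per pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {name: arr.shape[-2:] for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel plane shapes differ: {shapes}")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[-2:]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def write_tiff(image: MultiChannelImage, path: str | Path) -> Path:
    """Write channels as pages of one TIFF; names and pixel size in metadata."""
    path = Path(path)
    names, pages = [], []
    for name, arr in image.channels.items():
        arr = np.asarray(arr, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        names.append(name)
        pages.append(arr)
    planes_per_channel = [p.shape[0] for p in pages]
    desc = json.dumps(
        {
            "channel_names": names,
            "planes_per_channel": planes_per_channel,
            "pixel_size_um": image.pixel_size,
            **image.metadata,
        }
    )
    tifffile.imwrite(
        path,
        np.concatenate(pages, axis=0),
        description=desc,
        photometric="minisblack",
    )
    return path


def read_tiff(path: str | Path) -> MultiChannelImage:
    """Read a TIFF written by :func:`write_tiff` (or a bare stack).

    Without nucyto metadata a single-page file becomes channel
    ``"channel0"`` etc. and the pixel size defaults to 1 um/px.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    meta: Mapping = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    names = meta.get("channel_names")
    if names is None:
        names = [f"channel{i}" for i in range(data.shape[0])]
        planes = [1] * data.shape[0]
    else:
        planes = meta.get("planes_per_channel", [1] * len(names))
    channels: dict[str, np.ndarray] = {}
    i = 0
    for name, n in zip(names, planes):
        block = data[i : i + n]
        channels[name] = block[0] if n == 1 else block
        i += n
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("channel_names", "planes_per_channel", "pixel_size_um")
    }
    return MultiChannelImage(channels=channels, pixel_size=pixel_size, metadata=extra)
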