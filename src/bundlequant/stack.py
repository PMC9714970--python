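"""Multi-channel 3D stack container and OME-TIFF / mask / JSON I/O.

The in-memory container is :class:`VolumeStack`: a ``(channel, z, y, x)``
array of non-negative intensities plus the physical voxel size in
micrometres and one label per channel.  Stacks round-trip losslessly
through OME-TIFF (``PhysicalSizeX/Y/Z`` and channel names carried in the
OME metadata block); boolean masks are stored either as plain TIFFs or as
run-length-encoded JSON.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VolumeStack",
    "RoiBox",
    "SegmentationMask",
    "IntensitySummary",
    "read_stack",
    "write_stack",
    "rle_encode",
    "rle_decode",
]


@dataclass
class VolumeStack:
    """Multi-channel confocal stack with physical voxel size.

    Parameters
    ----------
    voxels
        Intensities indexed ``(channel, z, y, x)``; non-negative.
    voxel_size
        Physical voxel edge lengths ``(z, y, x)`` in µm; all > 0.
    channel_names
        One label per channel, e.g. ``("PM", "D4H")``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be 4-D (channel, z, y, x); got shape {self.voxels.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{self.voxels.shape[0]} channels but {len(self.channel_names)} channel names"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)`` in voxels."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        return self.voxels[self.channel_index(name_or_index)]

    def channel_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            idx = int(name_or_index)
            if not 0 <= idx < len(self.channel_names):
                raise KeyError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_names.index(str(name_or_index))
        except ValueError:
            raise KeyError(
                f"channel {name_or_index!r} not in {list(self.channel_names)}"
            ) from None


@dataclass
class RoiBox:
    """Axis-aligned box in physical coordinates.

    ``origin`` and ``extent`` are ``(z, y, x)`` in µm.  Conversion to voxel
    indices rounds outward: the origin is floored and the far edge is
    ceiled, so the voxel box always covers the requested physical box.
    """

    origin: tuple[float, float, float]
    extent: tuple[float, float, float]
    channel: str | int | None = None

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent):
            raise ValueError(f"extent components must be > 0, got {self.extent}")

    def to_slices(
        self, voxel_size: Sequence[float], shape: Sequence[int]
    ) -> tuple[slice, slice, slice]:
        """Convert to ``(z, y, x)`` voxel slices, validating stack bounds."""
        slices = []
        for o, e, v, n in zip(self.origin, self.extent, voxel_size, shape):
            lo = math.floor(o / v + 1e-9)
            hi = math.ceil((o + e) / v - 1e-9)
            if lo < 0 or hi > n:
                raise ValueError(
                    f"ROI [{o}, {o + e}) µm -> voxels [{lo}, {hi}) outside stack "
                    f"axis of {n} voxels"
                )
            slices.append(slice(lo, hi))
        return tuple(slices)


@dataclass
class SegmentationMask:
    """Boolean voxel mask aligned to one stack channel, with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D (z, y, x); got shape {self.mask.shape}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class IntensitySummary:
    """Voxel count, sum, mean and per-slice sums of a selection.

    An empty selection has ``sum == 0`` and an explicitly undefined mean
    (``mean_defined`` is False and ``mean`` is NaN) — never a silent zero.
    """

    voxel_count: int
    sum: float
    mean: float
    per_slice_sums: np.ndarray
    mean_defined: bool

    @classmethod
    def from_values(cls, values: np.ndarray, per_slice_sums: np.ndarray) -> "IntensitySummary":
        n = int(values.size)
        total = float(values.sum()) if n else 0.0
        if n:
            return cls(n, total, total / n, per_slice_sums, True)
        return cls(0, 0.0, float("nan"), per_slice_sums, False)


# ---------------------------------------------------------------------------
# OME-TIFF I/O

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def write_stack(path: str | Path, stack: VolumeStack) -> None:
    """Write a stack as OME-TIFF with PhysicalSizeX/Y/Z and channel names."""
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        str(path),
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> VolumeStack:
    """Read an OME-TIFF/TIFF stack.

    Voxel size is taken from the OME ``PhysicalSize*`` metadata; plain
    TIFFs without physical-size metadata require the ``voxel_size``
    override, otherwise a descriptive error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    meta_size = None
    meta_channels: list[str] | None = None
    if ome:
        root = ET.fromstring(ome)
        pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
        if pixels is not None:
            try:
                meta_size = (
                    float(pixels.attrib["PhysicalSizeZ"]),
                    float(pixels.attrib["PhysicalSizeY"]),
                    float(pixels.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                meta_size = None
            names = [
                ch.attrib.get("Name", f"channel_{i}")
                for i, ch in enumerate(pixels.findall(f"{_OME_NS}Channel"))
            ]
            meta_channels = names or None
    if voxel_size is None:
        voxel_size = meta_size
    if voxel_size is None:
        raise ValueError(
            f"{path}: no PhysicalSizeX/Y/Z metadata found and no voxel_size override given"
        )
    data = np.asarray(data)
    if data.ndim == 3:
        data = data[np.newaxis]
    elif data.ndim != 4:
        raise ValueError(f"{path}: expected 3-D or 4-D data, got shape {data.shape}")
    if channel_names is None:
        if meta_channels is not None and len(meta_channels) == data.shape[0]:
            channel_names = meta_channels
        else:
            channel_names = [f"channel_{i}" for i in range(data.shape[0])]
    return VolumeStack(data, voxel_size, tuple(channel_names))


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(bool)


# ---------------------------------------------------------------------------
# Run-length encoding for boolean masks (JSON-friendly ground truth)


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean array (C-order) as {shape, runs}.

    Runs are ``[start, length]`` pairs over the flattened array.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    # boundaries where the value changes
    diff = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate(([0], diff + 1))
    ends = np.concatenate((diff + 1, [flat.size]))
    runs = [
        [int(s), int(e - s)] for s, e in zip(starts, ends) if flat.size and flat[s]
    ]
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    shape = tuple(encoded["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in encoded["runs"]:
        flat[start : start + length] = True
    return flat.reshape(shape)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
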