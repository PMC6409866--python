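"""Raster containers and multi-channel micrograph I/O.

Fluorescence fields are small multi-channel 2D images: one counterstain
(DAPI) plane that defines nuclear shape, plus one or two FISH signal
planes. All downstream geometry uses the raster pixel frame: pixel (0,0)
at the top-left, x rightward, y downward, pixel centres at integer
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import imageio.v3 as iio
import tifffile

CHANNEL_ROLES = ("counterstain", "signal_A", "signal_B")


class ChannelMapError(ValueError):
    """A channel map does not cover the roles an operation requires."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-size calibration of an acquisition, in microns per pixel."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    def px2_to_um2(self, n_pixels: float) -> float:
        """Convert a pixel count (area) to square microns."""
        return float(n_pixels) * self.microns_per_pixel**2


@dataclass
class ChannelRaster:
    """A single fluorochrome plane of a field image.

    ``pixels`` is an unsigned 8- or 16-bit array; the dtype is the recorded
    bit depth and is preserved on round-trip through :func:`write_raster`.
    """

    pixels: np.ndarray
    channel_role: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {self.pixels.shape}")
        if self.pixels.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"bit depth must be 8 or 16 (uint8/uint16), got {self.pixels.dtype}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16


@dataclass
class FieldImage:
    """One captured field: co-registered channel rasters plus calibration."""

    channels: dict[str, ChannelRaster]
    calibration: Calibration
    source_path: str = ""

    def __post_init__(self) -> None:
        if "counterstain" not in self.channels:
            raise ChannelMapError("a FieldImage requires exactly one counterstain channel")
        shapes = {c.pixels.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share dimensions, got {shapes}")
        for role, ch in self.channels.items():
            if ch.channel_role != role:
                raise ValueError(f"channel stored under {role!r} has role {ch.channel_role!r}")

    @property
    def counterstain(self) -> ChannelRaster:
        return self.channels["counterstain"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counterstain.pixels.shape

    def signal_roles(self) -> list[str]:
        return [r for r in self.channels if r != "counterstain"]


def _read_planes(path: Path) -> np.ndarray:
    """Read a TIFF/PNG as an array of planes, shape (n_planes, H, W)."""
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3:
        # channel-last (H, W, C<=4) images come from RGB(A) PNG readers
        if arr.shape[-1] <= 4 and arr.shape[0] > 4:
            arr = np.moveaxis(arr, -1, 0)
    else:
        raise OSError(f"{path}: expected a 2D image or a stack of planes, got shape {arr.shape}")
    return arr


def read_field(
    path: str | Path | Mapping[str, str | Path],
    channel_map: Mapping[int, str] | None = None,
    calibration: Calibration = Calibration(0.05),
) -> FieldImage:
    """Read a multi-channel field from one multi-plane file or several files.

    Parameters
    ----------
    path
        Either a single TIFF/PNG path whose planes are assigned roles via
        ``channel_map`` (plane index -> role), or a mapping of role ->
        single-channel file path.
    channel_map
        Required for single-path input; ignored for per-role file input.
    calibration
        Pixel size of the acquisition.

    Grayscale planes are used as-is; no colour conversion is applied.
    """
    channels: dict[str, ChannelRaster] = {}
    if isinstance(path, Mapping):
        for role, p in path.items():
            p = Path(p)
            if not p.exists():
                raise OSError(f"cannot read {p}: no such file")
            planes = _read_planes(p)
            if planes.shape[0] != 1:
                raise OSError(f"{p}: expected a single-channel file, got {planes.shape[0]} planes")
            channels[role] = ChannelRaster(planes[0], channel_role=role)
        src = ";".join(str(Path(p)) for p in path.values())
    else:
        p = Path(path)
        if not p.exists():
            raise OSError(f"cannot read {p}: no such file")
        if channel_map is None:
            raise ChannelMapError("channel_map is required for multi-plane input")
        planes = _read_planes(p)
        for plane_idx, role in channel_map.items():
            if plane_idx >= planes.shape[0]:
                raise ChannelMapError(
                    f"{p}: channel_map refers to plane {plane_idx} but file has {planes.shape[0]}"
                )
            channels[role] = ChannelRaster(planes[plane_idx], channel_role=role)
        src = str(p)
    if "counterstain" not in channels:
        raise ChannelMapError("channel_map assigns no counterstain role")
    return FieldImage(channels=channels, calibration=calibration, source_path=src)


def write_raster(raster, path: str | Path) -> None:
    """Write a raster losslessly as TIFF or PNG.

    Accepts a :class:`ChannelRaster`, a bare integer array, or a
    ``CompositeMap`` (anything with ``frequencies`` in [0, 1] and
    ``n_nuclei``). Composite frequencies are scaled to the full 16-bit
    range; the scale and the number of nuclei are recorded in a JSON
    sidecar (``<path>.json``) so the frequencies are recoverable.
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"cannot write {path}: parent directory does not exist")
    if hasattr(raster, "frequencies"):  # CompositeMap
        scale = float(np.iinfo(np.uint16).max)
        data = np.round(np.asarray(raster.frequencies, dtype=float) * scale).astype(np.uint16)
        sidecar = {"n": int(raster.n_nuclei), "scale": scale}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        data = raster.pixels if isinstance(raster, ChannelRaster) else np.asarray(raster)
        if data.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"integer rasters must be uint8/uint16, got {data.dtype}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_composite(path: str | Path) -> tuple[np.ndarray, dict]:
    """Re-read a composite written by :func:`write_raster`.

    Returns the frequency array in [0, 1] and the sidecar metadata.
    """
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    data = _read_planes(path)[0].astype(float)
    return data / sidecar["scale"], sidecar
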