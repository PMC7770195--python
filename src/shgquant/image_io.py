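"""Reading and writing microscopy stacks and derived 2-D images.

A sample is a single-channel z-stack (``ImageStack``) acquired on a multiphoton
microscope: optical slices of the anterior annulus fibrosus, e.g. a 100 µm
depth at 10 µm steps for in situ imaging of whole disks, or ~10 µm at 1.5 µm
steps for thin histological sections.  The analysis pipeline works on a single
2-D image (``Image2D``) obtained from the stack by maximum intensity
z-projection.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

from .exceptions import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: fallback physical spacing used when a TIFF carries no metadata
DEFAULT_PIXEL_SIZE_UM = 1.0
DEFAULT_Z_STEP_UM = 10.0

_ALLOWED_BIT_DEPTHS = (8, 12, 16)

#: fraction of pixels at the container maximum above which a saturation
#: warning is logged (comparable acquisition requires no over-saturation)
SATURATION_WARN_FRACTION = 0.01


def _check_range(arr: np.ndarray, bit_depth: int, what: str) -> None:
    if bit_depth < 1:
        raise ParameterError(f"{what}: bit_depth must be >= 1, got {bit_depth}")
    if arr.size == 0:
        raise ParameterError(f"{what}: empty intensity array")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)):
            raise ParameterError(f"{what}: non-finite intensities")
    lo, hi = arr.min(), arr.max()
    if lo < 0 or hi > (1 << bit_depth) - 1:
        raise ParameterError(
            f"{what}: intensities [{lo}, {hi}] outside [0, {(1 << bit_depth) - 1}]"
        )


@dataclass
class ImageStack:
    """A 3-D (slices, rows, cols) single-channel intensity volume.

    Parameters
    ----------
    voxels
        Nonnegative integer intensities, shape ``(slices, rows, cols)``.
    pixel_size_um, z_step_um
        Physical in-plane pixel size and z step, micrometres.
    bit_depth
        Container bit depth; intensities must lie in ``[0, 2**bit_depth - 1]``.
    channel_label
        E.g. ``"SHG"``, ``"CHP-green"``, ``"DAPI-blue"``.
    """

    voxels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    bit_depth: int = 16
    channel_label: str = "SHG"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 2 and self.voxels.ndim != 3:
            raise ParameterError(
                f"voxels must be 2-D or 3-D, got ndim={self.voxels.ndim}"
            )
        if self.voxels.ndim == 2:  # degenerate single-slice stack
            self.voxels = self.voxels[np.newaxis, ...]
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ParameterError(
                f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS}, got {self.bit_depth}"
            )
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ParameterError("pixel_size_um and z_step_um must be > 0")
        _check_range(self.voxels, self.bit_depth, "ImageStack")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Image2D:
    """A 2-D working image with a provenance tag.

    ``provenance`` records the pipeline stage that produced the image:
    ``"raw-projection"``, ``"background-subtracted"``, ``"equalized"`` or
    ``"binary"`` (binary images contain only {0, 1}).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    provenance: str = "raw-projection"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        _check_range(self.pixels, self.bit_depth, "Image2D")
        if self.provenance == "binary":
            vals = np.unique(self.pixels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ParameterError("binary image must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def _bit_depth_from_dtype(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise FormatError(
        f"unsupported TIFF sample dtype {dtype}; expected uint8 or uint16 grayscale"
    )


def read_stack(
    path: str | PathLike,
    channel_label: str = "SHG",
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    detect_12bit: bool = False,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Missing physical-spacing metadata is filled from the module defaults
    (1.0 µm pixels, 10 µm z step).  RGB or palette TIFFs are rejected with an
    instruction to split channels first — each channel is analyzed separately.

    With ``detect_12bit=True``, a uint16 file whose maximum value is <= 4095 is
    relabeled as 12-bit data stored in a 16-bit container; the default trusts
    the container depth to avoid silently rescaling thresholds.
    """
    try:
        arr = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # tifffile raises assorted types on corrupt input
        raise OSError(f"could not read TIFF {path!s}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise FormatError(
            f"{path!s} looks like an RGB/RGBA TIFF; split it into single "
            "channels and read each channel separately"
        )
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path!s}: expected a 2-D page or a z-stack, got ndim={arr.ndim}")

    bit_depth = _bit_depth_from_dtype(arr.dtype)
    if detect_12bit and bit_depth == 16 and arr.max() <= 4095:
        bit_depth = 12

    stack = ImageStack(
        voxels=arr,
        pixel_size_um=DEFAULT_PIXEL_SIZE_UM if pixel_size_um is None else pixel_size_um,
        z_step_um=DEFAULT_Z_STEP_UM if z_step_um is None else z_step_um,
        bit_depth=bit_depth,
        channel_label=channel_label,
    )
    sat = float(np.mean(stack.voxels == (1 << bit_depth) - 1))
    if sat > SATURATION_WARN_FRACTION:
        logger.warning(
            "%s: %.1f%% of voxels saturated at %d; intensity comparisons may be biased",
            path, 100 * sat, (1 << bit_depth) - 1,
        )
    return stack


def max_projection(stack: ImageStack) -> Image2D:
    """Maximum intensity z-projection: ``out[r, c] = max_s voxels[s, r, c]``."""
    return Image2D(
        pixels=stack.voxels.max(axis=0),
        bit_depth=stack.bit_depth,
        provenance="raw-projection",
    )


def single_slice(stack: ImageStack, index: int | None = None) -> Image2D:
    """Extract one focal plane (default: middle slice) instead of projecting."""
    if index is None:
        index = stack.n_slices // 2
    if not 0 <= index < stack.n_slices:
        raise ParameterError(f"slice index {index} outside [0, {stack.n_slices})")
    return Image2D(
        pixels=stack.voxels[index],
        bit_depth=stack.bit_depth,
        provenance="raw-projection",
    )


def write_binary_mask(image: Image2D, path: str | PathLike) -> None:
    """Write a {0,1} mask as an 8-bit TIFF with 0/255 coding."""
    vals = np.unique(image.pixels)
    if not np.all(np.isin(vals, (0, 1))):
        raise ParameterError("write_binary_mask expects a {0,1} image")
    tifffile.imwrite(path, (image.pixels.astype(np.uint8) * 255))


def read_binary_mask(path: str | PathLike) -> Image2D:
    """Read a 0/255-coded mask TIFF back as a {0,1} binary image."""
    arr = tifffile.imread(path)
    if not np.all(np.isin(np.unique(arr), (0, 255))):
        raise FormatError(f"{path!s} is not a 0/255-coded binary mask")
    return Image2D(pixels=(arr > 0).astype(np.uint8), bit_depth=8, provenance="binary")


def write_csv(
    rows: Iterable[Mapping[str, object]],
    path: str | PathLike,
    fieldnames: Sequence[str] | None = None,
) -> None:
    """Write result rows as RFC-4180 CSV (one row per sample, shared header).

    ``fieldnames`` fixes the column order; otherwise it is taken from the first
    row.  An empty iterable with explicit ``fieldnames`` yields a header-only
    file.
    """
    rows = list(rows)
    if fieldnames is None:
        if not rows:
            raise ParameterError("empty rows require explicit fieldnames")
        fieldnames = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
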