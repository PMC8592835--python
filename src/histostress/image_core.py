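"""Core raster types, file I/O, and optical-density conversions.

All processing operates on :class:`RGBPatch`, an 8-bit RGB raster with an
opaque identifier.  Pixel arrays are row-major with origin at the top-left;
coordinates are ``(row, col)``, 0-based, with half-open ranges.

Optical density (absorbance) follows the Beer-Lambert convention used by
stain-deconvolution methods: ``od = -log10(I / I0)`` per channel, with the
transmitted intensity floored at 1 so the OD stays finite.  The reference
white ``I0`` defaults to 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import PatchFormatError

__all__ = [
    "RGBPatch",
    "OpticalDensityImage",
    "read_patch",
    "write_patch",
    "rgb_to_od",
    "od_to_rgb",
    "DEFAULT_PATCH_SIZE",
]

#: Default patch side length in pixels.
DEFAULT_PATCH_SIZE = 300


@dataclass(frozen=True)
class RGBPatch:
    """An 8-bit RGB image patch.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array of channel intensities in ``[0, 255]``.
    id
        Opaque identifier (e.g., file stem or synthetic patch id).
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise PatchFormatError(
                f"patch must be H x W x 3, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise PatchFormatError("patch must be at least 1 x 1 px")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise PatchFormatError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def with_pixels(self, pixels: np.ndarray, id: str | None = None) -> "RGBPatch":
        """Return a new patch carrying ``pixels`` and (by default) the same id."""
        return RGBPatch(pixels=pixels, id=self.id if id is None else id)


@dataclass(frozen=True)
class OpticalDensityImage:
    """Per-channel absorbance image; entries are nonnegative reals."""

    od: np.ndarray = field()

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=np.float64)
        if od.ndim != 3 or od.shape[2] != 3:
            raise ValueError(f"OD image must be H x W x 3, got {od.shape}")
        if od.min() < 0:
            raise ValueError("optical density must be nonnegative")
        object.__setattr__(self, "od", od)


def read_patch(path: str | Path) -> RGBPatch:
    """Read an 8-bit RGB PNG or TIFF patch from disk.

    The patch ``id`` is set to the file stem.  Raises
    :class:`~histostress.errors.PatchFormatError` for missing files or images
    that are not 3-channel 8-bit.
    """
    path = Path(path)
    if not path.exists():
        raise PatchFormatError(f"no such file: {path}")
    try:
        with Image.open(path) as img:
            if img.mode != "RGB":
                raise PatchFormatError(
                    f"{path.name}: expected 8-bit RGB, got mode {img.mode!r}"
                )
            pixels = np.asarray(img, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise PatchFormatError(f"{path.name}: not a readable image") from exc
    return RGBPatch(pixels=pixels, id=path.stem)


def write_patch(patch: RGBPatch, path: str | Path) -> None:
    """Write a patch losslessly as PNG or TIFF (chosen by extension)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in {".png", ".tif", ".tiff"}:
        raise PatchFormatError(f"unsupported extension {ext!r}; use .png or .tiff")
    img = Image.fromarray(patch.pixels, mode="RGB")
    if ext == ".png":
        img.save(path, format="PNG")
    else:
        # deflate keeps TIFF lossless and small
        img.save(path, format="TIFF", compression="tiff_deflate")


def rgb_to_od(patch: RGBPatch, i0: float = 255.0) -> OpticalDensityImage:
    """Convert intensities to optical density: ``-log10(max(I, 1) / i0)``."""
    if i0 <= 0:
        raise ValueError("reference white intensity i0 must be positive")
    intensities = np.maximum(patch.pixels.astype(np.float64), 1.0)
    od = -np.log10(intensities / i0)
    return OpticalDensityImage(od=np.maximum(od, 0.0))


def od_to_rgb(od: OpticalDensityImage, i0: float = 255.0, id: str = "") -> RGBPatch:
    """Invert :func:`rgb_to_od`: ``round(i0 * 10**(-od))`` clipped to [0, 255]."""
    if i0 <= 0:
        raise ValueError("reference white intensity i0 must be positive")
    arr = np.asarray(od.od, dtype=np.float64)
    pixels = np.clip(np.rint(i0 * np.power(10.0, -arr)), 0, 255).astype(np.uint8)
    return RGBPatch(pixels=pixels, id=id)


def od_array_from_rgb(pixels: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Array-level OD transform used internally by the stain module."""
    intensities = np.maximum(np.asarray(pixels, dtype=np.float64), 1.0)
    return np.maximum(-np.log10(intensities / i0), 0.0)


def rgb_array_from_od(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Array-level inverse OD transform; returns uint8."""
    return np.clip(np.rint(i0 * np.power(10.0, -np.asarray(od, dtype=np.float64))), 0, 255).astype(np.uint8)
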