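"""Information-destroying artifacts: the 16-level focus ladder and JPEG recompression.

The focus ladder models progressive defocus with a Gaussian blur whose square
window grows by 2 px per level: level ``L`` uses a ``(2L-1) x (2L-1)`` kernel,
so level 1 is a 1 px (identity) window.  The standard deviation is derived
from the window by the common imaging convention
``sigma = 0.3 * ((k - 1)/2 - 1) + 0.8``; an alternative ``radius`` mode with
``sigma = k / 3`` is available for users who need level 1 to perturb the
image.

JPEG recompression encodes the patch at a chosen quality and decodes it back,
with chroma subsampling pinned to 4:2:0 for reproducibility across codec
builds.  Many scanners store slides at quality 80, which serves as the
baseline of the default ladder.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import correlate1d

from .image_core import RGBPatch

__all__ = [
    "FocusLevel",
    "JpegQuality",
    "FOCUS_LADDER",
    "JPEG_LADDER",
    "JPEG_BASELINE_QUALITY",
    "focus_kernel_size",
    "apply_focus",
    "apply_jpeg",
]

#: Number of levels in the default focus ladder.
N_FOCUS_LEVELS = 16

#: Default focus ladder: levels 1..16.
FOCUS_LADDER = tuple(range(1, N_FOCUS_LEVELS + 1))

#: Scanner-standard JPEG quality used as the undegraded reference.
JPEG_BASELINE_QUALITY = 80

#: Default JPEG ladder: baseline 80 down to 5 in steps of 5.
JPEG_LADDER = tuple(range(JPEG_BASELINE_QUALITY, 0, -5))


@dataclass(frozen=True)
class FocusLevel:
    """One rung of the focus ladder; ``kernel_size = 2 * level - 1``."""

    level: int

    def __post_init__(self) -> None:
        if not 1 <= self.level <= N_FOCUS_LEVELS:
            raise ValueError(f"focus level must be in 1..{N_FOCUS_LEVELS}, got {self.level}")

    @property
    def kernel_size(self) -> int:
        return focus_kernel_size(self.level)


@dataclass(frozen=True)
class JpegQuality:
    """JPEG encoder quality in 1..100."""

    quality: int

    def __post_init__(self) -> None:
        if not 1 <= self.quality <= 100:
            raise ValueError(f"JPEG quality must be in 1..100, got {self.quality}")


def focus_kernel_size(level: int) -> int:
    """Kernel side (px) for a focus level: 1 px at level 1, +2 px per level."""
    if not 1 <= int(level) <= N_FOCUS_LEVELS:
        raise ValueError(f"focus level must be in 1..{N_FOCUS_LEVELS}, got {level}")
    return 2 * int(level) - 1


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    """Sampled, normalized 1-D Gaussian on a window of ``size`` taps."""
    if size == 1:
        return np.ones(1)
    half = (size - 1) / 2
    x = np.arange(size) - half
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def apply_focus(
    patch: RGBPatch,
    level: FocusLevel | int,
    sigma_mode: str = "window",
) -> RGBPatch:
    """Blur a patch with the Gaussian window of the given focus level.

    Parameters
    ----------
    level
        Focus level 1..16 (or a :class:`FocusLevel`).
    sigma_mode
        ``"window"`` (default): sigma from the window size via
        ``0.3 * ((k-1)/2 - 1) + 0.8``, so level 1 is an exact no-op.
        ``"radius"``: ``sigma = k / 3``, which perturbs even at level 1.

    Border handling is reflective, and the output has the input's dimensions.
    """
    lv = level.level if isinstance(level, FocusLevel) else int(level)
    k = focus_kernel_size(lv)
    if sigma_mode == "window":
        if k == 1:
            return patch.with_pixels(patch.pixels.copy())
        sigma = 0.3 * ((k - 1) / 2 - 1) + 0.8
    elif sigma_mode == "radius":
        # window auto-sized from sigma (4-sigma support), so even the 1 px
        # level perturbs the image
        sigma = k / 3.0
        k = 2 * int(np.ceil(4.0 * sigma)) + 1
    else:
        raise ValueError(f"sigma_mode must be 'window' or 'radius', got {sigma_mode!r}")

    kernel = _gaussian_kernel_1d(k, sigma)
    blurred = patch.pixels.astype(np.float64)
    for axis in (0, 1):
        blurred = correlate1d(blurred, kernel, axis=axis, mode="reflect")
    return patch.with_pixels(np.clip(np.rint(blurred), 0, 255).astype(np.uint8))


def apply_jpeg(patch: RGBPatch, quality: JpegQuality | int) -> RGBPatch:
    """Round-trip a patch through the JPEG codec at the given quality."""
    q = quality.quality if isinstance(quality, JpegQuality) else int(quality)
    if not 1 <= q <= 100:
        raise ValueError(f"JPEG quality must be in 1..100, got {q}")
    buf = io.BytesIO()
    Image.fromarray(patch.pixels, mode="RGB").save(
        buf, format="JPEG", quality=q, subsampling=2  # 4:2:0
    )
    buf.seek(0)
    with Image.open(buf) as img:
        decoded = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return patch.with_pixels(decoded)


def jpeg_encoded_size(patch: RGBPatch, quality: int) -> int:
    """Byte length of the patch encoded at ``quality`` (diagnostic helper)."""
    buf = io.BytesIO()
    Image.fromarray(patch.pixels, mode="RGB").save(
        buf, format="JPEG", quality=int(quality), subsampling=2
    )
    return buf.getbuffer().nbytes
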