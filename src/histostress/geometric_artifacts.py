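"""Geometric perturbations: flips, right-angle rotations, and elastic deformation.

Rotations are restricted to multiples of 90 degrees so no border content is
fabricated.  Elastic deformation displaces control points on a regular grid by
uniform offsets, interpolates the offsets bicubically into a dense
displacement field, and resamples the patch bilinearly with reflective
padding — the grid-warp scheme standard in medical-image augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import map_coordinates

from .image_core import RGBPatch

__all__ = [
    "ElasticSpec",
    "ELASTIC_GRID_LADDER",
    "apply_flip",
    "apply_rotation",
    "apply_elastic",
]

#: Default elastic ladder of grid-cell sides (px), centred on 70 px.
ELASTIC_GRID_LADDER = (30, 50, 70, 90, 110)

#: Default maximum control-point displacement as a fraction of the grid cell.
DEFAULT_MAGNITUDE_FRACTION = 1 / 8


@dataclass(frozen=True)
class ElasticSpec:
    """Parameters of one grid-based elastic deformation.

    ``grid_size`` is the cell side of the control-point grid in px;
    ``magnitude`` the maximum per-axis control-point displacement in px
    (default ``grid_size / 8``, which keeps deformations in a visually
    realistic range); ``seed`` drives the offset draw.
    """

    grid_size: int
    magnitude: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError(f"grid_size must be >= 2 px, got {self.grid_size}")
        mag = self.magnitude
        if mag is None:
            mag = self.grid_size * DEFAULT_MAGNITUDE_FRACTION
        if mag < 0:
            raise ValueError(f"magnitude must be >= 0, got {mag}")
        object.__setattr__(self, "magnitude", float(mag))


def apply_flip(patch: RGBPatch, axis: str) -> RGBPatch:
    """Mirror the patch about the ``"horizontal"`` or ``"vertical"`` axis.

    A horizontal flip mirrors left-right (columns reversed); a vertical flip
    mirrors top-bottom (rows reversed).
    """
    if axis == "horizontal":
        return patch.with_pixels(patch.pixels[:, ::-1].copy())
    if axis == "vertical":
        return patch.with_pixels(patch.pixels[::-1].copy())
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def apply_rotation(
    patch: RGBPatch,
    quarter_turns: int | None = None,
    rng: np.random.Generator | None = None,
) -> RGBPatch:
    """Rotate by 90 degrees counter-clockwise ``quarter_turns`` times (1..3).

    When ``quarter_turns`` is None an ``rng`` must be supplied and the number
    of turns is drawn uniformly from {1, 2, 3}.
    """
    if quarter_turns is None:
        if rng is None:
            raise ValueError("provide quarter_turns or an rng to draw it")
        quarter_turns = int(rng.integers(1, 4))
    if quarter_turns % 4 == 0:
        return patch.with_pixels(patch.pixels.copy())
    return patch.with_pixels(np.rot90(patch.pixels, k=quarter_turns % 4).copy())


def _dense_offsets(
    shape: tuple[int, int], grid_size: int, magnitude: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bicubic interpolation of uniform control-point offsets to pixel grid."""
    h, w = shape
    # control points at spacing grid_size, padded one cell beyond each border
    # so the cubic spline is supported over the full patch
    nr = int(np.ceil((h - 1) / grid_size)) + 3
    nc = int(np.ceil((w - 1) / grid_size)) + 3
    ctrl_rows = (np.arange(nr) - 1) * grid_size
    ctrl_cols = (np.arange(nc) - 1) * grid_size
    d_row = rng.uniform(-magnitude, magnitude, size=(nr, nc))
    d_col = rng.uniform(-magnitude, magnitude, size=(nr, nc))
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    dr = RectBivariateSpline(ctrl_rows, ctrl_cols, d_row, kx=3, ky=3)(rows, cols)
    dc = RectBivariateSpline(ctrl_rows, ctrl_cols, d_col, kx=3, ky=3)(rows, cols)
    return dr, dc


def apply_elastic(patch: RGBPatch, spec: ElasticSpec) -> RGBPatch:
    """Apply a seeded grid-based elastic deformation.

    With ``magnitude == 0`` the output is bit-identical to the input.  The
    bilinear resampling cannot overshoot, so the output value range is
    contained in the input's.
    """
    if spec.grid_size >= min(patch.height, patch.width):
        raise ValueError(
            f"grid_size {spec.grid_size} must be smaller than the patch "
            f"({patch.height} x {patch.width})"
        )
    if spec.magnitude == 0:
        return patch.with_pixels(patch.pixels.copy())
    rng = np.random.default_rng(spec.seed)
    dr, dc = _dense_offsets((patch.height, patch.width), spec.grid_size, spec.magnitude, rng)
    rows, cols = np.meshgrid(
        np.arange(patch.height, dtype=np.float64),
        np.arange(patch.width, dtype=np.float64),
        indexing="ij",
    )
    coords = [rows + dr, cols + dc]
    out = np.empty_like(patch.pixels)
    for ch in range(3):
        warped = map_coordinates(
            patch.pixels[..., ch].astype(np.float64), coords, order=1, mode="reflect"
        )
        out[..., ch] = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    return patch.with_pixels(out)
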