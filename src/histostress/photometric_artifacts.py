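"""Brightness and contrast perturbation ladders.

Brightness is a multiplicative gain: ``I' = I * (1 + delta)``.  Contrast
scales the deviation from the patch's mean gray level (Rec. 601 luma
``0.299 R + 0.587 G + 0.114 B``): ``I' = mu + (1 + delta) * (I - mu)``.
Both results are rounded and clipped to [0, 255].  The two operators are
orthogonal: contrast leaves the mean fixed, brightness scales it.

The default ladder steps delta by 0.1 (10%) from -0.5 to +0.5, with 0 being
the unperturbed baseline.
"""

from __future__ import annotations

import numpy as np

from .image_core import RGBPatch

__all__ = [
    "PHOTOMETRIC_LADDER_UP",
    "PHOTOMETRIC_LADDER_DOWN",
    "adjust_brightness",
    "adjust_contrast",
    "mean_luma",
]

#: Default increasing ladder: +10% .. +50% in 10% steps.
PHOTOMETRIC_LADDER_UP = (0.1, 0.2, 0.3, 0.4, 0.5)

#: Default decreasing ladder: -10% .. -50% in 10% steps.
PHOTOMETRIC_LADDER_DOWN = (-0.1, -0.2, -0.3, -0.4, -0.5)

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def mean_luma(patch: RGBPatch) -> float:
    """Mean Rec. 601 luma of the patch."""
    return float(np.mean(patch.pixels.astype(np.float64) @ _LUMA_WEIGHTS))


def _check_delta(delta: float) -> float:
    delta = float(delta)
    if delta <= -1:
        raise ValueError(f"delta must be > -1, got {delta}")
    return delta


def adjust_brightness(patch: RGBPatch, delta: float) -> RGBPatch:
    """Scale all intensities by ``1 + delta`` (delta in signed fractions)."""
    delta = _check_delta(delta)
    out = np.clip(np.rint(patch.pixels.astype(np.float64) * (1.0 + delta)), 0, 255)
    return patch.with_pixels(out.astype(np.uint8))


def adjust_contrast(patch: RGBPatch, delta: float) -> RGBPatch:
    """Scale deviations from the mean gray level by ``1 + delta``."""
    delta = _check_delta(delta)
    mu = mean_luma(patch)
    px = patch.pixels.astype(np.float64)
    out = np.clip(np.rint(mu + (1.0 + delta) * (px - mu)), 0, 255)
    return patch.with_pixels(out.astype(np.uint8))
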