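"""Foreign-object artifacts composited onto patches from an RGBA template bank.

Four template kinds emulate common slide contaminants: semi-transparent dark
spots (dust, scratches; 3 size variants), curvilinear synthetic threads that
additionally defocus the tissue under and around them (10 path variants),
faintly stained squamous-epithelial cell clusters (20 variants), and a single
high-transparency fat drop left by a fingerprint.  Alpha compositing leaves
all pixels outside the template footprint (plus the thread's defocus halo)
bit-identical to the input.

Placements are drawn so templates always lie fully inside the patch; when
several objects are placed, centers are re-drawn until they are at least half
a template diagonal apart, so footprints do not pile up on one spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation, correlate1d

from .degradation_artifacts import _gaussian_kernel_1d
from .image_core import RGBPatch

__all__ = [
    "OverlayTemplate",
    "Placement",
    "TemplateBank",
    "BANK_SIZES",
    "THREAD_HALO_RADIUS",
    "composite",
    "apply_dark_spots",
    "apply_thread",
    "apply_squamous",
    "apply_fingerprint",
]

#: Number of variants per template kind.
BANK_SIZES = {"dark_spot": 3, "thread": 10, "squamous": 20, "fingerprint": 1}

#: Radius (px) by which the thread footprint is dilated before local defocus.
THREAD_HALO_RADIUS = 12

#: Gaussian window (px) of the thread's local defocus.
THREAD_HALO_BLUR_KERNEL = 9


@dataclass(frozen=True)
class OverlayTemplate:
    """An RGBA cut-out: color plus per-pixel opacity in [0, 1].

    ``defocus_halo`` marks templates (threads) that locally blur the patch
    under and around their footprint.
    """

    rgba: np.ndarray
    kind: str
    variant: int = 0
    defocus_halo: bool = False

    def __post_init__(self) -> None:
        rgba = np.asarray(self.rgba, dtype=np.float64)
        if rgba.ndim != 3 or rgba.shape[2] != 4:
            raise ValueError(f"template must be h x w x 4, got {rgba.shape}")
        if rgba[..., 3].min() < 0 or rgba[..., 3].max() > 1:
            raise ValueError("template opacity must lie in [0, 1]")
        object.__setattr__(self, "rgba", rgba)

    @property
    def height(self) -> int:
        return int(self.rgba.shape[0])

    @property
    def width(self) -> int:
        return int(self.rgba.shape[1])

    @property
    def footprint(self) -> np.ndarray:
        """Boolean mask of pixels with opacity > 0."""
        return self.rgba[..., 3] > 0

    @classmethod
    def load(cls, path: str | Path, kind: str, variant: int = 0) -> "OverlayTemplate":
        """Load an RGBA PNG template; 8-bit alpha is rescaled to [0, 1]."""
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGBA"), dtype=np.float64)
        rgba = np.empty_like(arr)
        rgba[..., :3] = arr[..., :3]
        rgba[..., 3] = arr[..., 3] / 255.0
        return cls(rgba=rgba, kind=kind, variant=variant,
                   defocus_halo=(kind == "thread"))

    def save(self, path: str | Path) -> None:
        arr = np.empty(self.rgba.shape, dtype=np.uint8)
        arr[..., :3] = np.clip(np.rint(self.rgba[..., :3]), 0, 255)
        arr[..., 3] = np.clip(np.rint(self.rgba[..., 3] * 255), 0, 255)
        Image.fromarray(arr, mode="RGBA").save(path, format="PNG")


@dataclass(frozen=True)
class Placement:
    """Top-left offset of a template in patch coordinates (row, col)."""

    row: int
    col: int


class TemplateBank:
    """The on-disk template bank ``{kind}/{variant:02d}.png``."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self._cache: dict[tuple[str, int], OverlayTemplate] = {}

    def get(self, kind: str, variant: int) -> OverlayTemplate:
        if kind not in BANK_SIZES:
            raise ValueError(f"unknown template kind {kind!r}")
        if not 1 <= variant <= BANK_SIZES[kind]:
            raise ValueError(f"{kind} variant must be in 1..{BANK_SIZES[kind]}")
        key = (kind, variant)
        if key not in self._cache:
            path = self.root / kind / f"{variant:02d}.png"
            self._cache[key] = OverlayTemplate.load(path, kind=kind, variant=variant)
        return self._cache[key]


def _random_placement(
    patch: RGBPatch, template: OverlayTemplate, rng: np.random.Generator
) -> Placement:
    if template.height > patch.height or template.width > patch.width:
        raise ValueError(
            f"template ({template.height}x{template.width}) larger than patch "
            f"({patch.height}x{patch.width})"
        )
    row = int(rng.integers(0, patch.height - template.height + 1))
    col = int(rng.integers(0, patch.width - template.width + 1))
    return Placement(row=row, col=col)


def _spaced_placements(
    patch: RGBPatch,
    template: OverlayTemplate,
    count: int,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[Placement]:
    """Rejection-sample placements with min center distance = diagonal / 2."""
    min_dist = float(np.hypot(template.height, template.width)) / 2.0
    placements: list[Placement] = []
    centers: list[tuple[float, float]] = []
    for _ in range(count):
        for _ in range(max_tries):
            p = _random_placement(patch, template, rng)
            c = (p.row + template.height / 2, p.col + template.width / 2)
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= min_dist for o in centers):
                placements.append(p)
                centers.append(c)
                break
        else:
            # patch too crowded for the spacing rule; accept the last draw
            placements.append(p)
            centers.append(c)
    return placements


def composite(
    patch: RGBPatch, template: OverlayTemplate, placement: Placement
) -> RGBPatch:
    """Alpha-blend a template onto the patch at the given offset.

    ``out = alpha * template + (1 - alpha) * patch`` inside the footprint;
    everything outside is untouched.
    """
    r, c = placement.row, placement.col
    if r < 0 or c < 0 or r + template.height > patch.height or c + template.width > patch.width:
        raise ValueError("placement puts the template outside the patch")
    out = patch.pixels.astype(np.float64)
    region = out[r : r + template.height, c : c + template.width]
    alpha = template.rgba[..., 3:4]
    blended = alpha * template.rgba[..., :3] + (1.0 - alpha) * region
    out[r : r + template.height, c : c + template.width] = blended
    return patch.with_pixels(np.clip(np.rint(out), 0, 255).astype(np.uint8))


def apply_dark_spots(
    patch: RGBPatch,
    bank: TemplateBank,
    spot_type: int,
    count: int,
    rng: np.random.Generator,
) -> RGBPatch:
    """Overlay ``count`` dark spots of one size variant at random placements."""
    if not 1 <= spot_type <= BANK_SIZES["dark_spot"]:
        raise ValueError(f"spot_type must be in 1..{BANK_SIZES['dark_spot']}")
    if not 1 <= count <= 3:
        raise ValueError("count must be in 1..3")
    template = bank.get("dark_spot", spot_type)
    out = patch
    for placement in _spaced_placements(patch, template, count, rng):
        out = composite(out, template, placement)
    return out


def _blur_region(pixels: np.ndarray, mask: np.ndarray, kernel_size: int) -> np.ndarray:
    """Gaussian-blur the whole frame, then keep it only inside ``mask``."""
    sigma = 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8
    kernel = _gaussian_kernel_1d(kernel_size, sigma)
    blurred = pixels.astype(np.float64)
    for axis in (0, 1):
        blurred = correlate1d(blurred, kernel, axis=axis, mode="reflect")
    blurred = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    out = pixels.copy()
    out[mask] = blurred[mask]
    return out


def apply_thread(
    patch: RGBPatch,
    bank: TemplateBank,
    variant: int | None = None,
    rng: np.random.Generator | None = None,
) -> RGBPatch:
    """Overlay a synthetic thread and locally defocus tissue around it.

    The thread footprint is dilated by :data:`THREAD_HALO_RADIUS` and patch
    content inside the dilated region is Gaussian-blurred, emulating the
    focal focus distortion threads cause during scanning.  Pixels outside the
    dilated footprint are bit-identical to the input.
    """
    if variant is None:
        if rng is None:
            raise ValueError("provide a variant or an rng to draw one")
        variant = int(rng.integers(1, BANK_SIZES["thread"] + 1))
    template = bank.get("thread", variant)
    if rng is not None:
        placement = _random_placement(patch, template, rng)
    else:
        placement = Placement(
            row=(patch.height - template.height) // 2,
            col=(patch.width - template.width) // 2,
        )
    out = composite(patch, template, placement)

    mask = np.zeros((patch.height, patch.width), dtype=bool)
    r, c = placement.row, placement.col
    mask[r : r + template.height, c : c + template.width] = template.footprint
    ry, rx = np.ogrid[-THREAD_HALO_RADIUS : THREAD_HALO_RADIUS + 1,
                      -THREAD_HALO_RADIUS : THREAD_HALO_RADIUS + 1]
    disk = ry**2 + rx**2 <= THREAD_HALO_RADIUS**2
    halo = binary_dilation(mask, structure=disk)
    return out.with_pixels(_blur_region(out.pixels, halo, THREAD_HALO_BLUR_KERNEL))


def apply_squamous(
    patch: RGBPatch, bank: TemplateBank, count: int, rng: np.random.Generator
) -> RGBPatch:
    """Overlay ``count`` squamous-epithelium clusters drawn from the 20-variant bank."""
    if not 1 <= count <= 3:
        raise ValueError("count must be in 1..3")
    out = patch
    for _ in range(count):
        variant = int(rng.integers(1, BANK_SIZES["squamous"] + 1))
        template = bank.get("squamous", variant)
        out = composite(out, template, _random_placement(patch, template, rng))
    return out


def apply_fingerprint(
    patch: RGBPatch, bank: TemplateBank, rng: np.random.Generator
) -> RGBPatch:
    """Overlay the single high-transparency fat drop at a random placement."""
    template = bank.get("fingerprint", 1)
    return composite(patch, template, _random_placement(patch, template, rng))
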