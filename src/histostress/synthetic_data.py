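"""Synthetic H&E-like inputs: labeled patches, overlay templates, staining schemes.

Patches are rendered in *stain-concentration space* — a hematoxylin field
(nuclei) and an eosin field (cytoplasm/stroma) — and pushed through a fixed
reference stain matrix to RGB.  Because the generative stain vectors are
known, stain-deconvolution experiments have an exact ground truth.

Three tissue classes mimic the gross architecture a prostate-patch
classifier distinguishes:

* ``GLAND`` — a few large rounded benign glands with open (near-white)
  lumina and a single rim of nuclei, embedded in stroma;
* ``TUMOR`` — many small crowded glands with scant lumina, dense nuclear
  rims and scattered interstitial nuclei;
* ``NONGLAND`` — fibrous stroma streaks and/or fat vacuoles with sparse
  nuclei and no glands.

All generators are deterministic given their seed.  The rendering is a
cartoon of tissue: it reproduces the color statistics, nuclear texture and
white-lumen geometry that simple stain/texture features respond to, not
histology that would convince a pathologist.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_core import DEFAULT_PATCH_SIZE, RGBPatch, rgb_array_from_od, write_patch
from .overlay_artifacts import BANK_SIZES, OverlayTemplate

__all__ = [
    "TISSUE_CLASSES",
    "REFERENCE_STAIN_MATRIX",
    "LabeledPatch",
    "DatasetSpec",
    "FULL_SCALE_COUNTS",
    "DESK_SCALE_COUNTS",
    "generate_patch",
    "generate_patches",
    "generate_dataset",
    "generate_template_bank",
    "generate_scheme_bank",
]

#: The three tissue classes the plug-in classifier must score.
TISSUE_CLASSES = ("TUMOR", "GLAND", "NONGLAND")

#: Test-set composition (tumor / benign glandular / benign nonglandular).
FULL_SCALE_COUNTS = (50_000, 50_000, 20_000)

#: Desk-scale composition preserving the 5:5:2 class ratio.
DESK_SCALE_COUNTS = (500, 500, 200)


def _unit_columns(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0, keepdims=True)


#: Canonical H&E stain matrix (columns: hematoxylin, eosin RGB-OD directions).
REFERENCE_STAIN_MATRIX = _unit_columns(
    np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
)


@dataclass(frozen=True)
class LabeledPatch:
    """A rendered patch with its ground-truth tissue class and seed."""

    patch: RGBPatch
    true_class: str
    seed: int

    def __post_init__(self) -> None:
        if self.true_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.true_class!r}")


@dataclass(frozen=True)
class DatasetSpec:
    """Composition of a synthetic dataset."""

    n_tumor: int
    n_gland: int
    n_nongland: int
    seed: int = 0
    patch_size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_gland, self.n_nongland) < 0:
            raise ValueError("patch counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_tumor + self.n_gland + self.n_nongland


# ---------------------------------------------------------------------------
# field rendering helpers
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field with correlation sigma."""
    field = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


def _paint_disk(
    field: np.ndarray, row: float, col: float, radius: float, value: float,
    feather: float = 1.5,
) -> None:
    """Max-composite a soft-edged disk into a scalar field, in place."""
    h, w = field.shape
    r0, r1 = max(0, int(row - radius - 2)), min(h, int(row + radius + 3))
    c0, c1 = max(0, int(col - radius - 2)), min(w, int(col + radius + 3))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    dist = np.hypot(rr - row, cc - col)
    profile = np.clip((radius - dist) / feather + 1.0, 0.0, 1.0)
    np.maximum(field[r0:r1, c0:c1], value * profile, out=field[r0:r1, c0:c1])


def _carve_disk(fields: list[np.ndarray], row: float, col: float, radius: float,
                floor: float = 0.01) -> None:
    """Clear (nearly) all stain inside a disk — an open lumen or fat vacuole."""
    h, w = fields[0].shape
    r0, r1 = max(0, int(row - radius - 2)), min(h, int(row + radius + 3))
    c0, c1 = max(0, int(col - radius - 2)), min(w, int(col + radius + 3))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    inside = np.hypot(rr - row, cc - col) <= radius
    for f in fields:
        region = f[r0:r1, c0:c1]
        region[inside] = np.minimum(region[inside], floor)


def _ring_nuclei(
    h_field: np.ndarray, row: float, col: float, ring_radius: float,
    spacing: float, nucleus_radius: float, value: float, rng: np.random.Generator,
) -> None:
    n = max(3, int(2 * np.pi * ring_radius / spacing))
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    angles = angles + rng.uniform(-0.3, 0.3, size=n) / max(ring_radius / spacing, 1)
    for a in angles:
        r = row + ring_radius * np.sin(a) + rng.uniform(-1, 1)
        c = col + ring_radius * np.cos(a) + rng.uniform(-1, 1)
        _paint_disk(h_field, r, c, nucleus_radius * rng.uniform(0.85, 1.15), value)


def _scatter_nuclei(
    h_field: np.ndarray, n: int, radius: float, value: float,
    rng: np.random.Generator,
) -> None:
    h, w = h_field.shape
    rows = rng.uniform(0, h, size=n)
    cols = rng.uniform(0, w, size=n)
    for r, c in zip(rows, cols):
        _paint_disk(h_field, r, c, radius * rng.uniform(0.8, 1.2), value)


def _render_gland_fields(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Benign glandular tissue: 2-5 large glands with open lumina."""
    shape = (size, size)
    e = 0.30 + 0.06 * _smooth_noise(rng, shape, size / 12)
    h = 0.05 + 0.02 * _smooth_noise(rng, shape, size / 12)
    scale = size / DEFAULT_PATCH_SIZE
    n_glands = int(rng.integers(2, 6))
    for _ in range(n_glands):
        outer = rng.uniform(45, 70) * scale
        row = rng.uniform(outer, size - outer)
        col = rng.uniform(outer, size - outer)
        lumen = 0.55 * outer
        _paint_disk(e, row, col, outer, 0.45, feather=4.0)
        _carve_disk([e, h], row, col, lumen)
        _ring_nuclei(h, row, col, lumen + 3 * scale, spacing=11 * scale,
                     nucleus_radius=3.0 * scale, value=1.0, rng=rng)
    _scatter_nuclei(h, int(rng.integers(8, 17)), 2.5 * scale, 0.9, rng)
    return np.clip(h, 0, None), np.clip(e, 0, None)


def _render_tumor_fields(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Tumor: 8-20 small crowded glands, dense nuclei, scant lumina."""
    shape = (size, size)
    e = 0.32 + 0.06 * _smooth_noise(rng, shape, size / 12)
    h = 0.10 + 0.03 * _smooth_noise(rng, shape, size / 12)
    scale = size / DEFAULT_PATCH_SIZE
    n_glands = int(rng.integers(8, 21))
    for _ in range(n_glands):
        outer = rng.uniform(12, 22) * scale
        row = rng.uniform(outer, size - outer)
        col = rng.uniform(outer, size - outer)
        lumen = 0.3 * outer
        _paint_disk(e, row, col, outer, 0.50, feather=3.0)
        _carve_disk([e, h], row, col, lumen, floor=0.05)
        _ring_nuclei(h, row, col, lumen + 2.5 * scale, spacing=5.5 * scale,
                     nucleus_radius=3.0 * scale, value=1.1, rng=rng)
    _scatter_nuclei(h, int(rng.integers(150, 301)), 2.6 * scale, 1.0, rng)
    return np.clip(h, 0, None), np.clip(e, 0, None)


def _render_nongland_fields(rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Benign nonglandular tissue: fibrous streaks and/or fat vacuoles."""
    shape = (size, size)
    scale = size / DEFAULT_PATCH_SIZE
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    theta = rng.uniform(0, np.pi)
    wavelength = rng.uniform(18, 40) * scale
    phase = rng.uniform(0, 2 * np.pi)
    waves = np.sin(2 * np.pi * (rr * np.cos(theta) + cc * np.sin(theta)) / wavelength + phase)
    e = 0.28 + 0.10 * waves + 0.05 * _smooth_noise(rng, shape, size / 15)
    e = np.clip(e, 0.05, None)
    h = np.clip(0.04 + 0.02 * _smooth_noise(rng, shape, size / 15), 0, None)
    if rng.random() < 0.6:  # fat component
        for _ in range(int(rng.integers(3, 9))):
            radius = rng.uniform(15, 35) * scale
            row = rng.uniform(radius, size - radius)
            col = rng.uniform(radius, size - radius)
            _paint_disk(e, row, col, radius + 2 * scale, 0.40, feather=2.0)
            _carve_disk([e, h], row, col, radius)
    _scatter_nuclei(h, int(rng.integers(15, 31)), 2.3 * scale, 0.9, rng)
    return np.clip(h, 0, None), np.clip(e, 0, None)


_RENDERERS = {
    "GLAND": _render_gland_fields,
    "TUMOR": _render_tumor_fields,
    "NONGLAND": _render_nongland_fields,
}

#: Relative multiplicative noise applied to the concentration fields.
CONCENTRATION_NOISE = 0.015


def render_concentration_fields(
    true_class: str, seed: int, patch_size: int = DEFAULT_PATCH_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Hematoxylin and eosin concentration fields for one patch (noise included)."""
    if true_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {true_class!r}")
    rng = np.random.default_rng([seed, TISSUE_CLASSES.index(true_class)])
    h, e = _RENDERERS[true_class](rng, patch_size)
    noise = 1.0 + CONCENTRATION_NOISE * rng.standard_normal((patch_size, patch_size, 2))
    h = np.clip(h * noise[..., 0], 0, None)
    e = np.clip(e * noise[..., 1], 0, None)
    return h, e


def generate_patch(
    true_class: str,
    seed: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    stain_matrix: np.ndarray | None = None,
    gain: float = 1.0,
    patch_id: str | None = None,
) -> LabeledPatch:
    """Render one labeled patch.

    ``stain_matrix`` (3x2 unit columns) and ``gain`` (global concentration
    scale) default to the reference scheme; they are used by the scheme-bank
    generator to emulate weak-to-strong staining.
    """
    m = REFERENCE_STAIN_MATRIX if stain_matrix is None else stain_matrix
    h, e = render_concentration_fields(true_class, seed, patch_size)
    conc = np.stack([h, e], axis=-1) * gain
    od = conc @ m.T
    pixels = rgb_array_from_od(od)
    pid = patch_id if patch_id is not None else f"{true_class.lower()}_{seed:08d}"
    return LabeledPatch(
        patch=RGBPatch(pixels=pixels, id=pid), true_class=true_class, seed=seed
    )


def _spec_seeds(spec: DatasetSpec) -> list[tuple[str, int, str]]:
    """(class, seed, patch_id) triples for every patch of a dataset."""
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, int, str]] = []
    for cls, n in zip(TISSUE_CLASSES, (spec.n_tumor, spec.n_gland, spec.n_nongland)):
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i, s in enumerate(seeds):
            rows.append((cls, int(s), f"{cls.lower()}_{i:05d}"))
    return rows


def generate_patches(spec: DatasetSpec) -> list[LabeledPatch]:
    """Render a whole dataset in memory (desk-scale compositions)."""
    return [
        generate_patch(cls, seed, spec.patch_size, patch_id=pid)
        for cls, seed, pid in _spec_seeds(spec)
    ]


def generate_dataset(
    spec: DatasetSpec, out_dir: str | Path | None = None, dry_run: bool = False
) -> pd.DataFrame:
    """Write a dataset to disk and return its manifest.

    The manifest has columns ``patch_id, path, true_class`` (plus ``seed``).
    With ``dry_run=True`` only the manifest is produced — useful to check
    full-scale compositions without rendering 120,000 patches.
    """
    rows = _spec_seeds(spec)
    manifest = pd.DataFrame(
        {
            "patch_id": [pid for _, _, pid in rows],
            "path": [f"{pid}.png" for _, _, pid in rows],
            "true_class": [cls for cls, _, _ in rows],
            "seed": [seed for _, seed, _ in rows],
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if not dry_run:
            for cls, seed, pid in rows:
                lp = generate_patch(cls, seed, spec.patch_size, patch_id=pid)
                write_patch(lp.patch, out_dir / f"{pid}.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# overlay template bank
# ---------------------------------------------------------------------------


def _blob_alpha(
    rng: np.random.Generator, radius: float, irregularity: float = 0.25,
    feather: float = 4.0,
) -> np.ndarray:
    """Alpha mask of an irregular blob: a disk with sinusoidal boundary wobble."""
    half = int(np.ceil(radius * (1 + irregularity) + feather)) + 2
    size = 2 * half + 1
    rr, cc = np.ogrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(rr, cc)
    angle = np.arctan2(rr, cc)
    wobble = np.zeros_like(dist, dtype=np.float64)
    for k in range(2, 6):
        wobble += rng.uniform(0, irregularity / 2) * np.sin(
            k * angle + rng.uniform(0, 2 * np.pi)
        )
    boundary = radius * (1 + wobble)
    return np.clip((boundary - dist) / feather + 1.0, 0.0, 1.0)


def _make_dark_spot(rng: np.random.Generator, variant: int) -> OverlayTemplate:
    radius = {1: 16.0, 2: 24.0, 3: 36.0}[variant]
    shape_alpha = _blob_alpha(rng, radius)
    opacity = rng.uniform(0.6, 0.95)
    texture = 1.0 - 0.15 * (_smooth_noise(rng, shape_alpha.shape, 4.0) ** 2)
    alpha = np.clip(shape_alpha * opacity * texture, 0, 0.95)
    rgba = np.empty(shape_alpha.shape + (4,))
    base = np.array([45.0, 38.0, 35.0]) + rng.uniform(-10, 10, size=3)
    rgba[..., :3] = np.clip(base, 0, 255)
    rgba[..., 3] = alpha
    return OverlayTemplate(rgba=rgba, kind="dark_spot", variant=variant)


def _make_thread(rng: np.random.Generator, variant: int, canvas: int = 240) -> OverlayTemplate:
    """A curvilinear fiber: a quadratic Bezier stroke with feathered width."""
    edges = rng.permutation(4)[:2]

    def edge_point(which: int) -> np.ndarray:
        t = rng.uniform(0.1, 0.9) * canvas
        return {
            0: np.array([0.0, t]),
            1: np.array([canvas - 1.0, t]),
            2: np.array([t, 0.0]),
            3: np.array([t, canvas - 1.0]),
        }[which]

    p0, p2 = edge_point(int(edges[0])), edge_point(int(edges[1]))
    p1 = np.array([rng.uniform(0.2, 0.8) * canvas, rng.uniform(0.2, 0.8) * canvas])
    t = np.linspace(0, 1, 4 * canvas)[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2

    rr, cc = np.meshgrid(np.arange(canvas), np.arange(canvas), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    # distance from every pixel to the polyline, chunked to bound memory
    dist = np.full(pts.shape[0], np.inf)
    for start in range(0, curve.shape[0], 64):
        seg = curve[start : start + 64]
        d = np.min(
            np.hypot(pts[:, None, 0] - seg[None, :, 0], pts[:, None, 1] - seg[None, :, 1]),
            axis=1,
        )
        dist = np.minimum(dist, d)
    width = rng.uniform(2.0, 3.5)
    alpha = np.clip((width - dist.reshape(canvas, canvas)) / 1.5 + 1.0, 0, 1) * 0.85
    rgba = np.empty((canvas, canvas, 4))
    rgba[..., :3] = np.array([50.0, 50.0, 70.0]) + rng.uniform(-10, 10, size=3)
    rgba[..., 3] = alpha
    return OverlayTemplate(rgba=rgba, kind="thread", variant=variant, defocus_halo=True)


def _make_squamous(rng: np.random.Generator, variant: int) -> OverlayTemplate:
    radius = rng.uniform(28, 45)
    alpha = _blob_alpha(rng, radius, irregularity=0.35, feather=6.0) * 0.35
    rgba = np.empty(alpha.shape + (4,))
    rgba[..., :3] = np.array([205.0, 170.0, 205.0]) + rng.uniform(-15, 15, size=3)
    rgba[..., 3] = alpha
    # a few faint nuclei inside the cell cluster
    half = alpha.shape[0] // 2
    for _ in range(int(rng.integers(1, 5))):
        a = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0, 0.5 * radius)
        nr, nc = half + r * np.sin(a), half + r * np.cos(a)
        nucleus = np.zeros(alpha.shape)
        _paint_disk(nucleus, nr, nc, rng.uniform(3, 5), 1.0)
        rgba[..., 3] = np.clip(rgba[..., 3] + 0.25 * nucleus, 0, 0.6)
        dark = nucleus > 0.5
        rgba[dark, :3] = np.array([120.0, 90.0, 140.0])
    return OverlayTemplate(rgba=rgba, kind="squamous", variant=variant)


def _make_fingerprint(rng: np.random.Generator) -> OverlayTemplate:
    """An elliptical bright-rimmed fat drop with very low opacity."""
    h, w = 100, 140
    rr, cc = np.ogrid[:h, :w]
    norm = np.hypot((rr - h / 2) / (h / 2 - 4), (cc - w / 2) / (w / 2 - 4))
    interior = np.clip(1.0 - norm, 0, 1)
    alpha = np.where(norm <= 1.0, 0.2, 0.0)
    rim = (norm > 0.82) & (norm <= 1.0)
    alpha[rim] = 0.32
    alpha *= np.clip(interior / 0.05, 0, 1)  # feather the outermost edge
    rgba = np.empty((h, w, 4))
    rgba[..., :3] = np.array([238.0, 228.0, 205.0])
    rgba[rim, :3] = np.array([250.0, 246.0, 232.0])
    rgba[..., 3] = np.clip(alpha, 0, 0.4)
    return OverlayTemplate(rgba=rgba, kind="fingerprint", variant=1)


def generate_template_bank(seed: int, out_dir: str | Path) -> None:
    """Write the full RGBA template bank: 3 spots, 10 threads, 20 squames, 1 drop."""
    out_dir = Path(out_dir)
    makers = {
        "dark_spot": _make_dark_spot,
        "thread": _make_thread,
        "squamous": _make_squamous,
    }
    for kind, n in BANK_SIZES.items():
        (out_dir / kind).mkdir(parents=True, exist_ok=True)
        for variant in range(1, n + 1):
            rng = np.random.default_rng(
                [seed, zlib.crc32(kind.encode()) % (2**31), variant]
            )
            if kind == "fingerprint":
                template = _make_fingerprint(rng)
            else:
                template = makers[kind](rng, variant)
            template.save(out_dir / kind / f"{variant:02d}.png")


# ---------------------------------------------------------------------------
# staining-scheme bank
# ---------------------------------------------------------------------------

#: Global concentration gain per scheme, spanning weak (pale) to strong
#: (oversaturated) staining; REF is the reference the classifier expects.
SCHEME_GAINS = {
    "REF": 1.0,
    "S01": 0.40, "S02": 0.55, "S03": 0.70, "S04": 0.85, "S05": 1.00,
    "S06": 1.15, "S07": 1.30, "S08": 1.45, "S09": 1.60,
}


def _scheme_stain_matrix(scheme_id: str, rng: np.random.Generator) -> np.ndarray:
    """Reference matrix for REF; slightly rotated hue variants otherwise."""
    if scheme_id == "REF":
        return REFERENCE_STAIN_MATRIX
    jitter = rng.uniform(-0.06, 0.06, size=(3, 2))
    m = np.clip(REFERENCE_STAIN_MATRIX + jitter, 0.01, None)
    return _unit_columns(m)


def generate_scheme_bank(seed: int, out_dir: str | Path) -> None:
    """Write REF.png plus S01.png .. S09.png representative staining images.

    Each scheme renders the same glandular tissue geometry under a
    scheme-specific stain matrix and concentration gain, giving a bank that
    spans weak to strong staining with varied hue.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, scheme_id in enumerate(SCHEME_GAINS):
        rng = np.random.default_rng([seed, 7919, i])
        matrix = _scheme_stain_matrix(scheme_id, rng)
        lp = generate_patch(
            "GLAND",
            seed=int(np.random.default_rng([seed, 104729]).integers(0, 2**31 - 1)),
            stain_matrix=matrix,
            gain=SCHEME_GAINS[scheme_id],
            patch_id=scheme_id,
        )
        write_patch(lp.patch, out_dir / f"{scheme_id}.png")
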