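import numpy as np
import pytest
from scipy.ndimage import binary_dilation, laplace

from histostress import (
    OverlayTemplate,
    Placement,
    RGBPatch,
    apply_dark_spots,
    apply_fingerprint,
    apply_squamous,
    apply_thread,
    composite,
)
from histostress.overlay_artifacts import BANK_SIZES, THREAD_HALO_RADIUS


def changed_mask(before, after):
    return np.any(before.pixels != after.pixels, axis=2)


def reach_mask(op, seed):
    """Pixels an op can possibly touch: union of its diffs on white and black.

    A template pixel with opacity a and color c moves a white patch by
    a*(255-c) and a black patch by a*c; both are sub-rounding only when
    a*255 < 1, in which case no 8-bit patch can change either.  The same rng
    seed reproduces the same placements on every call.
    """
    white = RGBPatch(np.full((300, 300, 3), 255, dtype=np.uint8), id="w")
    black = RGBPatch(np.zeros((300, 300, 3), dtype=np.uint8), id="b")
    return changed_mask(white, op(white, seed)) | changed_mask(black, op(black, seed))


class TestComposite:
    def test_transparent_template_is_noop(self, textured_patch):
        template = OverlayTemplate(np.zeros((10, 10, 4)), kind="dark_spot")
        out = composite(textured_patch, template, Placement(5, 5))
        assert np.array_equal(out.pixels, textured_patch.pixels)

    def test_opaque_black_square(self, textured_patch):
        rgba = np.zeros((10, 10, 4))
        rgba[..., 3] = 1.0
        out = composite(textured_patch, OverlayTemplate(rgba, kind="dark_spot"), Placement(0, 0))
        assert np.all(out.pixels[:10, :10] == 0)
        assert np.array_equal(out.pixels[10:], textured_patch.pixels[10:])
        assert np.array_equal(out.pixels[:10, 10:], textured_patch.pixels[:10, 10:])

    def test_half_alpha_gray_over_white(self):
        white = RGBPatch(np.full((20, 20, 3), 255, dtype=np.uint8))
        rgba = np.empty((4, 4, 4))
        rgba[..., :3] = 128.0
        rgba[..., 3] = 0.5
        out = composite(white, OverlayTemplate(rgba, kind="dark_spot"), Placement(2, 2))
        assert np.all(np.isin(out.pixels[2:6, 2:6], (191, 192)))

    def test_template_larger_than_patch_rejected(self):
        small = RGBPatch(np.zeros((8, 8, 3), dtype=np.uint8))
        rgba = np.zeros((10, 10, 4))
        with pytest.raises(ValueError):
            composite(small, OverlayTemplate(rgba, kind="dark_spot"), Placement(0, 0))


class TestDarkSpots:
    def test_seeded_determinism(self, gland_patch, template_bank):
        a = apply_dark_spots(gland_patch, template_bank, 2, 2, np.random.default_rng(5))
        b = apply_dark_spots(gland_patch, template_bank, 2, 2, np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_footprint_grows_with_count(self, gland_patch, template_bank):
        areas = []
        for count in (1, 2, 3):
            out = apply_dark_spots(gland_patch, template_bank, 1, count, np.random.default_rng(8))
            areas.append(changed_mask(gland_patch, out).sum())
        assert areas[0] <= areas[1] <= areas[2]

    def test_biggest_spot_type_has_largest_footprint(self, template_bank):
        small = template_bank.get("dark_spot", 1).footprint.sum()
        big = template_bank.get("dark_spot", 3).footprint.sum()
        assert big > small

    def test_spots_darken_their_footprint(self, gland_patch, template_bank):
        out = apply_dark_spots(gland_patch, template_bank, 3, 1, np.random.default_rng(2))
        mask = changed_mask(gland_patch, out)
        assert out.pixels[mask].mean() < gland_patch.pixels[mask].mean()

    def test_locality(self, gland_patch, template_bank):
        op = lambda p, s: apply_dark_spots(p, template_bank, 2, 3, np.random.default_rng(s))
        reach = reach_mask(op, 31)
        assert np.all(reach[changed_mask(gland_patch, op(gland_patch, 31))])


class TestThread:
    def test_locality_within_halo(self, gland_patch, template_bank):
        op = lambda p, s: apply_thread(p, template_bank, rng=np.random.default_rng(s))
        # on uniform patches blur has no effect, so the reach mask is the
        # composited footprint; the halo extends it by the defocus radius
        footprint = reach_mask(op, 17)
        ry, rx = np.ogrid[-THREAD_HALO_RADIUS:THREAD_HALO_RADIUS + 1,
                          -THREAD_HALO_RADIUS:THREAD_HALO_RADIUS + 1]
        disk = ry**2 + rx**2 <= THREAD_HALO_RADIUS**2
        halo = binary_dilation(footprint, structure=disk)
        assert np.all(halo[changed_mask(gland_patch, op(gland_patch, 17))])

    def test_determinism(self, gland_patch, template_bank):
        a = apply_thread(gland_patch, template_bank, variant=4, rng=np.random.default_rng(1))
        b = apply_thread(gland_patch, template_bank, variant=4, rng=np.random.default_rng(1))
        assert np.array_equal(a.pixels, b.pixels)

    def test_halo_blurs_underlying_texture(self, textured_patch, template_bank):
        out = apply_thread(textured_patch, template_bank, rng=np.random.default_rng(9))
        mask = changed_mask(textured_patch, out)
        luma_in = textured_patch.pixels.astype(np.float64).mean(axis=2)
        luma_out = out.pixels.astype(np.float64).mean(axis=2)
        assert np.sum(laplace(luma_out)[mask] ** 2) < np.sum(laplace(luma_in)[mask] ** 2)


class TestSquamous:
    def test_changed_area_nondecreasing_in_count(self, gland_patch, template_bank):
        areas = [
            changed_mask(
                gland_patch,
                apply_squamous(gland_patch, template_bank, count, np.random.default_rng(3)),
            ).sum()
            for count in (1, 2, 3)
        ]
        assert areas[0] <= areas[1] <= areas[2]

    def test_determinism(self, gland_patch, template_bank):
        a = apply_squamous(gland_patch, template_bank, 2, np.random.default_rng(7))
        b = apply_squamous(gland_patch, template_bank, 2, np.random.default_rng(7))
        assert np.array_equal(a.pixels, b.pixels)

    def test_locality(self, gland_patch, template_bank):
        op = lambda p, s: apply_squamous(p, template_bank, 2, np.random.default_rng(s))
        reach = reach_mask(op, 23)
        assert np.all(reach[changed_mask(gland_patch, op(gland_patch, 23))])


class TestFingerprint:
    def test_changed_fraction_below_half(self, gland_patch, template_bank):
        out = apply_fingerprint(gland_patch, template_bank, np.random.default_rng(6))
        assert changed_mask(gland_patch, out).mean() < 0.5

    def test_determinism(self, gland_patch, template_bank):
        a = apply_fingerprint(gland_patch, template_bank, np.random.default_rng(4))
        b = apply_fingerprint(gland_patch, template_bank, np.random.default_rng(4))
        assert np.array_equal(a.pixels, b.pixels)

    def test_locality(self, gland_patch, template_bank):
        op = lambda p, s: apply_fingerprint(p, template_bank, np.random.default_rng(s))
        reach = reach_mask(op, 12)
        assert np.all(reach[changed_mask(gland_patch, op(gland_patch, 12))])


def test_bank_sizes_match_template_inventory(template_bank):
    assert BANK_SIZES == {"dark_spot": 3, "thread": 10, "squamous": 20, "fingerprint": 1}
    for kind, n in BANK_SIZES.items():
        for variant in range(1, n + 1):
            t = template_bank.get(kind, variant)
            assert 0 <= t.rgba[..., 3].min() and t.rgba[..., 3].max() <= 1
        with pytest.raises(ValueError):
            template_bank.get(kind, n + 1)
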