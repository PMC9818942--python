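"""Contourlet and curvelet decompositions: reconstruction, energy, addressing."""

import numpy as np
import pytest

from cwriig.keys import SubbandKey, default_contourlet_keys, default_curvelet_keys
from cwriig.transforms import (
    contourlet_decompose,
    contourlet_reconstruct,
    curvelet_decompose,
    curvelet_reconstruct,
    select_subbands,
)


class TestContourlet:
    def test_round_trip_random_images(self):
        for seed in (0, 1, 2):
            x = np.random.default_rng(seed).random((256, 256))
            dec = contourlet_decompose(x)
            assert np.abs(contourlet_reconstruct(dec) - x).max() < 1e-8

    def test_round_trip_impulse(self):
        x = np.zeros((64, 64))
        x[31, 17] = 1.0
        dec = contourlet_decompose(x, [(4,), (8,)])
        assert np.abs(contourlet_reconstruct(dec) - x).max() < 1e-8

    def test_constant_image_has_zero_directional_bands(self):
        dec = contourlet_decompose(np.full((128, 128), 0.37))
        worst = max(
            np.abs(b).max()
            for by_count in dec.levels.values()
            for bands in by_count.values()
            for b in bands
        )
        assert worst < 1e-10
        assert abs(dec.lowpass.mean() - 0.37) < 1e-12  # DC energy in the lowpass

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((64, 64)), rng.random((64, 64))
        a, b = 0.7, -1.3
        d1 = contourlet_decompose(a * x + b * y, [(4,), (8,)])
        dx = contourlet_decompose(x, [(4,), (8,)])
        dy = contourlet_decompose(y, [(4,), (8,)])
        for lvl in d1.levels:
            for cnt in d1.levels[lvl]:
                for bc, bx, by in zip(d1.levels[lvl][cnt], dx.levels[lvl][cnt], dy.levels[lvl][cnt]):
                    assert np.abs(bc - (a * bx + b * by)).max() < 1e-10

    def test_band_extent_shrinks_with_direction_count(self, speckle_image):
        dec = contourlet_decompose(speckle_image)
        # level 4 bandpass is full-res; its 32-direction bands are 1/32 the area
        areas = {d: dec.levels[4][d][0].size for d in (16, 32)}
        assert areas[16] == 256 * 256 // 16
        assert areas[32] == 256 * 256 // 32

    def test_all_zero_decomposition_reconstructs_to_zero(self):
        dec = contourlet_decompose(np.zeros((64, 64)), [(4,), (8,)])
        assert np.abs(contourlet_reconstruct(dec)).max() == 0.0

    @pytest.mark.parametrize(
        "bad, err",
        [
            ({"directions_per_level": [(3,), (8,)]}, "power of 2"),
            ({"directions_per_level": [(4,)] * 7}, "divisible"),
        ],
    )
    def test_invalid_arguments(self, bad, err):
        x = np.random.default_rng(0).random((64, 64))
        with pytest.raises(ValueError, match=err):
            contourlet_decompose(x, **bad)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            contourlet_decompose(np.random.default_rng(0).random((16, 16)), [(4,)])


class TestCurvelet:
    def test_parseval(self, random_image):
        dec = curvelet_decompose(random_image)
        ratio = dec.energy() / np.sum(random_image**2)
        assert abs(ratio - 1.0) <= 1e-6

    def test_round_trip(self, random_image, speckle_image):
        for x in (random_image, speckle_image):
            dec = curvelet_decompose(x)
            assert np.abs(curvelet_reconstruct(dec) - x).max() < 1e-6

    def test_round_trip_impulse(self):
        x = np.zeros((128, 128))
        x[64, 64] = 1.0
        dec = curvelet_decompose(x, 4, (16, 32, 32))
        assert np.abs(curvelet_reconstruct(dec) - x).max() < 1e-6

    def test_constant_image_energy_in_coarse(self):
        dec = curvelet_decompose(np.full((128, 128), 0.5), 4, (16, 32, 32))
        worst = max(np.abs(w).max() for g in dec.wedges.values() for w in g)
        assert worst < 1e-10
        assert abs(np.sum(np.abs(dec.coarse) ** 2) - 128 * 128 * 0.25) < 1e-6

    def test_zero_coefficients_give_zero_image(self, random_image):
        dec = curvelet_decompose(random_image)
        dec.coarse[...] = 0
        for g in dec.wedges.values():
            for w in g:
                w[...] = 0
        assert np.abs(curvelet_reconstruct(dec)).max() == 0.0

    def test_angle_count_must_divide_by_four(self, random_image):
        with pytest.raises(ValueError, match="divisible by 4"):
            curvelet_decompose(random_image, 3, (16, 18))


class TestSelection:
    def test_default_contourlet_keys_resolve(self, speckle_image):
        dec = contourlet_decompose(speckle_image)
        subs = select_subbands(dec, default_contourlet_keys())
        assert [s.key.short_name for s in subs] == [
            "P2D4", "P2D8", "P3D8", "P3D16", "P4D16", "P4D32"
        ]
        assert all(min(s.shape) >= 13 for s in subs)

    def test_default_curvelet_keys_resolve_nonnegative(self, speckle_image):
        dec = curvelet_decompose(speckle_image)
        subs = select_subbands(dec, default_curvelet_keys())
        assert len(subs) == 6
        assert all(s.coeffs.min() >= 0 for s in subs)  # magnitudes
        assert [s.key.short_name for s in subs] == [
            "S2A16", "S3A32", "S4A32", "S5A16", "S5A32", "S5A64"
        ]

    def test_unresolvable_key_raises_keyerror_naming_key(self, speckle_image):
        dec = contourlet_decompose(speckle_image)
        with pytest.raises(KeyError, match="P9D4"):
            select_subbands(dec, [SubbandKey("contourlet", 9, 4)])

    def test_key_name_parsing_round_trip(self):
        k = SubbandKey.from_name("S5A64", index=3)
        assert (k.transform, k.level, k.n_directions, k.index) == ("curvelet", 5, 64, 3)
        with pytest.raises(ValueError):
            SubbandKey.from_name("X1Y2")
        with pytest.raises(ValueError):
            SubbandKey("contourlet", 2, 5)  # not a power of two
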