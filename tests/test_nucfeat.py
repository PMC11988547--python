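"""Feature oracles: colour stats, moments/Hu, shape descriptors, wavelet texture."""

import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse
from skimage.measure import (moments_central, moments_hu, moments_normalized)

from lungmorph.nucfeat import (FEATURE_COLUMNS, color_stats, extract_features,
                               geometric_moments, hu_moments,
                               shape_descriptors, wavelet_texture)
from lungmorph.segment import NucleusInstance, binarize_and_label


def _instance_from_mask(mask):
    insts = binarize_and_label(np.asarray(mask, float))
    assert len(insts) == 1
    return insts[0]


# ---------------------------------------------------------------- colour ----
class TestColorStats:
    def test_uniform_nucleus(self):
        tile = np.zeros((10, 10, 3), dtype=np.uint8)
        tile[2:5, 2:5] = (120, 30, 200)
        m = np.zeros((10, 10))
        m[2:5, 2:5] = 1
        inst = _instance_from_mask(m)
        r, g, b, rv, gv, bv = color_stats(tile, inst)
        assert (r, g, b) == (120, 30, 200)
        assert (rv, gv, bv) == (0, 0, 0)

    def test_population_variance_two_pixels(self):
        tile = np.zeros((2, 2, 3), dtype=np.uint8)
        tile[0, 0, 0], tile[0, 1, 0] = 0, 2
        m = np.zeros((2, 2))
        m[0, :] = 1
        inst = _instance_from_mask(m)
        stats = color_stats(tile, inst)
        assert stats[0] == 1.0 and stats[3] == 1.0  # R mean, population R var

    def test_matches_loop_summation(self, rng):
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        m = np.zeros((16, 16))
        idx = rng.choice(256, 50, replace=False)
        m[np.unravel_index(idx, (16, 16))] = 1
        # loop oracle over a connected version is unnecessary: compute directly
        coords = np.argwhere(m)
        inst = NucleusInstance(label=1, coords=coords, area=50.0,
                               perimeter=1.0, compactness=1.0)
        got = color_stats(tile, inst)
        for ch in range(3):
            vals = [float(tile[r, c, ch]) for r, c in coords]
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / len(vals)
            assert got[ch] == pytest.approx(mean)
            assert got[3 + ch] == pytest.approx(var)

    def test_empty_pixel_set_rejected(self):
        inst = NucleusInstance(label=1, coords=np.zeros((0, 2), int),
                               area=0, perimeter=1, compactness=1)
        with pytest.raises(ValueError):
            color_stats(np.zeros((4, 4, 3), np.uint8), inst)


# --------------------------------------------------------------- moments ----
def naive_hu(mask):
    """Brute-force double-loop evaluation of the moment pipeline."""
    h, w = mask.shape
    m = np.zeros((4, 4))
    for p in range(4):
        for q in range(4):
            m[p, q] = sum(x ** p * y ** q
                          for y in range(h) for x in range(w) if mask[y, x])
    xb, yb = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
    mu = np.zeros((4, 4))
    for p in range(4):
        for q in range(4):
            mu[p, q] = sum((x - xb) ** p * (y - yb) ** q
                           for y in range(h) for x in range(w) if mask[y, x])
    eta = np.zeros((4, 4))
    for p in range(4):
        for q in range(4):
            eta[p, q] = mu[p, q] / mu[0, 0] ** ((p + q) / 2 + 1)
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03, n21, n12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]
    return np.array([
        n20 + n02,
        (n20 - n02) ** 2 + 4 * n11 ** 2,
        (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2,
        (n30 + n12) ** 2 + (n21 + n03) ** 2,
        (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
        (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
        + 4 * n11 * (n30 + n12) * (n21 + n03),
        (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
        - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2),
    ])


class TestMoments:
    @pytest.mark.parametrize("seed", range(4))
    def test_moment_invariants_hold(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((12, 15)) > 0.6).astype(np.uint8)
        mask[6, 7] = 1
        ms = geometric_moments(mask)
        assert ms.mu[0, 0] == ms.m[0, 0] > 0
        assert ms.mu[1, 0] == pytest.approx(0, abs=1e-9)
        assert ms.mu[0, 1] == pytest.approx(0, abs=1e-9)
        assert ms.eta[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_hu_equals_naive_summation(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = (rng.random((9, 7)) > 0.5).astype(np.uint8)
        mask[4, 3] = 1
        np.testing.assert_allclose(hu_moments(mask), naive_hu(mask),
                                   rtol=1e-7, atol=1e-14)

    def test_translation_invariance_is_bit_exact(self, rng):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[5:14, 8:15] = (rng.random((9, 7)) > 0.4)
        mask[9, 11] = 1
        shifted = np.roll(np.roll(mask, 17, axis=0), 23, axis=1)
        assert np.array_equal(hu_moments(mask), hu_moments(shifted))

    def test_quarter_turn_invariance_machine_precision(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:20, 8:14] = 1
        mask[10:12, 14:22] = 1
        np.testing.assert_allclose(hu_moments(mask), hu_moments(np.rot90(mask)),
                                   rtol=1e-10, atol=1e-30)

    def test_cross_check_against_skimage(self, rng):
        """Independent library evaluation agrees; the axis-swapped convention
        is a reflection, which flips the sign of the seventh invariant only."""
        mask = (rng.random((20, 24)) > 0.5).astype(np.uint8)
        mask[10, 12] = 1
        sk = moments_hu(moments_normalized(moments_central(mask.astype(float))))
        mine = hu_moments(mask)
        np.testing.assert_allclose(mine[:6], sk[:6], rtol=1e-7, atol=1e-14)
        np.testing.assert_allclose(mine[6], -sk[6], rtol=1e-7, atol=1e-14)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hu_moments(np.zeros((5, 5)))


# ---------------------------------------------------------------- shapes ----
class TestShapeDescriptors:
    def test_rasterized_disc_is_nearly_circular(self):
        """The chain-code perimeter overestimates smooth contours by 3-5%,
        so a digital disc's circularity sits just below 1 (rasterisation
        study: 0.92-0.98 over radii 10-60)."""
        m = np.zeros((101, 101), np.uint8)
        rr, cc = disk((50, 50), 40)
        m[rr, cc] = 1
        a, p, circ, comp, ecc = shape_descriptors(_instance_from_mask(m))
        assert 0.90 <= circ <= 1.0
        assert ecc <= 0.15
        assert comp == pytest.approx(4 * math.pi / circ)

    def test_five_three_ellipse_eccentricity(self):
        """a:b = 5:3 gives E = sqrt(25-9)/5 = 0.8 up to raster tolerance."""
        m = np.zeros((101, 101), np.uint8)
        rr, cc = ellipse(50, 50, 30, 18)
        m[rr, cc] = 1
        ecc = shape_descriptors(_instance_from_mask(m))[4]
        assert ecc == pytest.approx(0.8, abs=0.02)

    @pytest.mark.parametrize("seed", range(3))
    def test_compactness_times_circularity_is_4pi(self, seed, small_cohort):
        from lungmorph.synthetic import render_tile

        r = render_tile(small_cohort[seed], 6, seed=40 + seed, tile_size=96)
        for inst in binarize_and_label(r.mask.astype(float)):
            _, _, circ, comp, _ = shape_descriptors(inst)
            assert circ * comp == pytest.approx(4 * math.pi, rel=1e-12)

    def test_degenerate_line_region_clamped(self):
        m = np.zeros((3, 12))
        m[1, 1:11] = 1
        ecc = shape_descriptors(_instance_from_mask(m))[4]
        assert 0 <= ecc < 1


# --------------------------------------------------------------- wavelet ----
def naive_cd(patch):
    """Row-then-column decimated Haar filtering (the plain filter bank)."""
    h = np.array([1.0, -1.0]) / np.sqrt(2.0)
    dh = patch[:, 0::2] * h[0] + patch[:, 1::2] * h[1]
    return dh[0::2, :] * h[0] + dh[1::2, :] * h[1]


class TestWaveletTexture:
    def _inst(self, side):
        m = np.ones((side, side))
        return _instance_from_mask(m)

    def test_constant_patch_has_zero_cd(self):
        tile = np.full((8, 8, 3), 99, dtype=np.uint8)
        inst = self._inst(8)
        assert wavelet_texture(tile, inst) == (0.0, 0.0)

    def test_2x2_hand_evaluation(self):
        """cD of [[1,0],[0,1]] with g=(1,1)/sqrt2, h=(1,-1)/sqrt2 equals 1
        for the double high-pass: rows give (1,-1)/sqrt2, columns give 1."""
        tile = np.zeros((2, 2, 3), dtype=np.uint8)
        tile[0, 0] = tile[1, 1] = (255, 255, 255)
        inst = self._inst(2)
        cd_avg, cd_var = wavelet_texture(tile, inst)
        gray = 255.0 * (0.2125 + 0.7154 + 0.0721)
        assert cd_avg == pytest.approx(gray)
        assert cd_var == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_separable_transform_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        inst = self._inst(16)
        cd_avg, cd_var = wavelet_texture(tile, inst)
        gray = (tile[..., 0] * 0.2125 + tile[..., 1] * 0.7154
                + tile[..., 2] * 0.0721)
        cd = naive_cd(gray)
        assert cd_avg == pytest.approx(cd.mean(), rel=1e-12)
        assert cd_var == pytest.approx(cd.var(), rel=1e-12)

    def test_tile_scope(self, rng):
        tile = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        inst = _instance_from_mask(np.pad(np.ones((4, 4)), 6))
        nuc = wavelet_texture(tile, inst, scope="nucleus")
        whole = wavelet_texture(tile, inst, scope="tile")
        assert nuc != whole

    def test_too_small_patch_rejected(self):
        tile = np.zeros((4, 4, 3), dtype=np.uint8)
        inst = NucleusInstance(label=1, coords=np.array([[1, 1]]), area=1,
                               perimeter=1, compactness=1)
        with pytest.raises(ValueError, match="minimum side"):
            wavelet_texture(tile, inst)


# --------------------------------------------------------- feature table ----
class TestExtractFeatures:
    def test_empty_instance_list(self):
        df = extract_features(np.zeros((8, 8, 3), np.uint8), [])
        assert len(df) == 0
        assert list(df.columns[3:]) == list(FEATURE_COLUMNS)
        assert len(FEATURE_COLUMNS) == 20

    def test_one_row_per_instance(self, rendered):
        insts = binarize_and_label(rendered.mask.astype(float))
        df = extract_features(rendered.tile, insts, patient_id="p", tile_id="t")
        assert len(df) == len(insts)
        assert df[list(FEATURE_COLUMNS)].notna().all().all()

    def test_eccentric_separates_discs_from_ellipses(self):
        """Discs (E=0) vs 3:1 ellipses (E=0.943): mean Eccentric gap > 0.5."""
        tile = np.zeros((256, 256, 3), dtype=np.uint8)
        m_disc = np.zeros((256, 256))
        m_ell = np.zeros((256, 256))
        for i in range(3):
            rr, cc = disk((40 + 80 * i, 60), 15)
            m_disc[rr, cc] = 1
            rr, cc = ellipse(40 + 80 * i, 170, 10, 30)
            m_ell[rr, cc] = 1
        e_disc = extract_features(tile, binarize_and_label(m_disc)).Eccentric
        e_ell = extract_features(tile, binarize_and_label(m_ell)).Eccentric
        assert e_ell.mean() - e_disc.mean() > 0.5
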