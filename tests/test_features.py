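"""Texture-bank correctness: hand examples, degenerate cases, and
equivalence with independently coded brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import random_block
from ultratex import FEATURE_IDS, FEATURE_NAMES, N_FEATURES, extract_all, feature_name
from ultratex.config import MatrixFamilyConfig
from ultratex.features import histogram, glcm, sfm, glrlm, laws, ngldm, ngtdm, local_fourier
from ultratex.features.wavelet import wavelet_ll

CFG = MatrixFamilyConfig()


# ---------------------------------------------------------------------------
# hand-derived examples

class TestHistogram:
    def test_constant_block_degenerate_vector(self):
        f = histogram.histogram_features(np.full((5, 5), 100))
        assert f["Mean"] == 100 and f["Variance"] == 0 and f["Standard Deviation"] == 0
        assert f["Entropy"] == 0 and f["Energy"] == 1
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_half_and_half_block(self):
        block = np.array([[0] * 4] * 2 + [[1] * 4] * 2)
        f = histogram.histogram_features(block)
        assert f["Mean"] == 0.5 and f["Variance"] == 0.25
        assert f["Entropy"] == pytest.approx(1.0) and f["Energy"] == pytest.approx(0.5)


class TestGLCM:
    def test_two_row_image_single_angle(self):
        # horizontal pairs of [[0,0],[1,1]]: (0,0) and (1,1) once each
        P = glcm.cooccurrence_matrix(np.array([[0, 0], [1, 1]]), 2, 1, 0)
        np.testing.assert_allclose(P, np.diag([0.5, 0.5]))
        f = glcm.glcm_features_single(P)
        assert f["Energy"] == pytest.approx(0.5)
        assert f["Contrast"] == 0
        assert f["Correlation"] == pytest.approx(1.0)

    def test_constant_image_all_mass_on_diagonal(self):
        f = glcm.glcm_features(np.zeros((6, 6), dtype=int), 32)
        assert f["Energy"] == 1 and f["Contrast"] == 0
        assert f["Entropy"] == 0 and f["Local homogeneity"] == 1

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            glcm.cooccurrence_matrix(np.zeros((2, 2), dtype=int), 2, 5, 0)


class TestSFM:
    def test_constant_image_zero(self):
        assert sfm.sfm_dissimilarity(np.zeros((4, 4)))["Dissimilarity"] == 0

    def test_vertical_stripes_horizontal_displacement(self):
        stripes = np.tile([0, 1, 0, 1], (4, 1))
        f = sfm.sfm_dissimilarity(stripes, displacements=((0, 1),))
        assert f["Dissimilarity"] == pytest.approx(1.0)


class TestGLRLM:
    def test_single_row_hand_runs(self):
        mat = glrlm.run_length_matrix(np.array([[0, 0, 0, 1, 1]]), 2, 0)
        f = glrlm.glrlm_features_single(mat, 5)
        assert f["Short-run emphasis"] == pytest.approx((1 / 9 + 1 / 4) / 2)
        assert f["Long-run emphasis"] == pytest.approx(6.5)
        assert f["Run percentage"] == pytest.approx(0.4)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_constant_square_forced_values(self, n):
        mat = glrlm.run_length_matrix(np.zeros((n, n), dtype=int), 2, 0)
        f = glrlm.glrlm_features_single(mat, n * n)
        assert f["Short-run emphasis"] == pytest.approx(1 / n**2)
        assert f["Run percentage"] == pytest.approx(1 / n)


class TestLaws:
    def test_constant_image_all_zero(self):
        f = laws.laws_features(np.full((8, 8), 9.0), CFG.laws_vectors)
        assert all(v == 0 for v in f.values())

    def test_unit_impulse_mean_is_mask_l1_over_area(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        masks = laws.laws_masks(CFG.laws_vectors)
        f = laws.laws_features(img, CFG.laws_vectors)
        for name, mask in masks.items():
            # valid responses collect every mask coefficient exactly once
            assert f[f"{name} mean"] == pytest.approx(np.abs(mask).sum() / 25)


class TestNGLDM:
    def test_constant_image_single_cell(self):
        f = ngldm.ngldm_features(np.zeros((5, 5), dtype=int), 32, 1, 0)
        assert f["Small number emphasis"] == pytest.approx(1 / 64)
        assert f["Large number emphasis"] == pytest.approx(64)
        assert f["Entropy"] == 0

    def test_checkerboard_diagonal_matches(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        f = ngldm.ngldm_features(board, 2, 1, 0)
        assert f["Large number emphasis"] == pytest.approx(16)


class TestNGTDM:
    def test_constant_image_guarded(self):
        f = ngtdm.ngtdm_features(np.zeros((5, 5), dtype=int), 32, 1, epsilon=1e-6)
        assert f["Contrast"] == 0 and f["Busyness"] == 0 and f["Complexity"] == 0
        assert f["Coarseness"] == pytest.approx(1e6)

    def test_single_raised_pixel_contrast(self):
        img = np.zeros((5, 5), dtype=int)
        img[2, 2] = 4
        f = ngtdm.ngtdm_features(img, 8, 1)
        assert f["Contrast"] == pytest.approx(oracles.ngtdm_oracle(img, 8, 1)[3])


class TestWavelet:
    def test_constant_gain_two(self):
        ll = wavelet_ll(np.full((10, 10), 3.0))
        np.testing.assert_allclose(ll, 6.0)

    def test_ll_dimensions_23(self):
        assert wavelet_ll(np.zeros((23, 23))).shape == (12, 12)


class TestLocalFourier:
    def test_constant_dc_only(self):
        f = local_fourier.local_fourier_features(np.full((5, 5), 3.0))
        assert f["Mean of magnitude 0"] == pytest.approx(24.0)
        for u in range(1, 8):
            assert f[f"Mean of magnitude {u}"] == pytest.approx(0.0, abs=1e-12)
        for u in range(8):
            assert f[f"SD of magnitude {u}"] == pytest.approx(0.0, abs=1e-12)
            assert f[f"SD of phase angle {u}"] == pytest.approx(0.0, abs=1e-12)

    def test_unit_impulse_flat_spectrum(self):
        # a single neighbour equal to 1 gives |F_u| = 1 for every u
        img = np.zeros((3, 3))
        img[1, 2] = 1.0  # the "east" neighbour of the only interior pixel
        f = local_fourier.local_fourier_features(img)
        for u in range(8):
            assert f[f"Mean of magnitude {u}"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

FAMILY_CASES = {
    "histogram": (
        lambda b: list(histogram.histogram_features(b).values()),
        lambda b: oracles.hist_oracle(b),
    ),
    "glcm": (
        lambda b: list(glcm.glcm_features(b, 32).values()),
        lambda b: oracles.glcm_oracle(b, 32),
    ),
    "sfm": (
        lambda b: list(sfm.sfm_dissimilarity(b).values()),
        lambda b: [oracles.sfm_oracle(b)],
    ),
    "glrlm": (
        lambda b: list(glrlm.glrlm_features(b, 32).values()),
        lambda b: oracles.glrlm_oracle(b, 32),
    ),
    "laws": (
        lambda b: list(laws.laws_features(b, CFG.laws_vectors).values()),
        lambda b: oracles.laws_oracle(b, CFG.laws_vectors),
    ),
    "ngldm": (
        lambda b: list(ngldm.ngldm_features(b, 32).values()),
        lambda b: oracles.ngldm_oracle(b, 32),
    ),
    "ngtdm": (
        lambda b: list(ngtdm.ngtdm_features(b, 32).values()),
        lambda b: oracles.ngtdm_oracle(b, 32),
    ),
    "wavelet_ll": (
        lambda b: wavelet_ll(np.asarray(b, float)).ravel().tolist(),
        lambda b: oracles.haar_ll_oracle(b).ravel().tolist(),
    ),
    "local_fourier": (
        lambda b: list(local_fourier.local_fourier_features(b).values()),
        lambda b: oracles.local_fourier_oracle(b),
    ),
}


@pytest.mark.parametrize("family", sorted(FAMILY_CASES))
def test_family_matches_brute_force_oracle(family):
    """Each family agrees with its naive-loop oracle on seeded random blocks."""
    impl, oracle = FAMILY_CASES[family]
    rng = np.random.default_rng(hash(family) % 2**31)
    n_blocks = 20  # the acceptance suite runs the full 100-block sweep
    for _ in range(n_blocks):
        block = random_block(rng)
        np.testing.assert_allclose(
            impl(block), oracle(block), rtol=1e-8, atol=1e-10, err_msg=family
        )


# ---------------------------------------------------------------------------
# the assembled 126-vector

class TestExtractAll:
    def test_exactly_126_finite_values_and_determinism(self, rng):
        block = random_block(rng, size=23, levels=256)
        v1, v2 = extract_all(block), extract_all(block)
        assert v1.shape == (126,) and np.isfinite(v1).all()
        np.testing.assert_array_equal(v1, v2)

    def test_family_slices_equal_family_operations(self, rng):
        from ultratex.image import quantize

        block = random_block(rng, size=23, levels=256)
        v = extract_all(block)
        q = quantize(block, 32)
        np.testing.assert_allclose(
            v[:7], list(histogram.histogram_features(block).values())
        )
        np.testing.assert_allclose(v[7:20], list(glcm.glcm_features(q, 32).values()))
        np.testing.assert_allclose(
            v[26:36], list(laws.laws_features(block, CFG.laws_vectors).values())
        )
        # wavelet-domain slice equals re-applying families to the LL subband
        ll = wavelet_ll(block)
        qll = quantize(ll, 32)
        np.testing.assert_allclose(
            v[46:53], list(histogram.histogram_features(qll).values())
        )
        assert v[72] == pytest.approx(ll.mean())
        assert v[73] == pytest.approx(ll.std())
        np.testing.assert_allclose(
            v[94:], list(local_fourier.local_fourier_features(block).values())
        )

    def test_constant_block_fully_determined(self):
        v = extract_all(np.full((23, 23), 5))
        named = dict(zip(FEATURE_IDS, v))
        assert named["F4"] == 5  # mean
        assert named["F7"] == 0  # variance
        assert named["F16"] == 1  # co-occurrence energy
        assert named["F73"] == pytest.approx(10.0)  # LL mean = 2c
        assert named["F95"] == pytest.approx(40.0)  # ring DC = 8c

    def test_histogram_entropy_and_energy_bounds(self, rng):
        for _ in range(10):
            v = extract_all(random_block(rng, levels=256))
            named = dict(zip(FEATURE_IDS, v))
            assert 0 <= named["F2"] <= np.log2(256)
            assert 0 < named["F1"] <= 1
            assert 0 < named["F26"] <= 1  # run percentage

    def test_too_small_block_rejected(self):
        with pytest.raises(ValueError):
            extract_all(np.zeros((8, 8), dtype=int))


def test_feature_naming_table_order():
    assert N_FEATURES == 126 and len(FEATURE_NAMES) == 126
    assert feature_name("F4") == "Mean"
    assert feature_name("F21") == "Dissimilarity"
    assert feature_name("F43") == "Coarseness"
    assert feature_name(126).startswith("SD of phase angle")
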