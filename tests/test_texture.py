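"""Texture feature families: closed forms, invariances, oracle spot checks."""

import numpy as np
import pytest

import reference_impl as ref
from equitherm.texture import (
    FAMILY_NAMES,
    GLCMConfig,
    N_FEATURES,
    ar_features,
    extract_channel,
    gabor_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    gradient_features,
    hist_features,
    hog_features,
)
from equitherm.color import ChannelImage
from equitherm.texture import _glrlm_direction_features


def full(shape):
    return np.ones(shape, dtype=bool)


def test_feature_registry_has_88_names():
    assert N_FEATURES == 88
    assert len(FAMILY_NAMES["HS"]) == 14
    assert len(FAMILY_NAMES["GM"]) == 6
    assert len(FAMILY_NAMES["AM"]) == 5
    assert len(FAMILY_NAMES["GT"]) == 24
    assert len(FAMILY_NAMES["HOG"]) == 8
    assert len(FAMILY_NAMES["GRLM"]) == 7
    assert len(FAMILY_NAMES["GLCM"]) == len(FAMILY_NAMES["GLCH"]) == 12


# ------------------------------------------------------------------ HS --

def test_hist_worked_example():
    data = np.array([[1, 2, 2], [3, 3, 3], [4, 4, 5]])
    out = hist_features(data, full((3, 3)), bit_depth=3)
    assert out["HistMean"] == pytest.approx(3.0)
    assert out["HistVariance"] == pytest.approx(12 / 9)
    assert out["HistArea"] == 9


def test_hist_constant_roi_degenerate_moments():
    out = hist_features(np.full((5, 5), 7), full((5, 5)), bit_depth=4)
    assert out["HistVariance"] == 0.0
    assert out["HistSkewness"] == 0.0 and out["HistKurtosis"] == 0.0
    for name in ("HistPerc01", "HistPerc10", "HistPerc50", "HistPerc90",
                 "HistPerc99"):
        assert out[name] == 7.0


def test_hist_percentile_monotonicity(rng):
    for _ in range(10):
        data = rng.integers(1, 257, size=(9, 9)).astype(np.int32)
        out = hist_features(data, full((9, 9)))
        percs = [out[f"HistPerc{q}"] for q in ("01", "10", "50", "90", "99")]
        assert percs == sorted(percs)


def test_hist_empty_roi_rejected():
    with pytest.raises(ValueError):
        hist_features(np.ones((4, 4), int), np.zeros((4, 4), bool))


# ------------------------------------------------------------------ GM --

def test_gradient_constant_channel():
    out = gradient_features(np.full((6, 6), 9), full((6, 6)))
    assert out["GradMean"] == 0.0
    assert out["GradNonZeros"] == 0.0


def test_gradient_unit_ramp():
    data = np.tile(np.arange(10, dtype=float), (8, 1))
    out = gradient_features(data, full((8, 10)))
    assert out["GradMean"] == pytest.approx(1.0)
    assert out["GradVariance"] == pytest.approx(0.0, abs=1e-12)
    assert out["GradNonZeros"] == 1.0
    assert out["GradArea"] == 6 * 8


def test_gradient_invariant_to_constant_offset(rng):
    data = rng.uniform(0, 255, size=(10, 10))
    a = gradient_features(data, full((10, 10)))
    b = gradient_features(data + 57.3, full((10, 10)))
    for k in a:
        assert a[k] == pytest.approx(b[k], rel=1e-12, abs=1e-12)


def test_gradient_thin_roi_rejected():
    mask = np.zeros((6, 6), dtype=bool)
    mask[2] = True  # a single row has no interior
    with pytest.raises(ValueError):
        gradient_features(np.ones((6, 6)), mask)


# ------------------------------------------------------------------ AM --

def test_ar_constant_channel_minimum_norm():
    out = ar_features(np.full((6, 6), 13.0), full((6, 6)))
    for name in ("Teta1", "Teta2", "Teta3", "Teta4"):
        assert out[name] == pytest.approx(0.25, abs=1e-9)
    assert out["sigma"] == pytest.approx(0.0, abs=1e-9)


def test_ar_row_constant_reconstruction_from_left():
    data = np.tile(np.array([[3.0], [7.0], [2.0], [9.0], [5.0]]), (1, 8))
    out = ar_features(data, full((5, 8)))
    assert out["Teta1"] == pytest.approx(1.0, abs=1e-9)
    for name in ("Teta2", "Teta3", "Teta4"):
        assert out[name] == pytest.approx(0.0, abs=1e-9)
    assert out["sigma"] == pytest.approx(0.0, abs=1e-9)


def test_ar_white_noise_small_coefficients(rng):
    data = rng.standard_normal((40, 40)) * 10 + 100
    out = ar_features(data, full((40, 40)))
    assert out["sigma"] > 0
    # prediction from uncorrelated neighbors: no coefficient dominates
    for name in ("Teta1", "Teta2", "Teta3", "Teta4"):
        assert abs(out[name]) < 0.45


# ------------------------------------------------------------------ GT --

def test_gabor_constant_channel_zero_magnitudes():
    out = gabor_features(np.full((40, 40), 77.0), full((40, 40)))
    finite = {k: v for k, v in out.items() if np.isfinite(v)}
    assert finite  # at least the small wavelengths are supported
    assert max(abs(v) for v in finite.values()) < 1e-8


def test_gabor_grating_peaks_at_matching_orientation():
    x = np.arange(48)
    grating = np.tile(50 * np.sin(2 * np.pi * x / 8.0) + 100, (48, 1))
    out = gabor_features(grating, full((48, 48)))
    for other in ("V", "N", "Z"):
        assert out["Gab8H4Mag"] > out[f"Gab8{other}4Mag"]


def test_gabor_invariant_to_constant_offset(rng):
    data = rng.uniform(0, 100, size=(30, 30))
    a = gabor_features(data, full((30, 30)))
    b = gabor_features(data + 200.0, full((30, 30)))
    for k in a:
        if np.isnan(a[k]):
            assert np.isnan(b[k])
        else:
            assert a[k] == pytest.approx(b[k], rel=1e-9, abs=1e-7)


def test_gabor_roi_below_smallest_support_rejected():
    with pytest.raises(ValueError):
        gabor_features(np.ones((12, 12)), full((12, 12)))


# ----------------------------------------------------------------- HOG --

def test_hog_constant_channel_all_zero():
    out = hog_features(np.full((6, 6), 3.0), full((6, 6)))
    assert all(v == 0.0 for v in out.values())


def test_hog_vertical_step_edge_in_first_bin():
    data = np.zeros((8, 8))
    data[:, 4:] = 10.0
    out = hog_features(data, full((8, 8)))
    assert out["HogO8b0"] == pytest.approx(1.0)
    assert sum(out.values()) == pytest.approx(1.0)


def test_hog_bins_sum_to_one(rng):
    data = rng.uniform(0, 255, size=(12, 12))
    out = hog_features(data, full((12, 12)))
    assert sum(out.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------- GRLM --

def test_glrlm_constant_square_horizontal_closed_form():
    N = 5
    data = np.full((N, N), 3)
    P = glrlm_matrix(data, full((N, N)), "0")
    out = _glrlm_direction_features(P, N * N)
    assert out["LngREmph"] == pytest.approx(N**2)
    assert out["ShrtREmp"] == pytest.approx(1 / N**2)
    assert out["Fraction"] == pytest.approx(1 / N)


def test_glrlm_checkerboard_unit_runs():
    data = (np.indices((6, 6)).sum(axis=0) % 2) + 1
    P = glrlm_matrix(data, full((6, 6)), "0")
    out = _glrlm_direction_features(P, 36)
    assert out["Fraction"] == 1.0
    assert out["LngREmph"] == 1.0
    assert out["ShrtREmp"] == 1.0


def test_glrlm_emphasis_bounds(rng):
    for _ in range(10):
        data = rng.integers(1, 5, size=(10, 10)).astype(np.int32)
        out = glrlm_features(data, full((10, 10)))
        assert out["ShrtREmp"] <= 1.0 <= out["LngREmph"]


# ---------------------------------------------------------------- GLCM --

def test_glcm_constant_roi_single_cell_matrix():
    cfg = GLCMConfig(distances=(1, 2), bit_depth=3)
    out = glcm_features(np.full((6, 6), 5), full((6, 6)), cfg)
    assert out["AngScMom"] == 1.0
    assert out["Contrast"] == 0.0
    assert out["Entropy"] == 0.0
    assert out["InvDefMom"] == 1.0
    assert out["SumOfSqs"] == 0.0


def test_glcm_checkerboard_two_cell_closed_form():
    data = (np.indices((6, 6)).sum(axis=0) % 2) + 1
    cfg = GLCMConfig(distances=(1,), directions=("0",), log_base="2",
                     bit_depth=1)
    out = glcm_features(data, full((6, 6)), cfg)
    assert out["Contrast"] == pytest.approx(1.0)
    assert out["AngScMom"] == pytest.approx(0.5)
    assert out["Entropy"] == pytest.approx(1.0)  # one bit


def test_glcm_worked_4x4_pair_enumeration():
    img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]]) + 1
    C = glcm_matrix(img, full((4, 4)), (0, 1), 4, symmetric=True)
    assert C.sum() == 24
    assert C[0, 0] == 4
    assert C[0, 0] / C.sum() == pytest.approx(1 / 6)
    # asymmetric matrix counts each ordered pair once
    Ca = glcm_matrix(img, full((4, 4)), (0, 1), 4, symmetric=False)
    assert Ca.sum() == 12
    assert not np.array_equal(Ca, Ca.T)
    assert np.array_equal(C, C.T)


def test_glcm_feature_ranges(rng):
    for _ in range(5):
        data = rng.integers(1, 5, size=(10, 10)).astype(np.int32)
        cfg = GLCMConfig(bit_depth=2)
        for symmetric in (True, False):
            out = glcm_features(data, full((10, 10)), cfg, symmetric=symmetric)
            assert 0 < out["AngScMom"] <= 1
            assert 0 < out["InvDefMom"] <= 1
            assert out["Contrast"] >= 0
            assert out["Entropy"] >= 0
            assert out["SumEntrp"] >= 0 and out["DifEntrp"] >= 0


# ------------------------------------------------------- invariances ----

def _rot90(data, mask):
    return np.rot90(data).copy(), np.rot90(mask).copy()


def test_rotation_leaves_direction_averaged_matrix_features_unchanged(rng):
    data = rng.integers(1, 5, size=(10, 12)).astype(np.int32)
    mask = full((10, 12))
    rdata, rmask = _rot90(data, mask)
    cfg = GLCMConfig(distances=(1, 2, 3), bit_depth=2)
    a = glcm_features(data, mask, cfg)
    b = glcm_features(rdata, rmask, cfg)
    for k in a:
        assert a[k] == pytest.approx(b[k], rel=1e-9), k
    ra = glrlm_features(data, mask)
    rb = glrlm_features(rdata, rmask)
    for k in ra:
        assert ra[k] == pytest.approx(rb[k], rel=1e-9), k


def test_rotation_permutes_gabor_orientations(rng):
    data = rng.uniform(0, 255, size=(40, 40))
    mask = full((40, 40))
    a = gabor_features(data, mask)
    b = gabor_features(*_rot90(data, mask))
    for lam in (4, 6):
        half = lam // 2
        assert a[f"Gab{lam}H{half}Mag"] == pytest.approx(
            b[f"Gab{lam}V{half}Mag"], rel=1e-7)
        assert a[f"Gab{lam}V{half}Mag"] == pytest.approx(
            b[f"Gab{lam}H{half}Mag"], rel=1e-7)
        assert a[f"Gab{lam}N{half}Mag"] == pytest.approx(
            b[f"Gab{lam}Z{half}Mag"], rel=1e-7)


def test_extraction_is_deterministic(rng):
    data = rng.integers(1, 257, size=(20, 20)).astype(np.int32)
    ch = ChannelImage("RGB", "R", False, "none", data, 8)
    mask = full((20, 20))
    a = extract_channel(ch, mask)
    b = extract_channel(ch, mask)
    assert a == b
    assert len(a) == 88


# --------------------------------------------------- oracle spot checks --

def test_matrix_families_match_oracles_on_random_images(rng):
    """Spot equivalence with the naive enumeration oracles (the full
    200-image sweep runs in the acceptance suite)."""
    for _ in range(5):
        data = rng.integers(1, 5, size=(12, 12)).astype(np.int32)
        mask = full((12, 12))
        for symmetric in (True, False):
            mine = glcm_features(data, mask, GLCMConfig(bit_depth=2),
                                 symmetric=symmetric)
            theirs = ref.glcm_oracle(data, mask, 4, symmetric)
            for k, v in mine.items():
                assert v == pytest.approx(theirs[k], rel=1e-9), k
        mine = glrlm_features(data, mask)
        theirs = ref.glrlm_oracle(data, mask)
        for k, v in mine.items():
            assert v == pytest.approx(theirs[k], rel=1e-9), k
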