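"""Texture features against independent brute-force oracles.

Every matrix-derived feature is checked against direct double/triple sums
written as explicit Python loops over small hand-built matrices, to 1e-10.
"""

import numpy as np
import pytest
from scipy import ndimage

import pywt

from radsurv.texturefeat import (
    DIRECTIONS_13,
    WAVELET_SUBBANDS,
    extract_all,
    feature_names,
    first_order_features,
    glcm_build,
    glcm_features,
    gldm_build,
    gldm_features,
    glrlm_build,
    glrlm_features,
    glszm_build,
    glszm_features,
    ngtdm_build,
    ngtdm_features,
    shape_features,
    wavelet_decompose,
)
from radsurv.texturefeat import _glcm_features_single, _rlm_style_features


# ---------------------------------------------------------------------------
# brute-force oracles (explicit loops, independent of the implementation)


def oracle_glcm(P):
    Ng = P.shape[0]
    mx = my = 0.0
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    for i in range(Ng):
        mx += (i + 1) * px[i]
        my += (i + 1) * py[i]
    vx = sum((i + 1 - mx) ** 2 * px[i] for i in range(Ng))
    vy = sum((j + 1 - my) ** 2 * py[j] for j in range(Ng))
    out = dict.fromkeys(
        ["contrast", "dissimilarity", "homogeneity", "inverse_difference",
         "joint_energy", "joint_entropy", "autocorrelation",
         "cluster_tendency", "cluster_shade", "cluster_prominence"], 0.0)
    corr_num = 0.0
    for i in range(Ng):
        for j in range(Ng):
            p = P[i, j]
            a, b = i + 1, j + 1
            out["contrast"] += (a - b) ** 2 * p
            out["dissimilarity"] += abs(a - b) * p
            out["homogeneity"] += p / (1 + (a - b) ** 2)
            out["inverse_difference"] += p / (1 + abs(a - b))
            out["joint_energy"] += p * p
            if p > 0:
                out["joint_entropy"] -= p * np.log2(p)
            out["autocorrelation"] += a * b * p
            out["cluster_tendency"] += (a + b - mx - my) ** 2 * p
            out["cluster_shade"] += (a + b - mx - my) ** 3 * p
            out["cluster_prominence"] += (a + b - mx - my) ** 4 * p
            corr_num += (a - mx) * (b - my) * p
    out["joint_average"] = mx
    out["maximum_probability"] = P.max()
    out["correlation"] = corr_num / np.sqrt(vx * vy) if vx > 0 and vy > 0 \
        else np.nan
    return out


def oracle_rlm(M, n_voxels):
    Nr = M.sum()
    out = {}
    Ng, Nl = M.shape
    tot = {k: 0.0 for k in
           ["short_emphasis", "long_emphasis", "low_gl_emphasis",
            "high_gl_emphasis", "short_low_gl_emphasis",
            "short_high_gl_emphasis", "long_low_gl_emphasis",
            "long_high_gl_emphasis"]}
    mu_i = mu_j = 0.0
    for i in range(Ng):
        for j in range(Nl):
            m = M[i, j]
            a, b = i + 1, j + 1
            tot["short_emphasis"] += m / b**2
            tot["long_emphasis"] += m * b**2
            tot["low_gl_emphasis"] += m / a**2
            tot["high_gl_emphasis"] += m * a**2
            tot["short_low_gl_emphasis"] += m / (a**2 * b**2)
            tot["short_high_gl_emphasis"] += m * a**2 / b**2
            tot["long_low_gl_emphasis"] += m * b**2 / a**2
            tot["long_high_gl_emphasis"] += m * a**2 * b**2
            mu_i += a * m / Nr
            mu_j += b * m / Nr
    for k, v in tot.items():
        out[k] = v / Nr
    out["gl_nonuniformity"] = sum(M[i, :].sum() ** 2 for i in range(Ng)) / Nr
    out["size_nonuniformity"] = sum(M[:, j].sum() ** 2 for j in range(Nl)) / Nr
    out["percentage"] = Nr / n_voxels
    gv = sv = ent = 0.0
    for i in range(Ng):
        for j in range(Nl):
            p = M[i, j] / Nr
            gv += (i + 1 - mu_i) ** 2 * p
            sv += (j + 1 - mu_j) ** 2 * p
            if p > 0:
                ent -= p * np.log2(p)
    out["gl_variance"], out["size_variance"], out["entropy"] = gv, sv, ent
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_glcm_features_match_oracle_on_random_small_matrices(seed):
    rng = np.random.default_rng(seed)
    C = rng.integers(0, 9, (4, 4)).astype(float)
    C = C + C.T
    P = C / C.sum()
    got = _glcm_features_single(P)
    want = oracle_glcm(P)
    for k, v in want.items():
        assert got[k] == pytest.approx(v, abs=1e-10), k


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_rlm_style_features_match_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    M = rng.integers(0, 6, (4, 3)).astype(float)
    M[0, 0] += 1  # nonempty
    got = _rlm_style_features(M, n_voxels=50)
    want = oracle_rlm(M, 50)
    for k, v in want.items():
        assert got[k] == pytest.approx(v, abs=1e-10), k


def test_glcm_worked_examples():
    P = np.array([[0.75, 0.0], [0.0, 0.25]])
    f = _glcm_features_single(P)
    assert f["cluster_shade"] == pytest.approx(0.75, abs=1e-12)
    f2 = _glcm_features_single(np.diag([0.5, 0.5]))
    assert f2["cluster_shade"] == pytest.approx(0.0, abs=1e-12)
    f3 = _glcm_features_single(np.array([[1.0]]))
    assert f3["contrast"] == 0.0 and f3["cluster_shade"] == 0.0


def test_glszm_lahgle_single_zone():
    mask = np.zeros((1, 1, 4), bool)
    mask[0, 0, :] = True
    z = glszm_build(np.array([2, 2, 2, 2]), mask, n_levels=2)
    assert z.matrix[1, 3] == 1 and z.matrix.sum() == 1
    assert glszm_features(z)["long_high_gl_emphasis"] == pytest.approx(64.0)


def test_glszm_constant_roi_one_zone(small_cohort):
    mask = small_cohort[0].mask
    z = glszm_build(np.ones(int(mask.sum()), dtype=int), mask, n_levels=1)
    assert z.matrix.sum() == 1
    assert z.matrix[0, int(mask.sum()) - 1] == 1


# ---------------------------------------------------------------------------
# matrix construction


def test_glcm_strip_counts():
    mask = np.zeros((1, 1, 4), bool)
    mask[0, 0, :] = True
    g = glcm_build(np.array([1, 2, 1, 2]), mask, n_levels=2,
                   directions=((0, 0, 1),))
    P = g.matrices[0]
    assert P[0, 1] == pytest.approx(0.5)
    assert P[1, 0] == pytest.approx(0.5)
    assert P[0, 0] == P[1, 1] == 0.0


def test_glcm_constant_roi_single_cell():
    mask = np.ones((3, 3, 3), bool)
    g = glcm_build(np.ones(27, dtype=int), mask, n_levels=1)
    for k in range(len(DIRECTIONS_13)):
        assert g.matrices[k][0, 0] == pytest.approx(1.0)


def test_glcm_translation_invariance(rng):
    lv = rng.integers(1, 5, (4, 4, 4))
    big = np.zeros((10, 10, 10), dtype=int)
    m1 = np.zeros((10, 10, 10), bool)
    big[1:5, 1:5, 1:5] = lv
    m1[1:5, 1:5, 1:5] = True
    big2 = np.zeros((10, 10, 10), dtype=int)
    m2 = np.zeros((10, 10, 10), bool)
    big2[4:8, 3:7, 2:6] = lv
    m2[4:8, 3:7, 2:6] = True
    g1 = glcm_build(big[m1], m1, n_levels=4)
    g2 = glcm_build(big2[m2], m2, n_levels=4)
    np.testing.assert_allclose(g1.matrices, g2.matrices, atol=1e-12)


def test_glcm_rotation_leaves_averaged_features_unchanged(rng):
    lv3d = rng.integers(1, 6, (5, 5, 5))
    mask = np.ones((5, 5, 5), bool)
    f1 = glcm_features(glcm_build(lv3d[mask], mask, n_levels=5))
    rot = np.rot90(lv3d, k=1, axes=(0, 1))
    f2 = glcm_features(glcm_build(rot[mask], mask, n_levels=5))
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], abs=1e-10), k


def test_glrlm_strip_runs():
    mask = np.zeros((1, 1, 4), bool)
    mask[0, 0, :] = True
    r = glrlm_build(np.array([1, 1, 2, 2]), mask, n_levels=2,
                    directions=((0, 0, 1),))
    M = r.matrices[0]
    assert M[0, 1] == 1 and M[1, 1] == 1 and M.sum() == 2


def test_glrlm_matches_loop_oracle_on_random_volume(rng):
    """Run counts per direction equal a literal line-walking enumeration."""
    lv3d = rng.integers(1, 4, (4, 4, 4))
    mask = rng.random((4, 4, 4)) > 0.25
    r = glrlm_build(np.asarray(lv3d[mask]), mask, n_levels=3)
    for k, d in enumerate(DIRECTIONS_13):
        runs = {}
        visited = set()
        for start in np.ndindex(4, 4, 4):
            if not mask[start]:
                continue
            prev = tuple(np.subtract(start, d))
            if all(0 <= prev[i] < 4 for i in range(3)) and mask[prev] \
                    and lv3d[prev] == lv3d[start]:
                continue  # not a run start
            pos, length = start, 1
            while True:
                nxt = tuple(np.add(pos, d))
                if all(0 <= nxt[i] < 4 for i in range(3)) and mask[nxt] \
                        and lv3d[nxt] == lv3d[start]:
                    pos, length = nxt, length + 1
                else:
                    break
            runs[(int(lv3d[start]), length)] = runs.get(
                (int(lv3d[start]), length), 0) + 1
            visited.add(start)
        M = r.matrices[k]
        for (lvl, ln), cnt in runs.items():
            assert M[lvl - 1, ln - 1] == cnt
        assert M.sum() == sum(runs.values())


def test_gldm_dependence_counts():
    # 1D strip 1,1,2,2: deps with alpha=0 are 2,2,2,2 (one same neighbour each)
    mask = np.zeros((1, 1, 4), bool)
    mask[0, 0, :] = True
    g = gldm_build(np.array([1, 1, 2, 2]), mask, n_levels=2, alpha=0)
    assert g.matrix[0, 1] == 2 and g.matrix[1, 1] == 2
    f = gldm_features(g)
    assert f["percentage"] == pytest.approx(1.0)


def test_ngtdm_uniform_roi_zero_difference():
    mask = np.ones((3, 3, 3), bool)
    t = ngtdm_build(np.full(27, 2, dtype=int), mask, n_levels=2)
    assert t.s.sum() == pytest.approx(0.0)
    f = ngtdm_features(t)
    assert f["coarseness"] == 1e6  # no grey-tone differences anywhere


def test_ngtdm_matches_loop_oracle(rng):
    lv3d = rng.integers(1, 4, (3, 3, 3))
    mask = np.ones((3, 3, 3), bool)
    t = ngtdm_build(lv3d[mask], mask, n_levels=3)
    s = np.zeros(3)
    n = np.zeros(3)
    for idx in np.ndindex(3, 3, 3):
        nb = []
        for off in np.ndindex(3, 3, 3):
            o = tuple(np.array(off) - 1)
            if o == (0, 0, 0):
                continue
            q = tuple(np.add(idx, o))
            if all(0 <= q[i] < 3 for i in range(3)):
                nb.append(lv3d[q])
        if nb:
            s[lv3d[idx] - 1] += abs(lv3d[idx] - np.mean(nb))
            n[lv3d[idx] - 1] += 1
    np.testing.assert_allclose(t.s, s, atol=1e-10)
    np.testing.assert_array_equal(t.n, n)


# ---------------------------------------------------------------------------
# first order


def test_first_order_worked_examples():
    f = first_order_features([1, 2, 3, 4])
    assert f["mean"] == 2.5 and f["median"] == 2.5
    fc = first_order_features([7.0] * 10)
    assert fc["variance"] == 0.0 and fc["entropy"] == 0.0


def test_first_order_kurtosis_uncorrected_convention(rng):
    v = rng.standard_normal(200_000)
    f = first_order_features(v)
    assert f["kurtosis"] == pytest.approx(3.0, abs=0.1)
    assert f["skewness"] == pytest.approx(0.0, abs=0.05)


def test_first_order_empty_roi():
    with pytest.raises(ValueError, match="empty"):
        first_order_features([])


# ---------------------------------------------------------------------------
# wavelet


def test_wavelet_constant_image_high_bands_zero():
    bands = wavelet_decompose(np.full((8, 9, 10), 3.7))
    for name in WAVELET_SUBBANDS:
        if "H" in name:
            np.testing.assert_allclose(bands[name], 0.0, atol=1e-12)
    assert bands["LLL"].std() == pytest.approx(0.0, abs=1e-12)


def test_wavelet_impulse_equals_separable_convolution():
    imp = np.zeros((9, 9, 9))
    imp[4, 4, 4] = 1.0
    bands = wavelet_decompose(imp)
    w = pywt.Wavelet("coif1")
    filt = {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}
    for name in WAVELET_SUBBANDS:
        ref = imp
        for ax, letter in enumerate(name):
            ref = ndimage.convolve1d(ref, filt[letter], axis=ax, mode="reflect")
        np.testing.assert_allclose(bands[name], ref, atol=1e-12)


def test_wavelet_linearity(rng):
    X = rng.standard_normal((8, 8, 8))
    Y = rng.standard_normal((8, 8, 8))
    bx = wavelet_decompose(X)
    by = wavelet_decompose(Y)
    bz = wavelet_decompose(2.0 * X - 3.0 * Y)
    for name in WAVELET_SUBBANDS:
        np.testing.assert_allclose(bz[name], 2 * bx[name] - 3 * by[name],
                                   atol=1e-10)


def test_wavelet_rejects_short_dimension():
    with pytest.raises(ValueError, match="filter length"):
        wavelet_decompose(np.zeros((4, 8, 8)))


# ---------------------------------------------------------------------------
# shape


def test_shape_worked_examples():
    cube = np.ones((10, 10, 10), bool)
    f = shape_features(cube, (1, 1, 1))
    assert f["volume_ml"] == pytest.approx(1.0)
    assert shape_features(cube, (2, 2, 2))["volume_ml"] == pytest.approx(8.0)
    single = np.zeros((3, 3, 3), bool)
    single[1, 1, 1] = True
    fs = shape_features(single, (1, 1, 1))
    assert fs["volume_ml"] == pytest.approx(0.001)
    assert fs["max_3d_diameter_mm"] == 0.0
    with pytest.raises(ValueError, match="empty"):
        shape_features(np.zeros((3, 3, 3), bool), (1, 1, 1))


def test_sphericity_of_ball_near_one():
    m = np.zeros((31, 31, 31), bool)
    g = np.ogrid[0:31, 0:31, 0:31]
    r2 = sum((gi - 15.0) ** 2 for gi in g)
    m[r2 <= 13.0**2] = True
    f = shape_features(m, (1, 1, 1))
    assert 0.9 < f["sphericity"] <= 1.05


# ---------------------------------------------------------------------------
# orchestration


def test_extract_all_bookkeeping(small_cohort):
    p = small_cohort[0]
    fo_only = extract_all(p.image.data, p.mask, bin_number=16,
                          filters=("original",), classes=("firstorder",),
                          include_shape=False)
    assert len(fo_only) == len(first_order_features([1.0, 2.0]))
    assert all(k.startswith("original_firstorder_") for k in fo_only)


def test_extract_all_schema_stable_across_patients(small_cohort):
    kw = dict(bin_number=8, filters=("original", "wavelet-LHL"),
              classes=("firstorder", "glcm"))
    names = [tuple(extract_all(p.image.data, p.mask, **kw)) for p in
             small_cohort[:3]]
    assert names[0] == names[1] == names[2]
    assert tuple(feature_names(**kw)) == names[0]


def test_extract_all_constant_image_wavelet_medians_zero():
    mask = np.zeros((10, 10, 10), bool)
    mask[2:8, 2:8, 2:8] = True
    out = extract_all(np.full((10, 10, 10), 5.0), mask, bin_number=8,
                      classes=("firstorder",))
    for name in WAVELET_SUBBANDS:
        if "H" in name:
            assert out[f"wavelet-{name}_firstorder_median"] == pytest.approx(0.0)


def test_extract_all_error_carries_patient_id():
    with pytest.raises(RuntimeError, match="pt07"):
        extract_all(np.zeros((6, 6, 6)), np.zeros((6, 6, 6), bool),
                    patient_id="pt07")
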