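"""Zone extraction, CLAHE, GLCM and Haralick feature behaviour."""

import numpy as np
import pandas as pd
import pytest

from ksface.landmarks import LandmarkSet
from ksface.templates import ZONES, template_points
from ksface.texture import (
    HARALICK_STATS,
    ZoneError,
    _haralick14,
    clahe,
    extract_zones,
    glcm,
    haralick28,
    texture_feature_names,
    texture_features,
)


def _frontal(jitter=0.0, seed=0):
    pts = template_points("frontal").copy()
    if jitter:
        pts += np.random.default_rng(seed).normal(0, jitter, pts.shape)
    return LandmarkSet(photo_id="f", view="frontal", points=pts)


def _lateral():
    return LandmarkSet(
        photo_id="l", view="lateral_right", points=template_points("lateral")
    )


# ---------------------------------------------------------------------------
# zone extraction


def test_frontal_and_lateral_zone_counts():
    img = np.random.default_rng(0).uniform(0, 255, (256, 256))
    front = extract_zones(img, _frontal())
    lat = extract_zones(img, _lateral())
    assert len(front) == 11 and len(lat) == 3
    assert len(front) + len(lat) == len(ZONES) == 14
    assert all(p.shape == (64, 64) for _, p in front + lat)


def test_constant_image_gives_constant_patches():
    img = np.full((256, 256), 120.0)
    for _, patch in extract_zones(img, _frontal()):
        assert np.ptp(patch) == 0


def test_degenerate_polygon_raises_zone_error():
    img = np.zeros((256, 256))
    pts = template_points("frontal").copy()
    from ksface.templates import block_indices

    eye = block_indices("frontal")["right_eye"]
    pts[eye] = pts[eye].mean(axis=0) + np.random.default_rng(1).normal(
        0, 1e-4, (len(eye), 2)
    )
    # collapse one zone's polygon to (essentially) a point
    lms = LandmarkSet(photo_id="f", view="frontal", points=pts)
    with pytest.raises(ZoneError, match="right_eye"):
        extract_zones(img, lms)


def test_out_of_bounds_landmarks_clamped_with_warning():
    img = np.random.default_rng(0).uniform(0, 255, (240, 256))
    pts = template_points("frontal") + [0.0, 15.0]  # chin dips below the edge
    lms = LandmarkSet(photo_id="f", view="frontal", points=pts)
    with pytest.warns(UserWarning, match="clamping"):
        extract_zones(img, lms)


# ---------------------------------------------------------------------------
# CLAHE


def test_clahe_constant_patch_stays_constant():
    out = clahe(np.full((64, 64), 100.0))
    assert np.ptp(out) == 0


def test_clahe_single_tile_large_clip_equals_global_he():
    rng = np.random.default_rng(2)
    patch = rng.uniform(40, 200, (64, 64)).astype(np.uint8).astype(float)
    out = clahe(patch, clip_limit=64 * 64.0, tiles=(1, 1))
    # independent global histogram-equalization oracle
    v = patch.astype(np.uint8)
    hist = np.bincount(v.ravel(), minlength=256)
    cdf = np.cumsum(hist) / v.size
    expected = cdf[v] * 255.0
    assert np.abs(out - expected).max() <= 1.0


def test_clahe_expands_low_contrast():
    patch = np.full((64, 64), 100.0)
    patch[::2, ::2] = 110.0
    out = clahe(patch, clip_limit=2.0, tiles=(8, 8))
    assert np.ptp(out) > np.ptp(patch)


def test_clahe_rejects_bad_inputs():
    with pytest.raises(ValueError, match="clip_limit"):
        clahe(np.zeros((64, 64)), clip_limit=0.0)
    with pytest.raises(ValueError, match="smaller"):
        clahe(np.zeros((4, 4)), tiles=(8, 8))


# ---------------------------------------------------------------------------
# GLCM


def test_constant_patch_single_glcm_entry():
    g = glcm(np.full((16, 16), 200.0), levels=8)
    for a in range(4):
        m = g.matrices[:, :, a]
        assert m.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(m) == 1


def test_checkerboard_horizontal_pairs_hand_count():
    cb = (np.indices((4, 4)).sum(axis=0) % 2) * 255.0
    m0 = glcm(cb, levels=2, distance=1).matrices[:, :, 0]
    assert m0[0, 1] == pytest.approx(0.5)
    assert m0[1, 0] == pytest.approx(0.5)
    assert m0[0, 0] == m0[1, 1] == 0.0


def test_glcm_matrices_symmetric_and_normalized():
    rng = np.random.default_rng(3)
    g = glcm(rng.uniform(0, 255, (32, 32)), levels=16)
    for a in range(4):
        m = g.matrices[:, :, a]
        assert m.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(m, m.T)


def test_glcm_input_validation():
    with pytest.raises(ValueError, match="levels"):
        glcm(np.zeros((8, 8)), levels=1)
    with pytest.raises(ValueError, match="too small"):
        glcm(np.zeros((1, 1)))


# ---------------------------------------------------------------------------
# Haralick statistics


def _brute_force_haralick(p):
    """Independent double-loop implementation of the 14 statistics."""
    L = p.shape[0]
    px = p.sum(1)
    py = p.sum(0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    ps = np.zeros(2 * L - 1)
    pd_ = np.zeros(L)
    for i in range(L):
        for j in range(L):
            ps[i + j] += p[i, j]
            pd_[abs(i - j)] += p[i, j]

    def h(v):
        v = v[v > 1e-12]
        return -np.sum(v * np.log2(v))

    energy = np.sum(p**2)
    contrast = sum(
        (i - j) ** 2 * p[i, j] for i in range(L) for j in range(L)
    )
    corr = (
        (sum(i * j * p[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y)
        / (sx * sy)
        if sx > 1e-12 and sy > 1e-12
        else 0.0
    )
    var = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    s_avg = sum(k * ps[k] for k in range(2 * L - 1))
    s_var = sum((k - s_avg) ** 2 * ps[k] for k in range(2 * L - 1))
    s_ent = h(ps)
    ent = h(p.ravel())
    d_mean = sum(k * pd_[k] for k in range(L))
    d_var = sum((k - d_mean) ** 2 * pd_[k] for k in range(L))
    d_ent = h(pd_)
    hx, hy = h(px), h(py)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j] + 1e-12)
        for i in range(L)
        for j in range(L)
        if p[i, j] > 1e-12 or px[i] * py[j] > 1e-12
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j] + 1e-12)
        for i in range(L)
        for j in range(L)
        if p[i, j] > 1e-12 or px[i] * py[j] > 1e-12
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * max(hxy2 - ent, 0.0))))
    nz = (px > 1e-12) & (py > 1e-12)
    if nz.sum() >= 2:
        sub = p[np.ix_(nz, nz)]
        q = (sub / px[nz, None]) @ (sub / py[None, nz]).T
        ev = np.sort(np.linalg.eigvals(q).real)
        mcc = np.sqrt(max(ev[-2], 0.0))
    else:
        mcc = 0.0
    return np.array([
        energy, contrast, corr, var, idm, s_avg, s_var, s_ent, ent,
        d_var, d_ent, imc1, imc2, mcc,
    ])


def test_constant_patch_closed_forms():
    g = glcm(np.full((16, 16), 50.0), levels=8)
    s = pd.Series(haralick28(g).values, index=haralick28(g).names)
    assert s["contrast_mean"] == 0.0
    assert s["energy_mean"] == 1.0
    assert s["entropy_mean"] == 0.0
    assert s["homogeneity_mean"] == 1.0
    assert all(s[n] == 0.0 for n in s.index if n.endswith("_range"))


def test_checkerboard_closed_forms_at_zero_degrees():
    cb = (np.indices((4, 4)).sum(axis=0) % 2) * 255.0
    m0 = glcm(cb, levels=2).matrices[:, :, 0]
    f = _haralick14(m0)
    stats = dict(zip(HARALICK_STATS, f))
    assert stats["contrast"] == pytest.approx(1.0)
    assert stats["energy"] == pytest.approx(0.5)
    assert stats["entropy"] == pytest.approx(1.0)  # exactly one bit


def test_feature_vector_has_28_well_formed_names():
    g = glcm(np.random.default_rng(4).uniform(0, 255, (32, 32)))
    zf = haralick28(g, "glabella")
    assert len(zf.values) == len(zf.names) == 28
    for name in zf.names:
        stat, agg = name.rsplit("_", 1)
        assert stat in HARALICK_STATS and agg in ("mean", "range")


def test_statistics_match_brute_force_on_random_matrices():
    rng = np.random.default_rng(5)
    for _ in range(5):
        m = rng.uniform(0, 1, (8, 8))
        m = m + m.T
        m /= m.sum()
        assert np.allclose(_haralick14(m), _brute_force_haralick(m), atol=1e-10)


def test_statistics_invariant_under_transposition():
    rng = np.random.default_rng(6)
    m = rng.uniform(0, 1, (8, 8))
    m = m + m.T
    m /= m.sum()
    assert np.allclose(_haralick14(m), _haralick14(m.T), atol=1e-12)


def test_statistic_bounds_on_random_patches():
    rng = np.random.default_rng(7)
    for _ in range(5):
        g = glcm(rng.uniform(0, 255, (32, 32)), levels=16)
        s = pd.Series(haralick28(g).values, index=haralick28(g).names)
        assert 0 < s["energy_mean"] <= 1
        assert s["entropy_mean"] >= 0
        assert 0 < s["homogeneity_mean"] <= 1
        assert s["contrast_mean"] >= 0
        assert all(s[n] >= 0 for n in s.index if n.endswith("_range"))


def test_identical_angle_matrices_have_zero_ranges():
    m = np.full((4, 4), 1 / 16.0)
    from ksface.texture import GlcmSet

    g = GlcmSet(matrices=np.repeat(m[:, :, None], 4, axis=2), levels=4, distance=1)
    s = pd.Series(haralick28(g).values, index=haralick28(g).names)
    assert all(s[n] == 0.0 for n in s.index if n.endswith("_range"))


# ---------------------------------------------------------------------------
# per-session vector


def test_session_vector_392_named_values():
    rng = np.random.default_rng(8)
    img = rng.uniform(0, 255, (256, 256))
    vec = texture_features(img, _frontal(), img, _lateral())
    assert len(vec) == len(texture_feature_names()) == 392
    assert vec.notna().all()


def test_frontal_only_session_has_missing_lateral_markers():
    rng = np.random.default_rng(9)
    img = rng.uniform(0, 255, (256, 256))
    vec = texture_features(img, _frontal(), None, None)
    assert vec.notna().sum() == 11 * 28 == 308
    assert vec.isna().sum() == 3 * 28 == 84
    with pytest.raises(ValueError, match="at least one"):
        texture_features(None, None, None, None)


def test_features_robust_to_affine_illumination_change():
    # equalization exists to absorb illumination/skin-tone shifts: a
    # global gain/offset on a patch must barely move the feature vector
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(10)
    for _ in range(5):
        base = np.clip(
            gaussian_filter(rng.uniform(40, 200, (64, 64)), 1.5)
            + rng.normal(0, 12, (64, 64)),
            0, 255,
        ).astype(np.uint8).astype(float)
        bright = np.clip(base * 1.3 + 20.0, 0, 255)
        v1 = haralick28(glcm(clahe(base))).values
        v2 = haralick28(glcm(clahe(bright))).values
        rel = np.linalg.norm(v1 - v2) / np.linalg.norm(v1)
        assert rel < 0.05
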