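"""Procrustes superimposition and shape-PCA behaviour."""

import numpy as np
import pytest

from ksface.landmarks import PhotoMeta
from ksface.morphometrics import (
    ProcrustesAligner,
    ShapePCA,
    centroid_size,
    gpa,
    group_mean_shapes,
    pca_reduce,
)


def _random_similarity(rng, pts):
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return pts @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-10, 10, 2)


# ---------------------------------------------------------------------------
# independent brute-force oracle: direct SVD superimposition iterated hard


def _brute_force_gpa(shapes, tol=1e-12, iters=2000):
    def cs(p):
        c = p - p.mean(0)
        return c / np.sqrt((c**2).sum())

    def rot(src, dst):
        u, _, vt = np.linalg.svd(src.T @ dst)
        d = np.sign(np.linalg.det(u @ vt))
        return u @ np.diag([1.0, d]) @ vt

    normed = [cs(s) for s in shapes]
    mean = cs(normed[0])
    for _ in range(iters):
        aligned = [s @ rot(s, mean) for s in normed]
        new = np.mean(aligned, axis=0)
        new = cs(new)
        if np.sqrt(((new - mean) ** 2).sum()) < tol:
            mean = new
            break
        mean = new
    aligned = np.stack([s @ rot(s, mean) for s in normed])
    return aligned, mean


def test_single_configuration_is_its_centered_unit_size_self():
    rng = np.random.default_rng(0)
    shape = rng.normal(size=(8, 2))
    out = gpa(shape[None])
    sh = out.shapes()[0]
    centered = shape - shape.mean(0)
    expected = centered / np.sqrt((centered**2).sum())
    # alignment of one shape to itself involves one rotation solve; the
    # result must match up to that (identity) rotation
    assert np.allclose(sh, expected, atol=1e-10)
    assert abs(centroid_size(sh) - 1.0) < 1e-8


def test_similarity_copies_coincide_after_gpa():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(12, 2))
    shapes = np.stack([_random_similarity(rng, base) for _ in range(5)])
    out = gpa(shapes)
    sh = out.shapes()
    assert max(np.abs(sh[i] - sh[0]).max() for i in range(5)) < 1e-8
    # total Procrustes variance ~ 0
    assert np.var(out.coords, axis=0).sum() < 1e-16


def test_gpa_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    shapes = np.stack([rng.normal(size=(6, 2)) for _ in range(10)])
    out = gpa(shapes, tol=1e-12, max_iter=2000)
    ref_aligned, ref_mean = _brute_force_gpa(list(shapes))
    # mean shapes agree up to a global rotation; compare via rotation-free
    # summaries: pairwise Procrustes distances and distances to the mean
    d_ours = np.linalg.norm(
        out.shapes()[:, None] - out.shapes()[None, :], axis=(2, 3)
    )
    d_ref = np.linalg.norm(
        ref_aligned[:, None] - ref_aligned[None, :], axis=(2, 3)
    )
    assert np.allclose(d_ours, d_ref, atol=1e-6)
    dm_ours = np.linalg.norm(out.shapes() - out.mean_shape.reshape(-1, 2), axis=(1, 2))
    dm_ref = np.linalg.norm(ref_aligned - ref_mean, axis=(1, 2))
    assert np.allclose(dm_ours, dm_ref, atol=1e-6)


def test_gpa_invariant_under_input_similarity_transforms():
    rng = np.random.default_rng(3)
    shapes = np.stack([rng.normal(size=(7, 2)) for _ in range(6)])
    out1 = gpa(shapes)
    warped = np.stack([_random_similarity(rng, s) for s in shapes])
    out2 = gpa(warped)
    d1 = np.linalg.norm(out1.shapes()[:, None] - out1.shapes()[None, :], axis=(2, 3))
    d2 = np.linalg.norm(out2.shapes()[:, None] - out2.shapes()[None, :], axis=(2, 3))
    assert np.allclose(d1, d2, atol=1e-8)


def test_two_shape_gpa_equals_pairwise_procrustes():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=(2, 9, 2))
    out = gpa(np.stack([a, b]))

    def cs(p):
        c = p - p.mean(0)
        return c / np.sqrt((c**2).sum())

    za, zb = cs(a), cs(b)
    u, _, vt = np.linalg.svd(zb.T @ za)
    d = np.sign(np.linalg.det(u @ vt))
    zb_on_a = zb @ (u @ np.diag([1.0, d]) @ vt)
    pairwise = np.sqrt(((za - zb_on_a) ** 2).sum())
    ours = np.sqrt(((out.shapes()[0] - out.shapes()[1]) ** 2).sum())
    assert ours == pytest.approx(pairwise, abs=1e-8)


def test_unit_size_and_centering_invariants():
    rng = np.random.default_rng(5)
    shapes = np.stack([rng.normal(size=(10, 2)) for _ in range(8)])
    out = gpa(shapes)
    sh = out.shapes()
    assert np.abs(sh.mean(axis=1)).max() < 1e-8
    assert np.abs(np.sqrt((sh**2).sum(axis=(1, 2))) - 1).max() < 1e-8
    assert abs(np.sqrt((out.mean_shape**2).sum()) - 1) < 1e-8


def test_degenerate_configuration_rejected():
    shapes = np.zeros((3, 5, 2))
    with pytest.raises(ValueError, match="degenerate"):
        gpa(shapes)


# ---------------------------------------------------------------------------
# PCA reduction


def test_one_direction_of_variation_gives_single_component():
    rng = np.random.default_rng(6)
    base = rng.normal(size=(6, 2))
    direction = rng.normal(size=(6, 2)) * 0.01
    shapes = np.stack([base + t * direction for t in np.linspace(-1, 1, 20)])
    scores = pca_reduce(gpa(shapes))
    assert scores.m == 1
    # the scale renormalization in GPA bends a perfect line very slightly
    assert scores.explained_fraction[0] == pytest.approx(1.0, abs=1e-4)


def test_isotropic_data_keeps_nearly_all_components():
    rng = np.random.default_rng(7)
    from ksface.morphometrics import AlignedShapes

    X = rng.normal(size=(500, 10))
    est = ShapePCA(0.99).fit(X)
    assert est.m_ >= 9
    scores = est.transform(X)
    recon = scores @ est.components_ + est.mean_
    rel_err = ((X - recon) ** 2).sum() / ((X - X.mean(0)) ** 2).sum()
    assert rel_err <= 0.01


def test_variance_conservation_with_all_components():
    rng = np.random.default_rng(8)
    shapes = np.stack([rng.normal(size=(6, 2)) for _ in range(15)])
    aligned = gpa(shapes)
    scores = pca_reduce(aligned, variance_threshold=1.0)
    total = np.var(aligned.coords, axis=0, ddof=1).sum()
    by_scores = np.var(scores.scores, axis=0, ddof=1).sum()
    assert by_scores == pytest.approx(total, rel=1e-8)


def test_retained_components_are_orthogonal_and_threshold_tight():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(200, 12)) * np.linspace(3, 0.1, 12)
    est = ShapePCA(0.99).fit(X)
    ratios = np.cumsum(
        np.var(est.transform(X), axis=0, ddof=1)
    ) / np.var(X - X.mean(0), axis=0, ddof=1).sum()
    assert ratios[-1] >= 0.99
    if est.m_ > 1:
        assert ratios[-2] < 0.99
    gram = est.components_ @ est.components_.T
    assert np.abs(gram - np.eye(est.m_)).max() < 1e-6


def test_pca_requires_two_shapes():
    with pytest.raises(ValueError):
        ShapePCA().fit(np.zeros((1, 4)))


# ---------------------------------------------------------------------------
# group mean shapes


def _meta_for(photo_ids, labels, ages):
    return [
        PhotoMeta(patient_id=f"pt{i}", photo_id=p, view="frontal", age=a,
                  gender="female", ethnicity="Caucasian", label=l)
        for i, (p, l, a) in enumerate(zip(photo_ids, labels, ages))
    ]


def test_single_cell_mean_matches_overall_mean():
    rng = np.random.default_rng(10)
    shapes = np.stack([rng.normal(size=(6, 2)) for _ in range(12)])
    aligned = gpa(shapes)
    meta = _meta_for(aligned.photo_ids, ["control"] * 12, [5.0] * 12)
    table = group_mean_shapes(aligned, meta, age_bins=[0, 10])
    cell = table.iloc[0]
    assert cell["n"] == 12
    assert np.allclose(cell["mean_shape"], aligned.coords.mean(0), atol=1e-12)


def test_group_displacement_direction_recovered():
    rng = np.random.default_rng(11)
    base = rng.normal(size=(10, 2))
    base = (base - base.mean(0)) / np.sqrt(((base - base.mean(0)) ** 2).sum())
    delta = np.zeros((10, 2))
    delta[:5] = rng.normal(size=(5, 2))
    # superimposition removes the similarity component of any injected
    # displacement, so compare against the shape-space part of delta:
    # project off translation, scaling (base) and rotation (perp of base)
    k = len(base)
    basis = np.stack([
        np.tile([1.0, 0.0], k), np.tile([0.0, 1.0], k),
        base.ravel(), np.column_stack([-base[:, 1], base[:, 0]]).ravel(),
    ])
    d = delta.ravel()
    for v in basis:
        v = v / np.linalg.norm(v)
        d = d - (d @ v) * v
    delta = d.reshape(k, 2)
    delta *= 0.05 / np.linalg.norm(delta)
    noise = 0.1 * np.linalg.norm(delta)
    shapes, labels = [], []
    for grp, offset in (("control", 0.0), ("KS1", 1.0)):
        for _ in range(200):
            shapes.append(base + offset * delta + rng.normal(0, noise, (10, 2)))
            labels.append(grp)
    aligned = gpa(np.stack(shapes))
    meta = _meta_for(aligned.photo_ids, labels, [5.0] * len(labels))
    table = group_mean_shapes(aligned, meta, age_bins=[0, 10])
    means = {r["label"]: r["mean_shape"] for _, r in table.iterrows()}
    diff = means["KS1"] - means["control"]
    cos = np.dot(diff, delta.ravel()) / (
        np.linalg.norm(diff) * np.linalg.norm(delta)
    )
    assert cos > 0.95


def test_three_age_bins_and_empty_cells_flagged():
    rng = np.random.default_rng(12)
    shapes = np.stack([rng.normal(size=(6, 2)) for _ in range(9)])
    aligned = gpa(shapes)
    meta = _meta_for(
        aligned.photo_ids, ["control"] * 5 + ["KS1"] * 4,
        [1, 2, 3, 12, 13, 2, 3, 12, 13],
    )
    table = group_mean_shapes(aligned, meta, age_bins=[0, 6, 12, 18])
    assert len(table) == 6  # 2 labels x 3 bins
    empty = table[(table["label"] == "KS1") & (table["n"] == 0)]
    assert len(empty) == 1
    assert np.all(np.isnan(empty.iloc[0]["mean_shape"]))


def test_unknown_photo_id_is_pairing_error():
    rng = np.random.default_rng(13)
    aligned = gpa(np.stack([rng.normal(size=(6, 2)) for _ in range(4)]))
    meta = _meta_for(aligned.photo_ids[:-1], ["control"] * 3, [5.0] * 3)
    with pytest.raises(KeyError):
        group_mean_shapes(aligned, meta, age_bins=[0, 10])
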