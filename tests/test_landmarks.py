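"""Landmark I/O, laterality harmonization and inter-rater ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ksface.landmarks import (
    IccResult,
    LandmarkError,
    LandmarkSet,
    PhotoMeta,
    icc21,
    icc_two_raters,
    mirror_lateral,
    read_landmarks,
    read_metadata,
    write_landmarks,
    write_metadata,
)
from ksface.templates import TEMPLATE_SIZES, template_points


def _frontal_set(photo_id="p0", jitter=0.0, seed=0):
    pts = template_points("frontal").copy()
    if jitter:
        pts += np.random.default_rng(seed).normal(0, jitter, pts.shape)
    return LandmarkSet(photo_id=photo_id, view="frontal", points=pts)


# ---------------------------------------------------------------------------
# file round trips


def test_pts_toy_template_reads_in_file_order(tmp_path):
    p = tmp_path / "toy.pts"
    p.write_text("1 2\n3 4\n5 6\n")
    lms = read_landmarks(p, format="pts", n_points=3)
    assert np.array_equal(lms.points, [[1, 2], [3, 4], [5, 6]])


def test_pts_menpo_header_emitted_and_accepted(tmp_path):
    lms = read_landmarks(
        _write_toy(tmp_path / "t.pts", [[0.5, 1.5], [2, 3], [4, 0]]), n_points=3
    )
    text = (tmp_path / "t.pts").read_text()
    assert text.startswith("version: 1\nn_points: 3\n{")
    assert lms.points.shape == (3, 2)


def _write_toy(path, pts):
    lms = LandmarkSet.__new__(LandmarkSet)
    lms.photo_id, lms.view = path.stem, "frontal"
    lms.points = np.asarray(pts, dtype=float)
    lms.template_name = "custom3"
    write_landmarks(lms, path, format="pts")
    return path


@pytest.mark.parametrize("fmt", ["pts", "ljson"])
def test_round_trip_both_dialects(tmp_path, fmt):
    lms = _frontal_set(jitter=2.0)
    path = tmp_path / f"f.{fmt}"
    write_landmarks(lms, path, format=fmt)
    back = read_landmarks(path, format=fmt, view="frontal")
    assert np.allclose(back.points, lms.points, atol=1e-9)
    assert back.template_name == "frontal"


def test_ljson_frontal_infers_view_and_template(tmp_path):
    path = tmp_path / "x.ljson"
    write_landmarks(_frontal_set(), path)
    lms = read_landmarks(path)
    assert lms.view == "frontal"
    assert lms.n_points == 105


def test_ear_ljson_has_41_entries(tmp_path):
    pts = template_points("ear")
    lms = LandmarkSet(photo_id="e", view="ear", points=pts)
    path = tmp_path / "e.ljson"
    write_landmarks(lms, path)
    import json

    doc = json.loads(path.read_text())
    assert len(doc["landmarks"]["points"]) == 41
    assert read_landmarks(path).view == "ear"


def test_malformed_pts_names_line(tmp_path):
    p = tmp_path / "bad.pts"
    p.write_text("1 2\n3 4 5\n")
    with pytest.raises(LandmarkError, match=":2"):
        read_landmarks(p, format="pts", n_points=2)


def test_unregistered_point_count_is_template_error(tmp_path):
    p = tmp_path / "n7.pts"
    p.write_text("\n".join(f"{i} {i+1}" for i in range(7)) + "\n")
    with pytest.raises(LandmarkError, match="template"):
        read_landmarks(p, format="pts")


def test_template_count_enforced():
    with pytest.raises(LandmarkError, match="105"):
        LandmarkSet(photo_id="p", view="frontal", points=np.random.rand(73, 2))
    with pytest.raises(LandmarkError, match="finite"):
        pts = template_points("ear").copy()
        pts[0, 0] = np.nan
        LandmarkSet(photo_id="p", view="ear", points=pts)


# ---------------------------------------------------------------------------
# laterality


def test_mirror_reflection_formula():
    pts = template_points("lateral").copy()
    pts[0] = [10.0, 5.0]
    lms = LandmarkSet(photo_id="l", view="lateral_left", points=pts)
    out = mirror_lateral(lms, image_width=100)
    assert out.view == "lateral_right"
    assert tuple(out.points[0]) == (89.0, 5.0)


def test_mirror_right_profile_unchanged_and_non_lateral_rejected():
    pts = template_points("lateral")
    right = LandmarkSet(photo_id="r", view="lateral_right", points=pts)
    assert mirror_lateral(right, 100) is right
    with pytest.raises(LandmarkError):
        mirror_lateral(_frontal_set(), 100)


@given(width=st.integers(min_value=200, max_value=4000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_mirror_is_involution(width):
    pts = template_points("lateral")
    lms = LandmarkSet(photo_id="l", view="lateral_left", points=pts)
    once = mirror_lateral(lms, width)
    # mirroring the right-convention result back as a left profile
    twice = mirror_lateral(
        LandmarkSet(photo_id="l", view="lateral_left", points=once.points), width
    )
    assert np.allclose(twice.points, pts, atol=1e-12)


# ---------------------------------------------------------------------------
# inter-rater ICC


def test_icc_perfect_agreement_is_one_and_excellent():
    sets = [_frontal_set(f"p{i}", jitter=3.0, seed=i) for i in range(5)]
    res = icc_two_raters(sets, [LandmarkSet(l.photo_id, l.view, l.points.copy())
                                for l in sets])
    assert res.icc == pytest.approx(1.0, abs=1e-12)
    assert res.reliability_label == "excellent"


def test_icc_noise_dominated_agreement_is_low():
    # rater B adds noise with variance 100x the between-subject variance;
    # the two-way variance-component formula then gives ICC ~ sigma_s^2 /
    # (sigma_s^2 + sigma_e^2) with sigma_e^2 ~ 50x sigma_s^2 pooled
    rng = np.random.default_rng(3)
    subjects = rng.normal(0.0, 1.0, 200)
    noise = rng.normal(0.0, 10.0, 200)
    a = subjects
    b = subjects + noise
    icc = icc21(a, b)
    # direct variance-component evaluation (independent formula)
    s2 = np.var(subjects, ddof=1)
    e2 = np.var(noise, ddof=1) / 2.0  # error split across the two raters
    expected = s2 / (s2 + 2 * e2)
    assert icc < 0.1
    assert icc == pytest.approx(expected, abs=0.05)


def test_icc_shift_invariance():
    rng = np.random.default_rng(5)
    a = rng.normal(size=300)
    b = a + rng.normal(0, 0.3, 300)
    assert icc21(a + 17.5, b + 17.5) == pytest.approx(icc21(a, b), abs=1e-12)


@pytest.mark.parametrize(
    "icc,label", [(0.95, "excellent"), (0.89, "good"), (0.6, "moderate"), (0.2, "poor")]
)
def test_reliability_label_thresholds(icc, label):
    assert IccResult.from_icc(icc).reliability_label == label


def test_icc_matches_pingouin_two_way_agreement():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(8)
    subj = rng.normal(0, 2, 80)
    a = subj + rng.normal(0, 0.5, 80)
    b = subj + 0.3 + rng.normal(0, 0.5, 80)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(80), 2),
        "rater": ["a", "b"] * 80,
        "score": np.column_stack([a, b]).ravel(),
    })
    table = pg.intraclass_corr(df, targets="subject", raters="rater",
                               ratings="score")
    icc2 = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert icc21(a, b) == pytest.approx(icc2, abs=1e-10)


def test_icc_mismatched_photo_sets_rejected():
    sets_a = [_frontal_set(f"p{i}") for i in range(3)]
    sets_b = [_frontal_set(f"q{i}") for i in range(3)]
    with pytest.raises(LandmarkError, match="different photo sets"):
        icc_two_raters(sets_a, sets_b)


# ---------------------------------------------------------------------------
# metadata table


def test_metadata_round_trip(tmp_path):
    rows = [
        PhotoMeta("P1", "P1_v0", "frontal+lateral_left+ear", 4.5, "female",
                  "Caucasian", "KS1", gene="KMT2D", protein_hgvs="p.Gln1773*",
                  cdna_hgvs="c.5317C>T"),
        PhotoMeta("P2", "P2_v0", "frontal", 10.0, "male", "Asian", "control"),
    ]
    path = tmp_path / "meta.csv"
    write_metadata(rows, path)
    back = read_metadata(path)
    assert back == rows
    assert back[0].views == ("frontal", "lateral_left", "ear")


def test_metadata_validation():
    with pytest.raises(ValueError, match="age"):
        PhotoMeta("P", "p", "frontal", -1.0, "female", "Caucasian", "control")
    with pytest.raises(ValueError, match="label"):
        PhotoMeta("P", "p", "frontal", 4.0, "female", "Caucasian", "sick")
    with pytest.raises(ValueError, match="view"):
        PhotoMeta("P", "p", "profile", 4.0, "female", "Caucasian", "control")


def test_duplicate_metadata_rows_rejected(tmp_path):
    rows = [
        PhotoMeta("P1", "p1", "frontal", 4.0, "female", "Caucasian", "control"),
        PhotoMeta("P1", "p1", "ear", 4.0, "female", "Caucasian", "control"),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        write_metadata(rows, tmp_path / "m.csv")
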