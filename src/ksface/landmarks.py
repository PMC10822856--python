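"""Landmark and cohort-metadata I/O, laterality harmonization and
inter-rater reliability.

Landmark files are consumed in two dialects: menpo-style PTS
(``version: 1`` header, braces, one ``x y`` pair per line) and
landmarker.io LJSON.  Coordinates are 0-based pixels, origin top-left,
y increasing downward, throughout the package.

Inter-rater agreement of manual landmark placement is quantified with
ICC(2,1) — two-way random effects, absolute agreement, single
measurement — pooling every (photo, landmark, axis) value as a subject;
an ICC above 0.9 is labelled excellent reliability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .templates import TEMPLATE_SIZES, VIEWS, template_for_view, template_from_count

__all__ = [
    "LandmarkSet",
    "PhotoMeta",
    "IccResult",
    "LandmarkError",
    "read_landmarks",
    "write_landmarks",
    "mirror_lateral",
    "icc_two_raters",
    "read_metadata",
    "write_metadata",
]


class LandmarkError(ValueError):
    """Malformed landmark file, template mismatch or pairing failure."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LandmarkSet:
    """Ordered 2D landmarks for one view of one photograph.

    Parameters
    ----------
    photo_id : str
        Identifier of the photograph (or visit) the landmarks belong to.
    view : str
        One of ``frontal``, ``lateral_left``, ``lateral_right``, ``ear``.
    points : (n, 2) float array
        Pixel coordinates in file order.
    template_name : str
        Name of the template the point count must match (``frontal``,
        ``lateral`` or ``ear``); inferred from the view if omitted.
    """

    photo_id: str
    view: str
    points: np.ndarray
    template_name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.view not in VIEWS:
            raise LandmarkError(f"unknown view {self.view!r}")
        if not self.template_name:
            self.template_name = template_for_view(self.view)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise LandmarkError("points must be an (n, 2) array")
        expected = TEMPLATE_SIZES.get(self.template_name)
        if expected is not None and len(self.points) != expected:
            raise LandmarkError(
                f"template {self.template_name!r} expects {expected} points, "
                f"got {len(self.points)}"
            )
        if not np.all(np.isfinite(self.points)):
            raise LandmarkError("landmark coordinates must be finite")
        if len(self.points) >= 3 and _collinear(self.points):
            raise LandmarkError("landmarks are collinear (degenerate configuration)")

    @property
    def n_points(self) -> int:
        return len(self.points)


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


@dataclass(frozen=True)
class PhotoMeta:
    """Per-photo-session cohort metadata row.

    A session (one ``photo_id``) may carry several view captures taken
    at the same visit; ``view`` is a ``+``-joined list of the available
    views (e.g. ``"frontal+lateral_right+ear"``), so ``(patient_id,
    photo_id)`` stays unique with exactly one metadata row per session.
    """

    patient_id: str
    photo_id: str
    view: str
    age: float
    gender: str
    ethnicity: str
    label: str
    gene: str = ""
    protein_hgvs: str = ""
    cdna_hgvs: str = ""

    GENDERS = ("female", "male")
    ETHNICITIES = ("African/Caribbean", "Asian", "Caucasian")
    LABELS = ("control", "KS1", "KS2", "KS_unknown_gene")

    def __post_init__(self):
        if not (0.0 <= self.age <= 120.0):
            raise ValueError(f"age {self.age} outside [0, 120]")
        if self.gender not in self.GENDERS:
            raise ValueError(f"gender {self.gender!r} not in {self.GENDERS}")
        if self.ethnicity not in self.ETHNICITIES:
            raise ValueError(f"ethnicity {self.ethnicity!r} not in {self.ETHNICITIES}")
        if self.label not in self.LABELS:
            raise ValueError(f"label {self.label!r} not in {self.LABELS}")
        for v in self.views:
            if v not in VIEWS:
                raise ValueError(f"view {v!r} not in {VIEWS}")

    @property
    def views(self) -> tuple[str, ...]:
        return tuple(v for v in self.view.split("+") if v)

    @property
    def is_ks(self) -> bool:
        return self.label != "control"


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with the Koo–Li style reliability label."""

    icc: float
    reliability_label: str

    @staticmethod
    def from_icc(icc: float) -> "IccResult":
        if icc > 0.9:
            label = "excellent"
        elif icc > 0.75:
            label = "good"
        elif icc > 0.5:
            label = "moderate"
        else:
            label = "poor"
        return IccResult(icc=float(icc), reliability_label=label)


# ---------------------------------------------------------------------------
# PTS dialect


def _read_pts(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    pts = []
    n_declared = None
    for ln_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line in ("{", "}"):
            continue
        low = line.lower()
        if low.startswith("version:"):
            continue
        if low.startswith("n_points:"):
            try:
                n_declared = int(line.split(":", 1)[1])
            except ValueError as e:
                raise LandmarkError(f"{path}:{ln_no}: bad n_points header") from e
            continue
        fields = line.split()
        if len(fields) != 2:
            raise LandmarkError(f"{path}:{ln_no}: expected 'x y', got {raw!r}")
        try:
            pts.append((float(fields[0]), float(fields[1])))
        except ValueError as e:
            raise LandmarkError(f"{path}:{ln_no}: non-numeric coordinate") from e
    if not pts:
        raise LandmarkError(f"{path}: no coordinate lines found")
    if n_declared is not None and n_declared != len(pts):
        raise LandmarkError(
            f"{path}: header declares {n_declared} points, file has {len(pts)}"
        )
    return np.asarray(pts, dtype=float)


def _write_pts(points: np.ndarray, path: Path) -> None:
    lines = ["version: 1", f"n_points: {len(points)}", "{"]
    lines += [f"{x:.10g} {y:.10g}" for x, y in points]
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# LJSON (landmarker.io) dialect


def _read_ljson(path: Path) -> tuple[np.ndarray, str | None]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise LandmarkError(f"{path}: invalid JSON at line {e.lineno}") from e
    try:
        raw = doc["landmarks"]["points"]
    except (KeyError, TypeError) as e:
        raise LandmarkError(f"{path}: missing landmarks.points") from e
    pts = np.asarray(raw, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise LandmarkError(f"{path}: points must be a list of [x, y] pairs")
    label = None
    labels = doc.get("labels") or []
    if labels and isinstance(labels[0], dict):
        label = labels[0].get("label")
    return pts, label


def _write_ljson(lms: "LandmarkSet", path: Path) -> None:
    doc = {
        "version": 2,
        "labels": [
            {"label": lms.view, "mask": list(range(lms.n_points))}
        ],
        "landmarks": {
            "points": [[float(x), float(y)] for x, y in lms.points],
            "connectivity": [],
        },
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------------------
# public I/O


def read_landmarks(
    path,
    format: str | None = None,
    view: str | None = None,
    photo_id: str | None = None,
    n_points: int | None = None,
) -> LandmarkSet:
    """Read a landmark file in the PTS or LJSON dialect.

    Parameters
    ----------
    path : path-like
    format : {"pts", "ljson"}, optional
        Inferred from the file extension when omitted.
    view : str, optional
        View of the photograph.  For LJSON files carrying a view label
        the label is used when this is omitted; otherwise the view is
        inferred from the point count (105 -> frontal, 73 ->
        lateral_right, 41 -> ear).  Left profiles must be named
        explicitly — the file itself cannot distinguish laterality.
    photo_id : str, optional
        Defaults to the file stem.
    n_points : int, optional
        Toy-template override: accept exactly this point count instead
        of requiring one of the registered templates.
    """
    path = Path(path)
    fmt = format or ("ljson" if path.suffix.lower() in (".ljson", ".json") else "pts")
    if fmt == "pts":
        pts, label = _read_pts(path), None
    elif fmt == "ljson":
        pts, label = _read_ljson(path)
    else:
        raise LandmarkError(f"unknown landmark format {fmt!r}")

    if view is None and label in VIEWS:
        view = label
    if n_points is not None:
        if len(pts) != n_points:
            raise LandmarkError(
                f"{path}: expected {n_points} points, got {len(pts)}"
            )
        lms = LandmarkSet.__new__(LandmarkSet)
        lms.photo_id = photo_id or path.stem
        lms.view = view or "frontal"
        lms.points = np.asarray(pts, dtype=float)
        lms.template_name = f"custom{n_points}"
        return lms
    if view is None:
        try:
            template = template_from_count(len(pts))
        except ValueError as e:
            raise LandmarkError(f"{path}: {e}") from e
        view = {"frontal": "frontal", "lateral": "lateral_right", "ear": "ear"}[template]
    else:
        template = template_for_view(view)
        if len(pts) != TEMPLATE_SIZES[template]:
            raise LandmarkError(
                f"{path}: view {view!r} requires {TEMPLATE_SIZES[template]} "
                f"points, got {len(pts)}"
            )
    return LandmarkSet(photo_id=photo_id or path.stem, view=view, points=pts)


def write_landmarks(lms: LandmarkSet, path, format: str | None = None) -> None:
    """Write a landmark set; round-trips through :func:`read_landmarks`."""
    path = Path(path)
    fmt = format or ("ljson" if path.suffix.lower() in (".ljson", ".json") else "pts")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "pts":
        _write_pts(lms.points, path)
    elif fmt == "ljson":
        _write_ljson(lms, path)
    else:
        raise LandmarkError(f"unknown landmark format {fmt!r}")


def mirror_lateral(lms: LandmarkSet, image_width: int) -> LandmarkSet:
    """Harmonize a profile to the right-profile convention.

    Left profiles are reflected with ``x -> image_width - 1 - x`` and
    relabelled ``lateral_right``; right profiles pass through unchanged.
    Pooling both profile sides into one shape space requires this before
    superimposition — otherwise left and right faces would be mirror
    images in shape space.
    """
    if lms.view == "lateral_right":
        return lms
    if lms.view != "lateral_left":
        raise LandmarkError(f"mirror_lateral requires a lateral view, got {lms.view!r}")
    pts = lms.points.copy()
    pts[:, 0] = image_width - 1 - pts[:, 0]
    return replace(lms, points=pts, view="lateral_right")


# ---------------------------------------------------------------------------
# inter-rater reliability


def icc21(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``a`` and ``b`` are paired measurements of the same subjects by two
    raters.  Computed from the two-way ANOVA mean squares with k = 2
    raters::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise LandmarkError("ICC requires two equal-length series of >= 2 values")
    y = np.column_stack([a, b])  # n subjects x k raters
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((msr - mse) / denom)


def icc_two_raters(
    rater_a: Sequence[LandmarkSet], rater_b: Sequence[LandmarkSet]
) -> IccResult:
    """Inter-rater ICC over two raters' landmark placements.

    Every (photo, landmark, axis) coordinate is pooled as one ICC
    subject, yielding a single scalar per template.  Photos are paired
    by ``photo_id``; both raters must cover the same photos with the
    same templates.
    """
    if len(rater_a) < 2 or len(rater_a) != len(rater_b):
        raise LandmarkError("need the same >= 2 photos from both raters")
    b_by_id = {l.photo_id: l for l in rater_b}
    if set(b_by_id) != {l.photo_id for l in rater_a}:
        raise LandmarkError("raters annotated different photo sets")
    va, vb = [], []
    for la in rater_a:
        lb = b_by_id[la.photo_id]
        if la.template_name != lb.template_name or la.n_points != lb.n_points:
            raise LandmarkError(f"template mismatch on photo {la.photo_id!r}")
        va.append(la.points.ravel())
        vb.append(lb.points.ravel())
    icc = icc21(np.concatenate(va), np.concatenate(vb))
    return IccResult.from_icc(icc)


# ---------------------------------------------------------------------------
# cohort metadata table

_META_COLUMNS = ["patient_id", "photo_id", "view", "age", "gender", "ethnicity", "label"]
_VARIANT_COLUMNS = ["gene", "protein_hgvs", "cdna_hgvs"]


def read_metadata(path) -> list[PhotoMeta]:
    """Read the cohort metadata CSV (one row per photo view)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns {missing}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            PhotoMeta(
                patient_id=rec["patient_id"],
                photo_id=rec["photo_id"],
                view=rec["view"],
                age=float(rec["age"]),
                gender=rec["gender"],
                ethnicity=rec["ethnicity"],
                label=rec["label"],
                gene=rec.get("gene", ""),
                protein_hgvs=rec.get("protein_hgvs", ""),
                cdna_hgvs=rec.get("cdna_hgvs", ""),
            )
        )
    _check_unique(rows)
    return rows


def write_metadata(meta: Iterable[PhotoMeta], path) -> None:
    rows = list(meta)
    _check_unique(rows)
    df = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "photo_id": m.photo_id,
                "view": m.view,
                "age": m.age,
                "gender": m.gender,
                "ethnicity": m.ethnicity,
                "label": m.label,
                "gene": m.gene,
                "protein_hgvs": m.protein_hgvs,
                "cdna_hgvs": m.cdna_hgvs,
            }
            for m in rows
        ]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _check_unique(rows: Sequence[PhotoMeta]) -> None:
    seen = set()
    for m in rows:
        key = (m.patient_id, m.photo_id)
        if key in seen:
            raise ValueError(f"duplicate metadata row {key}")
        seen.add(key)
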