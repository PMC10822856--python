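"""Synthetic cohort generation and printed-table fixtures.

No patient photographs can be redistributed, so the pipeline is
exercised on synthetic cohorts that reproduce the *statistical*
structure the method assumes: repeated photo sessions per patient,
group-specific mean-shape displacements (arched eyebrows, elongated
palpebral fissures and vertically elongated ears in the syndromic
groups, with rounder-face/shorter-nose contrasts between the two
genotype groups), a linear age effect on shape shared across patients
plus a per-individual random age slope, Gaussian landmark noise, and
facial-zone textures whose contrast and spatial frequency shift with
the group in the eyebrow/eye zones.  Everything is reproducible from a
single seed.

The module also ships two small fixtures transcribed from the printed
cohort tables: the 105 patient-level variant records (with
multiplicities matching the per-gene aggregate counts) and the two
validation confusion matrices expanded into (predicted, reference)
label pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .landmarks import LandmarkSet, PhotoMeta, write_landmarks, write_metadata
from .templates import (
    CANVAS,
    TEMPLATE_SIZES,
    ZONES,
    block_indices,
    template_points,
)
from .variants import VariantRecord, read_variants

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "table2_fixture",
    "confusion_fixtures",
]

IMAGE_SIZE = 320  # synthetic photo canvas (landmark canvas is 256 + margin)

#: zones whose texture shifts in KS (eyebrow sparsening / heavy lashes)
_KS_TEXTURE_ZONES = ("right_eyebrow", "left_eyebrow", "right_eye", "left_eye")
#: zones whose texture additionally shifts in KS2 vs KS1
_KS2_TEXTURE_ZONES = ("philtrum", "nasal_tip")


@dataclass
class SynthConfig:
    """Generative settings of a synthetic cohort.

    Counts and demographic mixes default to the real cohort's
    structure (527 controls, 82 KS1, 23 KS2, 2 KS of unknown gene; 52%
    female; 92/5/3% Caucasian / African-Caribbean / Asian; ages
    gamma-distributed with mean 7.2 and sd 4.2 years, capped at the
    age range).  Effect magnitudes are in canvas pixels on a 256-pixel
    face and are package choices documented in the methods note.
    """

    n_controls: int = 527
    n_ks1: int = 82
    n_ks2: int = 23
    n_ks_unknown: int = 2
    photos_per_patient: tuple[int, int] = (1, 4)
    age_range: tuple[float, float] = (0.0, 40.0)
    group_shape_effect: float = 4.0      # KS-vs-control displacement, px
    subtype_shape_effect: float = 2.5    # KS1-vs-KS2 displacement, px
    allometric_slope: float = 0.4        # shared age effect, px / year
    random_slope_sd: float = 0.08        # per-individual age slope sd, px / year
    landmark_noise_sd: float = 1.5       # isotropic landmark noise, px
    texture_effect: float = 0.5          # fractional contrast shift in KS zones
    subtype_texture_effect: float = 0.3  # extra contrast shift in KS2 zones
    female_prop: float = 0.52
    ethnicity_props: tuple[float, float, float] = (0.05, 0.03, 0.92)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_controls", "n_ks1", "n_ks2", "n_ks_unknown"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("random_slope_sd", "landmark_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.ethnicity_props) - 1.0) > 1e-9:
            raise ValueError("ethnicity proportions must sum to 1")


@dataclass
class SynthCohort:
    """In-memory synthetic cohort; write() emits the on-disk formats."""

    config: SynthConfig
    meta: list[PhotoMeta]
    landmarks: dict               # (photo_id, view) -> LandmarkSet
    images: dict                  # (photo_id, view) -> uint8 image
    variants: dict                # patient_id -> VariantRecord

    def patients(self) -> list[str]:
        return sorted({m.patient_id for m in self.meta})

    def write(self, out_dir) -> Path:
        """Write PTS landmarks, PNG images and the metadata CSV."""
        out = Path(out_dir)
        (out / "landmarks").mkdir(parents=True, exist_ok=True)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for (photo_id, view), lms in self.landmarks.items():
            write_landmarks(lms, out / "landmarks" / f"{photo_id}_{view}.pts")
        for (photo_id, view), img in self.images.items():
            iio.imwrite(out / "images" / f"{photo_id}_{view}.png", img)
        write_metadata(self.meta, out / "metadata.csv")
        return out


# ---------------------------------------------------------------------------
# displacement fields


def _normalize_field(f: np.ndarray) -> np.ndarray:
    """Scale a displacement field to unit RMS over its nonzero rows."""
    norms = np.linalg.norm(f, axis=1)
    active = norms > 0
    if not np.any(active):
        return f
    rms = np.sqrt(np.mean(norms[active] ** 2))
    return f / rms


def _ks_field(template: str) -> np.ndarray:
    """KS-vs-control mean displacement direction (unit RMS)."""
    pts = template_points(template)
    f = np.zeros_like(pts)
    b = block_indices(template)
    if template == "frontal":
        for side in ("right_eyebrow", "left_eyebrow"):
            ix = b[side]
            # arched, raised brows: lift, most at the brow centre
            cx = pts[ix, 0].mean()
            w = pts[ix, 0].max() - pts[ix, 0].min()
            arch = 1.0 - ((pts[ix, 0] - cx) / (w / 2 + 1e-9)) ** 2
            f[ix, 1] = -(0.6 + 0.8 * arch)
        for side in ("right_eye", "left_eye"):
            ix = b[side]
            # long palpebral fissures: stretch the eye outline laterally
            cx = pts[ix, 0].mean()
            rx = np.abs(pts[ix, 0] - cx).max()
            f[ix, 0] = 0.9 * (pts[ix, 0] - cx) / (rx + 1e-9)
    elif template == "lateral":
        ix = b["ear_outline"]
        cy = pts[ix, 1].mean()
        ry = np.abs(pts[ix, 1] - cy).max()
        f[ix, 1] = 1.0 * (pts[ix, 1] - cy) / (ry + 1e-9)  # prominent, long ear
        ix = b["eyebrow"]
        f[ix, 1] = -0.8
    else:  # ear: vertical elongation of the helix and lobe
        ix = b["helix"]
        cy = pts[ix, 1].mean()
        ry = np.abs(pts[ix, 1] - cy).max()
        f[ix, 1] = 1.0 * (pts[ix, 1] - cy) / (ry + 1e-9)
        f[b["lobe"], 1] = 1.0
    return _normalize_field(f)


def _subtype_field(template: str) -> np.ndarray:
    """KS2-minus-KS1 displacement direction (unit RMS)."""
    pts = template_points(template)
    f = np.zeros_like(pts)
    b = block_indices(template)
    if template == "frontal":
        ix = b["outline"]
        cx = pts[ix, 0].mean()
        f[ix, 0] = 0.8 * np.sign(pts[ix, 0] - cx)   # rounder face
        f[b["nasal_tip"], 1] = -0.9                  # shorter nose
        ix = b["mouth"]
        top = pts[ix, 1] < pts[ix, 1].mean()
        f[ix, 1] = np.where(top, -0.8, 0.0)          # thicker upper lip
    elif template == "lateral":
        ix = b["ear_outline"]
        cy = pts[ix, 1].mean()
        ry = np.abs(pts[ix, 1] - cy).max()
        f[ix, 1] = 0.9 * (pts[ix, 1] - cy) / (ry + 1e-9)
        # counter-clockwise rotation of the ear
        c = pts[ix] - pts[ix].mean(axis=0)
        f[ix, 0] += -0.5 * c[:, 1] / (ry + 1e-9)
        f[ix, 1] += 0.5 * c[:, 0] / (ry + 1e-9)
    else:
        ix = b["helix"]
        cy = pts[ix, 1].mean()
        ry = np.abs(pts[ix, 1] - cy).max()
        f[ix, 1] = 0.9 * (pts[ix, 1] - cy) / (ry + 1e-9)
        f[b["lobe"], 1] = -0.8                       # hypoplastic lobe
    return _normalize_field(f)


def _growth_field(template: str) -> np.ndarray:
    """Shared allometric direction: the lower face grows with age."""
    pts = template_points(template)
    c = pts - pts.mean(axis=0)
    f = np.zeros_like(pts)
    lower = c[:, 1] > 0
    f[lower] = 0.8 * c[lower] / (np.abs(c[lower]).max() + 1e-9)
    f[:, 1] += 0.3 * c[:, 1] / (np.abs(c[:, 1]).max() + 1e-9)
    return _normalize_field(f)


# ---------------------------------------------------------------------------
# cohort generation


def _sample_age(rng: np.random.Generator, lo: float, hi: float) -> float:
    # gamma(3, 2.4): mean 7.2, sd ~4.2 years
    return float(np.clip(rng.gamma(3.0, 2.4), lo, hi))


def _similarity(rng: np.random.Generator, pts: np.ndarray) -> np.ndarray:
    """Random in-plane similarity transform (pose/zoom nuisance)."""
    ang = rng.uniform(-np.pi / 18, np.pi / 18)
    scale = rng.uniform(0.85, 1.2)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    center = np.array([CANVAS / 2, CANVAS / 2])
    shift = rng.uniform(-12, 12, size=2) + (IMAGE_SIZE - CANVAS) / 2
    return (pts - center) @ (scale * R.T) + center + shift


def _zone_texture_params(
    zone_name: str, label: str, cfg: SynthConfig
) -> tuple[float, float]:
    """(noise sd, smoothing sigma) of a zone's band-limited texture."""
    contrast, sigma = 18.0, 2.0
    if label != "control" and zone_name in _KS_TEXTURE_ZONES:
        contrast *= 1.0 + cfg.texture_effect
        sigma /= 1.0 + 0.5 * cfg.texture_effect
    if label == "KS2" and zone_name in _KS2_TEXTURE_ZONES:
        contrast *= 1.0 + cfg.subtype_texture_effect
    return contrast, sigma


def _render_view(
    rng: np.random.Generator,
    view: str,
    pts: np.ndarray,
    label: str,
    cfg: SynthConfig,
) -> np.ndarray:
    """Draw a synthetic photo: skin-like base plus per-zone textures."""
    from skimage.draw import polygon as draw_polygon

    img = 175.0 + gaussian_filter(rng.normal(0, 6.0, (IMAGE_SIZE, IMAGE_SIZE)), 2.0)
    zones = [z for z in ZONES if z.view == ("frontal" if view == "frontal" else "lateral")]
    for zone in zones:
        poly = pts[list(zone.polygon)]
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=img.shape)
        if rr.size == 0:
            continue
        contrast, sigma = _zone_texture_params(zone.name, label, cfg)
        y0, y1 = rr.min(), rr.max() + 1
        x0, x1 = cc.min(), cc.max() + 1
        noise = gaussian_filter(
            rng.normal(0, 1.0, (y1 - y0, x1 - x0)), sigma
        )
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * contrast
        img[rr, cc] = 140.0 + noise[rr - y0, cc - x0]
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a full synthetic cohort (landmarks, images, metadata).

    Landmarks per photo session are template + group displacement +
    age * (shared slope + individual slope) * growth field + Gaussian
    noise, then a random similarity transform (pose nuisance).  Half
    the lateral sessions are emitted in the left-profile convention
    (landmarks and image mirrored) to exercise laterality
    harmonization.  Byte-identical for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    fields = {t: _ks_field(t) for t in TEMPLATE_SIZES}
    sub_fields = {t: _subtype_field(t) for t in TEMPLATE_SIZES}
    growth = {t: _growth_field(t) for t in TEMPLATE_SIZES}
    templates = {t: template_points(t) for t in TEMPLATE_SIZES}

    groups = (
        [("control", None)] * cfg.n_controls
        + [("KS1", "KMT2D")] * cfg.n_ks1
        + [("KS2", "KDM6A")] * cfg.n_ks2
        + [("KS_unknown_gene", None)] * cfg.n_ks_unknown
    )
    table2 = table2_fixture()
    pools = {
        "KMT2D": [r for r in table2 if r.gene == "KMT2D"],
        "KDM6A": [r for r in table2 if r.gene == "KDM6A"],
    }

    meta: list[PhotoMeta] = []
    landmarks: dict = {}
    images: dict = {}
    variants: dict = {}

    for pi, (label, gene) in enumerate(groups):
        patient_id = f"P{pi:04d}"
        gender = "female" if rng.uniform() < cfg.female_prop else "male"
        ethnicity = rng.choice(
            ["African/Caribbean", "Asian", "Caucasian"], p=cfg.ethnicity_props
        )
        base_age = _sample_age(rng, *cfg.age_range)
        b_i = rng.normal(0.0, cfg.random_slope_sd)
        n_photos = int(rng.integers(cfg.photos_per_patient[0],
                                    cfg.photos_per_patient[1] + 1))
        if gene is not None:
            pool = pools[gene]
            variants[patient_id] = replace(pool[rng.integers(len(pool))])
        var = variants.get(patient_id)

        group_disp = {}
        for t in TEMPLATE_SIZES:
            d = np.zeros_like(templates[t])
            if label != "control":
                d = d + cfg.group_shape_effect * fields[t]
            if label == "KS1":
                d = d - 0.5 * cfg.subtype_shape_effect * sub_fields[t]
            elif label == "KS2":
                d = d + 0.5 * cfg.subtype_shape_effect * sub_fields[t]
            group_disp[t] = d

        for k in range(n_photos):
            photo_id = f"{patient_id}_v{k}"
            age = float(np.clip(base_age + 1.5 * k, *cfg.age_range))
            lateral_view = "lateral_left" if rng.uniform() < 0.5 else "lateral_right"
            views = []
            for view, template in (
                ("frontal", "frontal"),
                (lateral_view, "lateral"),
                ("ear", "ear"),
            ):
                pts = (
                    templates[template]
                    + group_disp[template]
                    + age * (cfg.allometric_slope + b_i) * growth[template]
                    + rng.normal(0, cfg.landmark_noise_sd, templates[template].shape)
                )
                pts = _similarity(rng, pts)
                if view != "ear":
                    img = _render_view(rng, view, pts, label, cfg)
                    if view == "lateral_left":
                        img = img[:, ::-1]
                        pts = pts.copy()
                        pts[:, 0] = IMAGE_SIZE - 1 - pts[:, 0]
                    images[(photo_id, view)] = img
                landmarks[(photo_id, view)] = LandmarkSet(
                    photo_id=photo_id, view=view, points=np.clip(pts, 0, IMAGE_SIZE - 1)
                )
                views.append(view)
            meta.append(
                PhotoMeta(
                    patient_id=patient_id,
                    photo_id=photo_id,
                    view="+".join(views),
                    age=age,
                    gender=gender,
                    ethnicity=str(ethnicity),
                    label=label,
                    gene=var.gene if var else "",
                    protein_hgvs=var.protein_hgvs if var else "",
                    cdna_hgvs=var.cdna_hgvs if var else "",
                )
            )

    return SynthCohort(config=cfg, meta=meta, landmarks=landmarks,
                       images=images, variants=variants)


# ---------------------------------------------------------------------------
# printed-table fixtures


def table2_fixture() -> list[VariantRecord]:
    """The 105 patient-level variant records of the molecular table.

    Unique HGVS strings as printed, with multiplicities expanded to one
    record per patient so the per-gene aggregate counts hold (82 KMT2D,
    23 KDM6A).  Categories are left blank for the classifier to fill.
    """
    path = resources.files("ksface.data") / "table2_variants.csv"
    with resources.as_file(path) as p:
        rows = read_variants(p)
    out: list[VariantRecord] = []
    for rec in rows:
        for _ in range(rec.multiplicity):
            out.append(replace(rec, multiplicity=1))
    return out


def confusion_fixtures() -> dict[int, tuple[list[str], list[str]]]:
    """The two validation confusion matrices as (predicted, reference).

    Design 1 (KS vs control): 24 patients — 13 true controls, 1 KS
    predicted control, 10 true KS.  Design 2 (KS1 vs KS2): 10 patients
    — 4 true KS1, 2 KS2 predicted KS1, 1 KS1 predicted KS2, 3 true KS2.
    """
    d1_pred = ["control"] * 14 + ["KS"] * 10
    d1_ref = ["control"] * 13 + ["KS"] * 11
    d2_pred = ["KS1"] * 6 + ["KS2"] * 4
    d2_ref = ["KS1"] * 4 + ["KS2"] * 2 + ["KS1"] * 1 + ["KS2"] * 3
    return {1: (d1_pred, d1_ref), 2: (d2_pred, d2_ref)}
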