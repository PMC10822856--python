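"""Zone-wise facial texture features: CLAHE equalization, gray-level
co-occurrence matrices and Haralick statistics.

Fourteen landmark-defined zones are analysed per photo session — 11 on
the frontal view (eyes, eyebrows, glabella, forehead, nasal tip,
philtrum, cheeks, chin) and 3 on the lateral view (pre-auricular
region, eye, zygoma relief).  Each zone is cropped along its landmark
polygon, masked to the polygon interior, resampled to a fixed 64x64
patch, contrast-equalized with CLAHE (reducing illumination and skin
tone influence), quantized and summarized by a GLCM at four angles.
Haralick's 14 statistics are computed per angle; their mean and range
(max - min) across angles give 28 features per zone, 392 per session.

Defaults (32 gray levels, unit pixel distance, clip limit 2.0 with 8x8
tiles) follow the classical GLCM/CLAHE settings; they are package
choices, documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon
from skimage.feature import graycomatrix
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkSet
from .templates import FRONTAL_ZONES, LATERAL_ZONES, ZONES, ZoneSpec

__all__ = [
    "GlcmSet",
    "ZoneFeatures",
    "ZoneError",
    "TextureFeaturizer",
    "extract_zones",
    "clahe",
    "glcm",
    "haralick28",
    "texture_features",
    "texture_feature_names",
    "HARALICK_STATS",
    "PATCH_SIZE",
]

PATCH_SIZE = 64  # standard resampled zone patch, pixels

#: Haralick's 14 statistics, in emission order.
HARALICK_STATS = (
    "energy",               # angular second moment
    "contrast",
    "correlation",
    "variance",             # sum of squares: variance
    "homogeneity",          # inverse difference moment
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                 # information measure of correlation 1
    "imc2",                 # information measure of correlation 2
    "mcc",                  # maximal correlation coefficient
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


class ZoneError(ValueError):
    """Degenerate or out-of-image zone polygon."""


@dataclass
class GlcmSet:
    """Normalized symmetric co-occurrence matrices at 0/45/90/135 deg."""

    matrices: np.ndarray  # (levels, levels, 4)
    levels: int
    distance: int


@dataclass
class ZoneFeatures:
    """The 28 texture features of one zone (14 stats x mean/range)."""

    zone_name: str
    values: np.ndarray
    names: list[str]


# ---------------------------------------------------------------------------
# zone extraction


def _as_gray_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.dtype != np.uint8:
        img = np.clip(np.asarray(img, dtype=float), 0, 255)
    return img.astype(float)


def extract_zones(
    image: np.ndarray,
    lms: LandmarkSet,
    patch_size: int = PATCH_SIZE,
) -> list[tuple[ZoneSpec, np.ndarray]]:
    """Crop and mask the registered zones of one view.

    Returns ``(zone, patch)`` pairs in registry order: 11 patches for a
    frontal view, 3 for a lateral view.  Pixels outside the landmark
    polygon are filled with the polygon-interior mean so the zone
    boundary does not inject artificial high-contrast pixel pairs, and
    the crop is resampled to ``patch_size`` square.
    """
    img = _as_gray_u8(image)
    h, w = img.shape
    if lms.view == "frontal":
        zones = FRONTAL_ZONES
    elif lms.view in ("lateral_left", "lateral_right"):
        zones = LATERAL_ZONES
    else:
        raise ZoneError(f"no zones registered for view {lms.view!r}")

    pts = lms.points
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > w - 1 or pts[:, 1].max() > h - 1):
        warnings.warn("landmarks outside image bounds; clamping", stacklevel=2)
        pts = np.column_stack(
            [np.clip(pts[:, 0], 0, w - 1), np.clip(pts[:, 1], 0, h - 1)]
        )

    out = []
    for zone in zones:
        poly = pts[list(zone.polygon)]
        xs, ys = poly[:, 0], poly[:, 1]
        x0, x1 = int(np.floor(xs.min())), int(np.ceil(xs.max()))
        y0, y1 = int(np.floor(ys.min())), int(np.ceil(ys.max()))
        area = 0.5 * abs(
            np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
        )
        if area < 4.0 or x1 <= x0 or y1 <= y0:
            raise ZoneError(f"zone {zone.name!r}: degenerate polygon (area {area:.2f})")
        crop = img[y0 : y1 + 1, x0 : x1 + 1].copy()
        rr, cc = _draw_polygon(ys - y0, xs - x0, shape=crop.shape)
        if rr.size == 0:
            raise ZoneError(f"zone {zone.name!r}: polygon outside image")
        mask = np.zeros(crop.shape, dtype=bool)
        mask[rr, cc] = True
        interior_mean = crop[mask].mean()
        crop[~mask] = interior_mean
        patch = resize(
            crop, (patch_size, patch_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        out.append((zone, np.clip(patch, 0, 255)))
    return out


# ---------------------------------------------------------------------------
# CLAHE


def clahe(
    patch: np.ndarray,
    clip_limit: float = 2.0,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile 256-bin histograms are clipped at ``clip_limit`` times the
    uniform bin height, the clipped excess is redistributed uniformly,
    and each pixel is mapped by bilinear interpolation between the CDF
    mappings of the four surrounding tile centres.  Output is float in
    [0, 255].  With a single tile and a clip limit at or above the
    patch area the result reduces to plain global histogram
    equalization.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    img = np.clip(np.asarray(patch, dtype=float), 0, 255).astype(np.uint8)
    h, w = img.shape
    tr, tc = tiles
    if h < tr or w < tc:
        raise ValueError(f"patch {img.shape} smaller than tile grid {tiles}")

    # tile edges (last tiles absorb the remainder)
    re = np.linspace(0, h, tr + 1).round().astype(int)
    ce = np.linspace(0, w, tc + 1).round().astype(int)

    nbins = 256
    maps = np.empty((tr, tc, nbins))
    centers_r = np.empty(tr)
    centers_c = np.empty(tc)
    for i in range(tr):
        for j in range(tc):
            tile = img[re[i]:re[i + 1], ce[j]:ce[j + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            # clamp to >= 1 count so sparse tiles (fewer pixels than
            # bins) keep their rank structure instead of flattening
            clip = max(clip_limit * npix / nbins, 1.0)
            # clipped excess is redistributed proportionally (the
            # histogram is renormalized): unlike the classical uniform
            # spread this keeps the mapping a pure function of gray-level
            # *ranks*, so a monotone illumination change cannot move the
            # equalized output — which is the point of this step
            hist = np.minimum(hist, clip)
            cdf = np.cumsum(hist) / hist.sum()
            maps[i, j] = cdf * 255.0
            centers_r[i] = (re[i] + re[i + 1] - 1) / 2.0
            centers_c[j] = (ce[j] + ce[j + 1] - 1) / 2.0

    # bilinear interpolation between tile mappings
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    ri = np.clip(np.searchsorted(centers_r, rows) - 1, 0, max(tr - 2, 0))
    ci = np.clip(np.searchsorted(centers_c, cols) - 1, 0, max(tc - 2, 0))
    if tr > 1:
        fr = (rows - centers_r[ri]) / (centers_r[ri + 1] - centers_r[ri])
        fr = np.clip(fr, 0.0, 1.0)
    else:
        ri = np.zeros(h, dtype=int)
        fr = np.zeros(h)
    if tc > 1:
        fc = (cols - centers_c[ci]) / (centers_c[ci + 1] - centers_c[ci])
        fc = np.clip(fc, 0.0, 1.0)
    else:
        ci = np.zeros(w, dtype=int)
        fc = np.zeros(w)

    v = img  # (h, w) uint8 values index the per-tile maps
    ri2 = np.minimum(ri + 1, tr - 1)
    ci2 = np.minimum(ci + 1, tc - 1)
    RI, CI = np.meshgrid(ri, ci, indexing="ij")
    RI2, CI2 = np.meshgrid(ri2, ci2, indexing="ij")
    FR, FC = np.meshgrid(fr, fc, indexing="ij")
    m00 = maps[RI, CI, v]
    m01 = maps[RI, CI2, v]
    m10 = maps[RI2, CI, v]
    m11 = maps[RI2, CI2, v]
    out = (
        (1 - FR) * ((1 - FC) * m00 + FC * m01)
        + FR * ((1 - FC) * m10 + FC * m11)
    )
    return np.clip(out, 0, 255)


# ---------------------------------------------------------------------------
# GLCM and Haralick statistics


def glcm(patch: np.ndarray, levels: int = 32, distance: int = 1) -> GlcmSet:
    """Symmetric, normalized co-occurrence matrices at the 4 angles.

    The patch is quantized to ``levels`` bins uniformly over [0, 255];
    co-occurrences are counted symmetrically at ``distance`` pixels for
    0, 45, 90 and 135 degrees and each matrix normalized to sum 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = np.clip(np.asarray(patch, dtype=float), 0, 255)
    if img.shape[0] <= distance or img.shape[1] <= distance:
        raise ValueError("patch too small for the requested offset distance")
    q = np.minimum((img / (256.0 / levels)).astype(np.uint8), levels - 1)
    mats = graycomatrix(
        q, distances=[distance], angles=list(_ANGLES),
        levels=levels, symmetric=True, normed=True,
    )
    return GlcmSet(matrices=mats[:, :, 0, :].astype(float), levels=levels,
                   distance=distance)


_EPS = 1e-12


def _haralick14(p: np.ndarray) -> np.ndarray:
    """Haralick's 14 statistics of one normalized GLCM (base-2 logs).

    Degenerate cases take defined fallbacks: correlation and the maximal
    correlation coefficient are 0 when a marginal standard deviation
    vanishes or the Q-matrix eigenproblem degenerates, so constant
    patches yield finite features.
    """
    L = p.shape[0]
    i = np.arange(L, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = np.sum(i * px)
    mu_y = np.sum(i * py)
    var_x = np.sum((i - mu_x) ** 2 * px)
    var_y = np.sum((i - mu_y) ** 2 * py)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    ps = np.zeros(2 * L - 1)
    pd = np.zeros(L)
    np.add.at(ps, (ii + jj).astype(int), p)
    np.add.at(pd, diff.astype(int), p)

    energy = np.sum(p**2)
    contrast = np.sum(diff**2 * p)
    if var_x > _EPS and var_y > _EPS:
        correlation = (np.sum(ii * jj * p) - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    variance = np.sum((ii - mu_x) ** 2 * p)
    homogeneity = np.sum(p / (1.0 + diff**2))

    k_s = np.arange(2 * L - 1, dtype=float)
    k_d = np.arange(L, dtype=float)
    sum_average = np.sum(k_s * ps)
    sum_variance = np.sum((k_s - sum_average) ** 2 * ps)
    sum_entropy = -np.sum(ps[ps > _EPS] * np.log2(ps[ps > _EPS]))
    entropy = -np.sum(p[p > _EPS] * np.log2(p[p > _EPS]))
    d_mean = np.sum(k_d * pd)
    difference_variance = np.sum((k_d - d_mean) ** 2 * pd)
    difference_entropy = -np.sum(pd[pd > _EPS] * np.log2(pd[pd > _EPS]))

    hx = -np.sum(px[px > _EPS] * np.log2(px[px > _EPS]))
    hy = -np.sum(py[py > _EPS] * np.log2(py[py > _EPS]))
    pxy = np.outer(px, py)
    mask = (p > _EPS) | (pxy > _EPS)
    hxy1 = -np.sum(p[mask] * np.log2(pxy[mask] + _EPS))
    hxy2 = -np.sum(pxy[mask] * np.log2(pxy[mask] + _EPS))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > _EPS else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - entropy, 0.0))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    # maximal correlation coefficient
    nz = (px > _EPS) & (py > _EPS)
    if nz.sum() >= 2:
        sub = p[np.ix_(nz, nz)]
        q = (sub / px[nz, None]) @ (sub / py[None, nz]).T
        try:
            ev = np.sort(np.linalg.eigvals(q).real)
            mcc = float(np.sqrt(max(ev[-2], 0.0))) if len(ev) >= 2 else 0.0
        except np.linalg.LinAlgError:
            mcc = 0.0
    else:
        mcc = 0.0

    return np.array([
        energy, contrast, correlation, variance, homogeneity,
        sum_average, sum_variance, sum_entropy, entropy,
        difference_variance, difference_entropy, imc1, imc2, mcc,
    ])


def haralick28(g: GlcmSet, zone_name: str = "") -> ZoneFeatures:
    """Mean and range across the 4 angles of Haralick's 14 statistics."""
    per_angle = np.stack([_haralick14(g.matrices[:, :, a]) for a in range(4)])
    mean = per_angle.mean(axis=0)
    rng = per_angle.max(axis=0) - per_angle.min(axis=0)
    values = np.concatenate([
        np.array([m, r]) for m, r in zip(mean, rng)
    ])
    names = []
    for stat in HARALICK_STATS:
        names += [f"{stat}_mean", f"{stat}_range"]
    return ZoneFeatures(zone_name=zone_name, values=values, names=names)


# ---------------------------------------------------------------------------
# per-session feature vector


def texture_feature_names() -> list[str]:
    """The 392 texture feature names, ``{zone}_{stat}_{mean|range}``."""
    names = []
    for zone in ZONES:
        for stat in HARALICK_STATS:
            names += [f"{zone.name}_{stat}_mean", f"{zone.name}_{stat}_range"]
    return names


class TextureFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from (image, landmarks) views to the
    392-element zone texture vector.

    Parameters mirror the zone pipeline: CLAHE clip limit and tile
    grid, GLCM gray-level count and offset distance, patch size.
    """

    def __init__(
        self,
        levels: int = 32,
        distance: int = 1,
        clip_limit: float = 2.0,
        tiles: tuple[int, int] = (8, 8),
        patch_size: int = PATCH_SIZE,
    ):
        self.levels = levels
        self.distance = distance
        self.clip_limit = clip_limit
        self.tiles = tiles
        self.patch_size = patch_size

    def fit(self, X=None, y=None):
        return self

    def transform_session(
        self,
        frontal_img: np.ndarray | None,
        frontal_lms: LandmarkSet | None,
        lateral_img: np.ndarray | None,
        lateral_lms: LandmarkSet | None,
    ) -> np.ndarray:
        """Texture vector for one photo session (NaN for a missing view)."""
        if frontal_img is None and lateral_img is None:
            raise ValueError("at least one of the two views must be present")
        chunks: dict[str, np.ndarray] = {}
        for img, lms in ((frontal_img, frontal_lms), (lateral_img, lateral_lms)):
            if img is None or lms is None:
                continue
            for zone, patch in extract_zones(img, lms, self.patch_size):
                eq = clahe(patch, self.clip_limit, self.tiles)
                g = glcm(eq, self.levels, self.distance)
                chunks[zone.name] = haralick28(g, zone.name).values
        out = []
        for zone in ZONES:
            out.append(chunks.get(zone.name, np.full(28, np.nan)))
        return np.concatenate(out)

    def transform(self, X) -> np.ndarray:
        """X: iterable of (frontal_img, frontal_lms, lateral_img, lateral_lms)."""
        return np.stack([self.transform_session(*row) for row in X])


def texture_features(
    frontal_img, frontal_lms, lateral_img, lateral_lms, **params
) -> pd.Series:
    """392 named texture features for one photo session."""
    vec = TextureFeaturizer(**params).transform_session(
        frontal_img, frontal_lms, lateral_img, lateral_lms
    )
    return pd.Series(vec, index=texture_feature_names())
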