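"""Geometric morphometrics: generalized Procrustes superimposition and
principal-component shape scores.

Photographs are uncalibrated, so only shape is analysed: every landmark
configuration is centred, scaled to unit centroid size and rotated onto
the evolving mean shape (rotation only — reflections are excluded so a
face is never mirror-matched).  Centroid sizes are computed but never
used as features.  The aligned Procrustes coordinates are reduced with
PCA, retaining the smallest number of components whose cumulative
explained variance reaches a threshold (0.99 by default); the last
percent is treated as noise.

The three view templates (frontal, lateral, ear) are incommensurable
point sets and are superimposed in three separate analyses; their PC
scores are concatenated per photo session downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .landmarks import LandmarkSet, PhotoMeta

__all__ = [
    "AlignedShapes",
    "ShapeScores",
    "ProcrustesAligner",
    "ShapePCA",
    "gpa",
    "pca_reduce",
    "group_mean_shapes",
    "centroid_size",
]


def centroid_size(points: np.ndarray) -> float:
    """Root sum of squared distances of the landmarks to their centroid."""
    c = points - points.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def _center_scale(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    size = np.sqrt(np.sum(c**2))
    if size <= 0:
        raise ValueError("degenerate (zero-size) landmark configuration")
    return c / size


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||src @ R - dst||_F."""
    u, _, vt = np.linalg.svd(src.T @ dst)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


@dataclass
class AlignedShapes:
    """Procrustes-superimposed configurations of one template."""

    photo_ids: list[str]
    coords: np.ndarray          # (n_photos, 2k) row-flattened aligned points
    mean_shape: np.ndarray      # (2k,) unit-size mean configuration
    n_iterations: int
    converged: bool
    template_name: str = ""
    centroid_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1] // 2

    def shapes(self) -> np.ndarray:
        """Aligned configurations as an (n, k, 2) array."""
        return self.coords.reshape(len(self.photo_ids), -1, 2)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a}{i+1}" for i in range(self.n_points) for a in ("x", "y")]
        return pd.DataFrame(self.coords, index=self.photo_ids, columns=cols)


@dataclass
class ShapeScores:
    """PC scores of Procrustes coordinates at a variance threshold."""

    photo_ids: list[str]
    scores: np.ndarray            # (n_photos, m)
    explained_fraction: np.ndarray  # (m,)
    m: int
    prefix: str = "gPC"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{self.prefix}{i+1}" for i in range(self.m)]
        return pd.DataFrame(self.scores, index=self.photo_ids, columns=cols)


class ProcrustesAligner(BaseEstimator, TransformerMixin):
    """Generalized Procrustes analysis as a transformer.

    ``fit`` runs the iterative superimposition on a sequence of
    landmark configurations; ``transform`` aligns configurations (seen
    or new) onto the fitted mean shape by ordinary Procrustes
    superimposition, which is how held-out photos enter the fitted
    shape space without influencing it.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the Frobenius change of the mean shape.
    max_iter : int
        Iteration cap; GPA converges in a handful of iterations.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: Sequence[LandmarkSet] | np.ndarray, y=None):
        shapes, photo_ids, template = _as_shape_array(X)
        n, k, _ = shapes.shape
        sizes = np.array([centroid_size(s) for s in shapes])
        normed = np.stack([_center_scale(s) for s in shapes])

        mean = normed[0].copy()
        mean /= np.sqrt(np.sum(mean**2))
        n_it = 0
        converged = False
        for n_it in range(1, self.max_iter + 1):
            aligned = np.stack([s @ _optimal_rotation(s, mean) for s in normed])
            new_mean = aligned.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            norm = np.sqrt(np.sum(new_mean**2))
            if norm <= 0:
                raise ValueError("degenerate mean shape during GPA")
            new_mean /= norm
            if np.sqrt(np.sum((new_mean - mean) ** 2)) < self.tol:
                mean = new_mean
                converged = True
                break
            mean = new_mean
        aligned = np.stack([s @ _optimal_rotation(s, mean) for s in normed])

        self.mean_shape_ = mean
        self.template_name_ = template
        self.n_iterations_ = n_it
        self.converged_ = converged
        self.aligned_ = AlignedShapes(
            photo_ids=photo_ids,
            coords=aligned.reshape(n, 2 * k),
            mean_shape=mean.ravel(),
            n_iterations=n_it,
            converged=converged,
            template_name=template,
            centroid_sizes=sizes,
        )
        return self

    def transform(self, X: Sequence[LandmarkSet] | np.ndarray) -> np.ndarray:
        shapes, _, template = _as_shape_array(X)
        if template and self.template_name_ and template != self.template_name_:
            raise ValueError(
                f"aligner fitted on {self.template_name_!r}, got {template!r}"
            )
        out = []
        for s in shapes:
            z = _center_scale(s)
            out.append(z @ _optimal_rotation(z, self.mean_shape_))
        return np.stack(out).reshape(len(shapes), -1)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).aligned_.coords


def _as_shape_array(X) -> tuple[np.ndarray, list[str], str]:
    """Coerce LandmarkSets or an (n, k, 2) array into a shape stack."""
    if isinstance(X, np.ndarray):
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("expected an (n, k, 2) array of configurations")
        return X.astype(float), [str(i) for i in range(len(X))], ""
    sets = list(X)
    if not sets:
        raise ValueError("need at least one landmark configuration")
    template = sets[0].template_name
    if any(l.template_name != template for l in sets):
        raise ValueError("mixed templates in one superimposition")
    shapes = np.stack([l.points for l in sets]).astype(float)
    return shapes, [l.photo_id for l in sets], template


class ShapePCA(BaseEstimator, TransformerMixin):
    """PCA of Procrustes coordinates with cumulative-variance retention.

    Keeps the smallest m with cumulative explained variance fraction
    >= ``variance_threshold``.  Applied to the aligned coordinates
    directly (no tangent-space projection).
    """

    def __init__(self, variance_threshold: float = 0.99):
        self.variance_threshold = variance_threshold

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("ShapePCA requires an (n >= 2, d) matrix")
        self._pca = PCA(svd_solver="full")
        self._pca.fit(X)
        ratios = self._pca.explained_variance_ratio_
        cum = np.cumsum(ratios)
        m = int(np.searchsorted(cum, self.variance_threshold - 1e-12) + 1)
        m = min(m, len(ratios))
        self.m_ = m
        self.explained_fraction_ = ratios[:m].copy()
        self.components_ = self._pca.components_[:m]
        self.mean_ = self._pca.mean_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


# ---------------------------------------------------------------------------
# functional wrappers


def gpa(
    configs: Sequence[LandmarkSet] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes superimposition of landmark configurations."""
    return ProcrustesAligner(tol=tol, max_iter=max_iter).fit(configs).aligned_


def pca_reduce(
    aligned: AlignedShapes, variance_threshold: float = 0.99, prefix: str = "gPC"
) -> ShapeScores:
    """PC scores of aligned shapes at the cumulative-variance threshold."""
    est = ShapePCA(variance_threshold=variance_threshold).fit(aligned.coords)
    return ShapeScores(
        photo_ids=list(aligned.photo_ids),
        scores=est.transform(aligned.coords),
        explained_fraction=est.explained_fraction_,
        m=est.m_,
        prefix=prefix,
    )


def group_mean_shapes(
    aligned: AlignedShapes,
    meta: Sequence[PhotoMeta],
    age_bins: Sequence[float],
) -> pd.DataFrame:
    """Mean aligned shape per (diagnostic label, age bin).

    ``age_bins`` are ordered bin edges; ages fall into ``len(age_bins)-1``
    intervals (left-closed, last right-closed).  Empty cells are kept
    with NaN coordinates and ``n = 0`` rather than silently dropped.
    """
    by_id = {m.photo_id: m for m in meta}
    missing = [p for p in aligned.photo_ids if p not in by_id]
    if missing:
        raise KeyError(f"metadata missing for photo(s) {missing[:5]}")
    edges = np.asarray(age_bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("age_bins must be increasing edges of >= 1 bin")

    labels = [by_id[p].label for p in aligned.photo_ids]
    ages = np.array([by_id[p].age for p in aligned.photo_ids])
    bin_ix = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    bin_names = [f"[{edges[i]:g}, {edges[i+1]:g})" for i in range(len(edges) - 1)]

    rows = []
    for lab in sorted(set(labels)):
        for bi, bname in enumerate(bin_names):
            mask = np.array([l == lab for l in labels]) & (bin_ix == bi)
            n = int(mask.sum())
            mean = aligned.coords[mask].mean(axis=0) if n else np.full(
                aligned.coords.shape[1], np.nan
            )
            rows.append({"label": lab, "age_bin": bname, "n": n, "mean_shape": mean})
    return pd.DataFrame(rows)
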