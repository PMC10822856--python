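"""Metadata residualization via per-feature linear mixed models.

Repeated photographs of the same patient are not independent, and age,
gender and ethnicity all shift facial features.  Each feature column f
is therefore modelled as

    f_ij = alpha + age_ij * beta1 + gender_i * beta2 + ethnicity_i * beta3
           + age_ij * b_i + eps_ij,

with a per-individual random *slope* on age, b_i ~ N(0, sigma_b^2)
(no random intercept), and eps_ij ~ N(0, sigma^2).  The classifier
consumes the residuals eps_ij = observed - fitted, where the fitted
value includes the BLUP-predicted random slope for individuals seen
during fitting and the population-level prediction (b_i = 0) for
unseen individuals, so validation labels never leak into the fit.

Estimation is REML.  Because the random part is a single scalar slope
per individual, the marginal covariance of each individual's photos is
sigma^2 (I + lam * a a^T) with a the individual's age vector and
lam = sigma_b^2 / sigma^2 — a rank-one update whose inverse and
determinant are closed-form.  The REML criterion therefore profiles
down to a one-dimensional optimization in log(lam), solved here by a
coarse grid plus golden-section refinement, *vectorized across feature
columns*: every evaluation computes the criterion for all features at
their own candidate lam simultaneously.  This is exact (not an
approximation) and fast enough for the hundreds of per-feature fits
the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import PhotoMeta

__all__ = [
    "MixedModelFit",
    "ResidualMatrix",
    "MixedEffectsResidualizer",
    "fit_feature_lmm",
    "residualize",
]

_ETH_DUMMIES = ("African/Caribbean", "Asian")  # Caucasian is the reference
_LOG_LAM_LO, _LOG_LAM_HI = -16.0, 16.0
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class MixedModelFit:
    """REML estimates of the per-feature mixed model."""

    feature_name: str
    alpha: float
    beta_age: float
    beta_gender: float            # male vs female
    beta_ethnicity: np.ndarray    # (African/Caribbean, Asian) vs Caucasian
    random_slopes: dict[str, float]   # patient_id -> BLUP slope
    var_slope: float
    var_resid: float
    converged: bool

    def fixed_coefs(self) -> np.ndarray:
        return np.concatenate(
            [[self.alpha, self.beta_age, self.beta_gender], self.beta_ethnicity]
        )


@dataclass
class ResidualMatrix:
    """Residual features, aligned with the input feature matrix."""

    photo_ids: list[str]
    residuals: np.ndarray
    feature_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.residuals, index=self.photo_ids, columns=self.feature_names
        )


def _design_matrix(meta: Sequence[PhotoMeta]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fixed-effects design (intercept, age, male, 2 ethnicity dummies)."""
    age = np.array([m.age for m in meta], dtype=float)
    male = np.array([1.0 if m.gender == "male" else 0.0 for m in meta])
    eth = np.column_stack(
        [[1.0 if m.ethnicity == e else 0.0 for m in meta] for e in _ETH_DUMMIES]
    )
    X = np.column_stack([np.ones(len(age)), age, male, eth])
    groups = [m.patient_id for m in meta]
    return X, age, groups


class _BatchLmm:
    """Profiled REML for many feature columns over one design.

    Precomputes the per-group rank-one structures once; the REML
    criterion, GLS solutions and BLUPs are then dense batched linear
    algebra over (n_groups, n_features) arrays.
    """

    def __init__(self, X: np.ndarray, age: np.ndarray, groups: Sequence[str]):
        self.X = X
        self.age = age
        self.n, self.p = X.shape
        self.group_ids = sorted(set(groups))
        gmap = {g: i for i, g in enumerate(self.group_ids)}
        self.gidx = np.array([gmap[g] for g in groups])
        self.G = len(self.group_ids)

        aX = X * age[:, None]
        self.Ba = np.zeros((self.G, self.p))      # a_g^T X_g
        np.add.at(self.Ba, self.gidx, aX)
        self.s = np.zeros(self.G)                 # a_g^T a_g
        np.add.at(self.s, self.gidx, age**2)
        self.XtX = X.T @ X

    def _aggregate(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a^T y per group, X^T y, y^T y) for all columns of Y."""
        U = np.zeros((self.G, Y.shape[1]))
        np.add.at(U, self.gidx, self.age[:, None] * Y)
        return U, self.X.T @ Y, np.sum(Y * Y, axis=0)

    def _solve(self, lam: np.ndarray, U, XtY, yty):
        """GLS at per-feature lam; returns (crit, beta, rss, ok)."""
        with np.errstate(over="ignore", invalid="ignore"):
            D = 1.0 + lam[None, :] * self.s[:, None]            # (G, F)
            C = lam[None, :] / D
            logdet_v = np.log(D).sum(axis=0)
            XtWX = self.XtX[None] - np.einsum("gf,gp,gq->fpq", C, self.Ba, self.Ba)
            CU = C * U
            XtWy = XtY - self.Ba.T @ CU                          # (p, F)
            yWy = yty - np.sum(CU * U, axis=0)
            sign, logdet_x = np.linalg.slogdet(XtWX)
            ok = sign > 0
            beta = np.full((len(lam), self.p), np.nan)
            if np.any(ok):
                beta[ok] = np.linalg.solve(XtWX[ok], XtWy.T[ok, :, None])[:, :, 0]
            rss = yWy - np.einsum("fp,pf->f", beta, XtWy)
            dof = self.n - self.p
            crit = np.where(
                ok & (rss > 0) & np.isfinite(rss),
                dof * np.log(np.maximum(rss, 1e-300) / dof) + logdet_v + logdet_x,
                np.inf,
            )
        return crit, beta, rss, ok

    def fit(self, Y: np.ndarray):
        """REML-fit all columns; returns (lam, beta, var_slope, var_resid,
        blups (G, F), converged)."""
        F = Y.shape[1]
        U, XtY, yty = self._aggregate(Y)

        # coarse bracket on log-lam, then golden-section refinement
        grid = np.linspace(_LOG_LAM_LO, _LOG_LAM_HI, 33)
        crits = np.stack([
            self._solve(np.full(F, np.exp(t)), U, XtY, yty)[0] for t in grid
        ])
        best = np.argmin(crits, axis=0)
        step = grid[1] - grid[0]
        lo = grid[best] - step
        hi = grid[best] + step
        c = hi - _GOLDEN * (hi - lo)
        d = lo + _GOLDEN * (hi - lo)
        fc = self._solve(np.exp(c), U, XtY, yty)[0]
        fd = self._solve(np.exp(d), U, XtY, yty)[0]
        for _ in range(40):
            left = fc < fd
            hi = np.where(left, d, hi)
            lo = np.where(left, lo, c)
            c_new = hi - _GOLDEN * (hi - lo)
            d_new = lo + _GOLDEN * (hi - lo)
            # re-evaluate both probes (cheap; keeps the update branch-free)
            c, d = c_new, d_new
            fc = self._solve(np.exp(c), U, XtY, yty)[0]
            fd = self._solve(np.exp(d), U, XtY, yty)[0]

        lam = np.exp((lo + hi) / 2.0)
        # features whose criterion is infinite everywhere (singular design,
        # zero residual variance) fall back to ordinary least squares
        degenerate = ~np.isfinite(np.min(crits, axis=0))
        lam = np.where(lam < 1e-8, 0.0, lam)
        lam[degenerate] = 0.0

        crit, beta, rss, ok = self._solve(lam, U, XtY, yty)
        bad = ~ok | ~np.isfinite(rss)
        if np.any(bad):
            b_ls, *_ = np.linalg.lstsq(self.X, Y[:, bad], rcond=None)
            beta[bad] = b_ls.T
            r = Y[:, bad] - self.X @ b_ls
            rss[bad] = np.sum(r * r, axis=0)
        dof = max(self.n - self.p, 1)
        var_resid = np.maximum(rss / dof, 1e-30)
        var_slope = lam * var_resid

        R = Y - self.X @ beta.T
        Ur = np.zeros((self.G, F))
        np.add.at(Ur, self.gidx, self.age[:, None] * R)
        D = 1.0 + lam[None, :] * self.s[:, None]
        blups = lam[None, :] * Ur / D

        converged = ~(degenerate | bad)
        return lam, beta, var_slope, var_resid, blups, converged


def _fit_columns(
    Y: np.ndarray, meta: Sequence[PhotoMeta], names: Sequence[str]
) -> dict[str, MixedModelFit]:
    """Fit every column; columns with missing cells are fitted on their
    observed rows only (a per-column reduced design)."""
    X, age, groups = _design_matrix(meta)
    fits: dict[str, MixedModelFit] = {}

    complete = np.all(np.isfinite(Y), axis=0)
    if np.any(complete):
        ws = _BatchLmm(X, age, groups)
        out = ws.fit(Y[:, complete])
        _store(fits, out, np.asarray(names)[complete], ws)
    for j in np.flatnonzero(~complete):
        mask = np.isfinite(Y[:, j])
        if mask.sum() < X.shape[1] + 2:
            fits[names[j]] = _null_fit(names[j])
            continue
        sub_meta = [m for m, keep in zip(meta, mask) if keep]
        Xs, ages, gs = _design_matrix(sub_meta)
        ws = _BatchLmm(Xs, ages, gs)
        out = ws.fit(Y[mask][:, [j]])
        _store(fits, out, [names[j]], ws)
    return fits


def _store(fits, out, names, ws: _BatchLmm) -> None:
    lam, beta, var_slope, var_resid, blups, converged = out
    for k, name in enumerate(names):
        fits[name] = MixedModelFit(
            feature_name=str(name),
            alpha=float(beta[k, 0]),
            beta_age=float(beta[k, 1]),
            beta_gender=float(beta[k, 2]),
            beta_ethnicity=beta[k, 3:5].copy(),
            random_slopes={
                g: float(blups[i, k]) for i, g in enumerate(ws.group_ids)
            },
            var_slope=float(var_slope[k]),
            var_resid=float(var_resid[k]),
            converged=bool(converged[k]),
        )


def _null_fit(name: str) -> MixedModelFit:
    return MixedModelFit(
        feature_name=name, alpha=0.0, beta_age=0.0, beta_gender=0.0,
        beta_ethnicity=np.zeros(2), random_slopes={},
        var_slope=0.0, var_resid=1e-30, converged=False,
    )


def fit_feature_lmm(
    feature: np.ndarray, meta: Sequence[PhotoMeta], feature_name: str = "feature"
) -> MixedModelFit:
    """REML fit of the metadata mixed model for one feature column."""
    y = np.asarray(feature, dtype=float)
    if len(y) != len(meta):
        raise ValueError("feature vector and metadata length mismatch")
    if len({m.patient_id for m in meta}) < 2:
        raise ValueError("need >= 2 individuals to fit the mixed model")
    return _fit_columns(y[:, None], meta, [feature_name])[feature_name]


class MixedEffectsResidualizer(BaseEstimator, TransformerMixin):
    """Per-feature mixed-model residualization as a transformer.

    ``fit`` estimates one mixed model per feature column on the
    training photos; ``transform`` subtracts the fitted fixed part plus
    the BLUP random-slope contribution (individuals unseen at fit time
    get the population-level prediction, i.e. a zero random slope).
    """

    def fit(self, X: pd.DataFrame, meta: Sequence[PhotoMeta]):
        X = _as_feature_frame(X)
        meta = _align_meta(X, meta)
        if len({m.patient_id for m in meta}) < 2:
            raise ValueError("need >= 2 individuals to fit the mixed models")
        self.fits_ = _fit_columns(
            X.to_numpy(dtype=float), meta, [str(c) for c in X.columns]
        )
        self.feature_names_ = [str(c) for c in X.columns]
        return self

    def transform(self, X: pd.DataFrame, meta: Sequence[PhotoMeta]) -> ResidualMatrix:
        X = _as_feature_frame(X)
        if [str(c) for c in X.columns] != self.feature_names_:
            raise ValueError("feature columns differ from the fitted columns")
        meta = _align_meta(X, meta)
        Xd, age, _ = _design_matrix(meta)
        patient = [m.patient_id for m in meta]
        resid = np.empty(X.shape)
        vals = X.to_numpy(dtype=float)
        for j, col in enumerate(self.feature_names_):
            fit = self.fits_[col]
            fitted = Xd @ fit.fixed_coefs()
            fitted += age * np.array([fit.random_slopes.get(p, 0.0) for p in patient])
            resid[:, j] = vals[:, j] - fitted
        return ResidualMatrix(
            photo_ids=[str(i) for i in X.index],
            residuals=resid,
            feature_names=list(self.feature_names_),
        )

    def fit_transform(self, X, meta=None, **kw) -> ResidualMatrix:
        return self.fit(X, meta).transform(X, meta)

    def fit_report(self) -> pd.DataFrame:
        """Per-feature estimates, variance components and convergence."""
        rows = []
        for name, f in self.fits_.items():
            rows.append({
                "feature": name, "alpha": f.alpha, "beta_age": f.beta_age,
                "beta_gender_male": f.beta_gender,
                "beta_eth_african_caribbean": f.beta_ethnicity[0],
                "beta_eth_asian": f.beta_ethnicity[1],
                "var_slope": f.var_slope, "var_resid": f.var_resid,
                "converged": f.converged,
            })
        return pd.DataFrame(rows)


def _as_feature_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("features must be a DataFrame indexed by photo_id")


def _align_meta(X: pd.DataFrame, meta: Sequence[PhotoMeta]) -> list[PhotoMeta]:
    by_id = {m.photo_id: m for m in meta}
    missing = [p for p in X.index if str(p) not in by_id]
    if missing:
        raise KeyError(f"metadata missing for photo(s) {missing[:5]}")
    return [by_id[str(p)] for p in X.index]


def residualize(
    features: pd.DataFrame,
    meta: Sequence[PhotoMeta],
    fit_meta: Sequence[PhotoMeta] | None = None,
    fit_features: pd.DataFrame | None = None,
) -> ResidualMatrix:
    """Residualize a feature matrix against the metadata mixed models.

    With only ``features``/``meta`` given the models are fitted and
    applied on the same photos.  To fit on a training set and apply to
    other photos, pass the training ``fit_features``/``fit_meta``.
    """
    est = MixedEffectsResidualizer()
    if fit_features is None:
        return est.fit_transform(features, meta)
    est.fit(fit_features, fit_meta if fit_meta is not None else meta)
    return est.transform(features, meta)
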