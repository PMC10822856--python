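"""Patient-level splitting and gradient-boosted diagnostic classification.

Three binary designs are supported: (1) KS vs control, (2) KS1 vs KS2
and (3) PTV vs PAV within KS1.  Validation splits are drawn at the
patient level — a patient's photos all follow the patient — with the
validation size set to round(0.1 * number of KS patients) for design 1
(and the same number of controls).  Design 3 is evaluated by grouped
cross-validation only, without a held-out split.

The classifier is gradient-boosted trees (XGBoost) with logistic loss
and the defaults learning rate 0.3, gamma 0, maximum depth 6.  The
boosting-round count is chosen by five-fold cross-validation grouped by
patient (so repeated photos of one patient never straddle a fold
boundary), minimizing the mean validation misclassification rate; the
final model is refitted on all training photos at that round count.
Training is photo-level; reporting is patient-level via the mean of a
patient's photo probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GroupKFold

from .adjust import ResidualMatrix
from .landmarks import PhotoMeta

__all__ = [
    "SplitPlan",
    "GradientBoostedDiagnosis",
    "make_validation_split",
    "train_gbt",
    "predict",
    "patient_scores",
    "DEFAULT_HYPERPARAMS",
]

DEFAULT_HYPERPARAMS: dict = {
    "learning_rate": 0.3,
    "gamma": 0.0,
    "max_depth": 6,
    "objective": "binary:logistic",
}

#: design number -> (negative/reference-first class, positive class)
DESIGN_CLASSES = {1: ("control", "KS"), 2: ("KS1", "KS2"), 3: ("PTV", "PAV")}


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level train/validation split for one design."""

    design: int
    train_patients: frozenset
    validation_patients: frozenset
    seed: int

    def __post_init__(self):
        if self.train_patients & self.validation_patients:
            raise ValueError("train and validation patient sets overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _patients_by_label(meta: Sequence[PhotoMeta]) -> dict[str, set]:
    out: dict[str, set] = {}
    for m in meta:
        out.setdefault(m.label, set()).add(m.patient_id)
    return out


def make_validation_split(
    meta: Sequence[PhotoMeta], design: int, seed: int
) -> SplitPlan:
    """Uniform random patient-level validation split for a design.

    Design 1 holds out round(0.1 * n_KS) KS patients plus the same
    number of controls; design 2 holds out the same total count from
    the KS1/KS2 patients, balanced between the two genotypes; design 3
    uses no held-out set (cross-validation only).
    """
    rng = np.random.default_rng(seed)
    by_label = _patients_by_label(meta)
    ks_labels = ("KS1", "KS2", "KS_unknown_gene")
    ks_patients = sorted(set().union(*(by_label.get(l, set()) for l in ks_labels)))
    controls = sorted(by_label.get("control", set()))
    all_patients = {m.patient_id for m in meta}

    if design == 1:
        if len(ks_patients) < 2 or len(controls) < 2:
            raise ValueError("design 1 needs >= 2 KS and >= 2 control patients")
        n_val = _round_half_up(0.1 * len(ks_patients))
        n_val = max(n_val, 1)
        val = set(rng.choice(ks_patients, size=n_val, replace=False))
        val |= set(rng.choice(controls, size=n_val, replace=False))
    elif design == 2:
        ks1 = sorted(by_label.get("KS1", set()))
        ks2 = sorted(by_label.get("KS2", set()))
        if len(ks1) < 2 or len(ks2) < 2:
            raise ValueError("design 2 needs >= 2 KS1 and >= 2 KS2 patients")
        n_val = max(_round_half_up(0.1 * len(ks_patients)), 2)
        n1 = min((n_val + 1) // 2, len(ks1) - 1)
        n2 = min(n_val - n1, len(ks2) - 1)
        val = set(rng.choice(ks1, size=n1, replace=False))
        val |= set(rng.choice(ks2, size=n2, replace=False))
    elif design == 3:
        val = set()
    else:
        raise ValueError(f"unknown design {design}")

    return SplitPlan(
        design=design,
        train_patients=frozenset(all_patients - val),
        validation_patients=frozenset(val),
        seed=seed,
    )


class GradientBoostedDiagnosis(BaseEstimator, ClassifierMixin):
    """Gradient-boosted tree classifier with grouped-CV round selection.

    Parameters
    ----------
    learning_rate, gamma, max_depth : booster hyperparameters
        Defaults 0.3 / 0 / 6.
    n_cv_folds : int
        Patient-grouped cross-validation folds used to pick the
        boosting-round count (default 5).
    max_rounds : int
        Upper bound on boosting rounds scanned by CV (default 500).
    seed : int
        Booster and fold-shuffling seed.
    """

    def __init__(
        self,
        learning_rate: float = 0.3,
        gamma: float = 0.0,
        max_depth: int = 6,
        n_cv_folds: int = 5,
        max_rounds: int = 500,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.max_depth = max_depth
        self.n_cv_folds = n_cv_folds
        self.max_rounds = max_rounds
        self.seed = seed

    def _params(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "gamma": self.gamma,
            "max_depth": self.max_depth,
            "objective": "binary:logistic",
            "eval_metric": "error",
            "seed": int(self.seed) & 0x7FFFFFFF,
            "nthread": 1,
        }

    def fit(self, X, y, groups: Sequence[str] | None = None):
        X, feature_names = _as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        self.classes_ = classes
        ybin = (y == classes[1]).astype(int)
        if groups is None:
            groups = np.arange(len(ybin))
        groups = np.asarray(groups)

        dtrain = xgb.DMatrix(X, label=ybin, feature_names=feature_names,
                             missing=np.nan)
        n_folds = min(self.n_cv_folds, len(np.unique(groups)))
        folds = list(
            GroupKFold(n_splits=n_folds, shuffle=True,
                       random_state=int(self.seed) & 0x7FFFFFFF)
            .split(X, ybin, groups)
        )
        cv = xgb.cv(
            self._params(),
            dtrain,
            num_boost_round=self.max_rounds,
            folds=folds,
            shuffle=False,
            early_stopping_rounds=50,
        )
        errs = cv["test-error-mean"].to_numpy()
        self.n_rounds_ = int(np.argmin(errs)) + 1
        self.cv_error_ = float(errs[self.n_rounds_ - 1])
        self.cv_results_ = cv
        self.booster_ = xgb.train(
            self._params(), dtrain, num_boost_round=self.n_rounds_
        )
        self.feature_names_ = feature_names
        return self

    def predict_proba(self, X) -> np.ndarray:
        X, names = _as_matrix(X)
        if names != self.feature_names_:
            raise ValueError("feature names differ from the training features")
        d = xgb.DMatrix(X, feature_names=names, missing=np.nan)
        p1 = self.booster_.predict(d)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= 0.5, self.classes_[1], self.classes_[0])

    def importance(self, kind: str = "total_gain") -> dict[str, float]:
        """Per-feature gain of the fitted booster (absent features -> 0)."""
        score = self.booster_.get_score(importance_type=kind)
        return {f: float(score.get(f, 0.0)) for f in self.feature_names_}


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ResidualMatrix):
        return X.residuals.astype(float), list(X.feature_names)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def train_gbt(
    residuals: ResidualMatrix | pd.DataFrame,
    labels: Sequence,
    patient_ids: Sequence[str],
    hyper: Mapping | None = None,
    seed: int = 0,
) -> GradientBoostedDiagnosis:
    """Fit the grouped-CV gradient-boosted classifier on photo rows."""
    params = dict(DEFAULT_HYPERPARAMS)
    params.update(hyper or {})
    est = GradientBoostedDiagnosis(
        learning_rate=params["learning_rate"],
        gamma=params["gamma"],
        max_depth=params["max_depth"],
        seed=seed,
    )
    return est.fit(residuals, labels, groups=patient_ids)


def predict(
    model: GradientBoostedDiagnosis, residuals: ResidualMatrix | pd.DataFrame
) -> np.ndarray:
    """Per-photo probability of the positive (second) class."""
    return model.predict_proba(residuals)[:, 1]


def patient_scores(
    photo_probs: Sequence[float], patient_ids: Sequence[str]
) -> pd.Series:
    """Patient-level score: mean of the patient's photo probabilities."""
    s = pd.Series(np.asarray(photo_probs, dtype=float),
                  index=pd.Index(patient_ids, name="patient_id"))
    return s.groupby(level=0).mean()
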