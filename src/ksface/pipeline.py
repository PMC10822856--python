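"""End-to-end orchestration of the three classification designs.

``run_design`` executes, for one cohort and one design: patient-level
validation split -> per-view Procrustes superimposition and shape PCA
(fitted on training photos, applied to all) -> zone texture features ->
mixed-model residualization (fitted on training photos) -> grouped-CV
gradient boosting -> patient-level evaluation -> gain-based feature
selection -> UMAP embedding, and optionally writes the full artifact
bundle (features, residuals, model, evaluation report, ROC and
embedding tables, run log).

Designs: 1 = KS vs control, 2 = KS1 vs KS2, 3 = PTV vs PAV within KS1
(design 3 is evaluated by grouped cross-validation only).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import GroupKFold

from . import __version__
from .adjust import MixedEffectsResidualizer
from .classify import (
    DESIGN_CLASSES,
    GradientBoostedDiagnosis,
    SplitPlan,
    make_validation_split,
    patient_scores,
)
from .evaluate import (
    EvalReport,
    confusion_and_metrics,
    roc_auc,
    select_features_by_gain,
    umap_embed,
)
from .landmarks import PhotoMeta, mirror_lateral, read_landmarks, read_metadata
from .morphometrics import ProcrustesAligner, ShapePCA
from .synth import SynthCohort
from .texture import TextureFeaturizer, texture_feature_names
from .variants import VariantRecord, classify_variant

__all__ = ["CohortBundle", "RunResult", "run_design", "load_cohort", "design_labels"]


@dataclass
class CohortBundle:
    """A cohort ready for the pipeline: metadata, landmarks, images."""

    meta: list[PhotoMeta]
    landmarks: dict       # (photo_id, view) -> LandmarkSet
    images: dict          # (photo_id, view) -> ndarray

    @staticmethod
    def from_synth(cohort: SynthCohort) -> "CohortBundle":
        return CohortBundle(
            meta=list(cohort.meta),
            landmarks=dict(cohort.landmarks),
            images=dict(cohort.images),
        )


def load_cohort(landmarks_dir, images_dir, metadata_csv) -> CohortBundle:
    """Load a cohort from PTS/LJSON files, PNG/JPEG images and a CSV."""
    import imageio.v3 as iio

    meta = read_metadata(metadata_csv)
    landmarks, images = {}, {}
    ldir, idir = Path(landmarks_dir), Path(images_dir)
    for m in meta:
        for view in m.views:
            stem = f"{m.photo_id}_{view}"
            for ext in (".pts", ".ljson", ".json"):
                p = ldir / (stem + ext)
                if p.exists():
                    landmarks[(m.photo_id, view)] = read_landmarks(
                        p, view=view, photo_id=m.photo_id
                    )
                    break
            else:
                raise FileNotFoundError(f"no landmark file for {stem}")
            for ext in (".png", ".jpg", ".jpeg"):
                p = idir / (stem + ext)
                if p.exists():
                    images[(m.photo_id, view)] = iio.imread(p)
                    break
    return CohortBundle(meta=meta, landmarks=landmarks, images=images)


# ---------------------------------------------------------------------------
# design label derivation


def design_labels(meta: Sequence[PhotoMeta], design: int) -> dict[str, str]:
    """Patient -> binary class label for a design (patients not in the
    design's contrast are omitted)."""
    out: dict[str, str] = {}
    for m in meta:
        if m.patient_id in out:
            continue
        if design == 1:
            out[m.patient_id] = "KS" if m.is_ks else "control"
        elif design == 2:
            if m.label in ("KS1", "KS2"):
                out[m.patient_id] = m.label
        elif design == 3:
            if m.label == "KS1" and (m.protein_hgvs or m.cdna_hgvs):
                rec = VariantRecord(
                    gene=m.gene or "KMT2D",
                    protein_hgvs=m.protein_hgvs,
                    cdna_hgvs=m.cdna_hgvs,
                )
                rec.category = classify_variant(rec)
                out[m.patient_id] = "PTV" if rec.is_ptv else "PAV"
        else:
            raise ValueError(f"unknown design {design}")
    return out


# ---------------------------------------------------------------------------
# feature assembly


def _harmonized_landmarks(bundle: CohortBundle) -> dict:
    """All lateral sets brought to the right-profile convention."""
    out = {}
    for (photo_id, view), lms in bundle.landmarks.items():
        if view == "lateral_left":
            img = bundle.images.get((photo_id, view))
            width = img.shape[1] if img is not None else int(lms.points[:, 0].max()) + 1
            out[(photo_id, "lateral")] = mirror_lateral(lms, width)
        elif view == "lateral_right":
            out[(photo_id, "lateral")] = lms
        else:
            out[(photo_id, view)] = lms
    return out


def _harmonized_images(bundle: CohortBundle) -> dict:
    out = {}
    for (photo_id, view), img in bundle.images.items():
        if view == "lateral_left":
            out[(photo_id, "lateral")] = img[:, ::-1]
        elif view == "lateral_right":
            out[(photo_id, "lateral")] = img
        else:
            out[(photo_id, view)] = img
    return out


def build_features(
    bundle: CohortBundle,
    train_photo_ids: Sequence[str] | None = None,
    variance_threshold: float = 0.99,
    texturizer: TextureFeaturizer | None = None,
) -> pd.DataFrame:
    """Geometric PC scores + zone texture features per photo session.

    The three view templates are superimposed separately (on the
    training photos when ``train_photo_ids`` is given) and their PC
    scores concatenated; texture features come from the frontal and
    lateral views.  Missing views yield NaN cells, which the boosted
    trees handle natively.
    """
    photo_ids = [m.photo_id for m in bundle.meta]
    train = set(train_photo_ids) if train_photo_ids is not None else set(photo_ids)
    lms = _harmonized_landmarks(bundle)
    imgs = _harmonized_images(bundle)

    blocks: list[pd.DataFrame] = []
    for key in ("frontal", "lateral", "ear"):
        with_view = [p for p in photo_ids if (p, key) in lms]
        fit_ids = [p for p in with_view if p in train] or with_view
        aligner = ProcrustesAligner().fit([lms[(p, key)] for p in fit_ids])
        pca = ShapePCA(variance_threshold).fit(
            aligner.transform([lms[(p, key)] for p in fit_ids])
        )
        scores = pca.transform(aligner.transform([lms[(p, key)] for p in with_view]))
        cols = [f"{key}_gPC{i+1}" for i in range(pca.m_)]
        blocks.append(pd.DataFrame(scores, index=with_view, columns=cols))

    tex = texturizer or TextureFeaturizer()
    rows = []
    for p in photo_ids:
        f_im, f_lm = bundle.images.get((p, "frontal")), lms.get((p, "frontal"))
        l_im, l_lm = imgs.get((p, "lateral")), lms.get((p, "lateral"))
        if f_im is None and l_im is None:
            rows.append(np.full(392, np.nan))
        else:
            rows.append(tex.transform_session(f_im, f_lm, l_im, l_lm))
    blocks.append(
        pd.DataFrame(np.stack(rows), index=photo_ids, columns=texture_feature_names())
    )

    out = pd.concat(blocks, axis=1).loc[photo_ids]
    out.index.name = "photo_id"
    return out


# ---------------------------------------------------------------------------
# run


@dataclass
class RunResult:
    """Artifacts of one design run."""

    design: int
    seed: int
    split: SplitPlan
    features: pd.DataFrame
    residuals: pd.DataFrame
    model: GradientBoostedDiagnosis
    report: EvalReport
    patient_probs: pd.Series       # probability of the design's positive class
    patient_labels: pd.Series
    selected_features: list[str]
    embedding: pd.DataFrame | None
    roc_points: pd.DataFrame | None


def _substreams(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in ss.spawn(n)]


def run_design(
    bundle: CohortBundle | SynthCohort,
    design: int,
    seed: int = 0,
    out_dir=None,
    hyper: dict | None = None,
    umap_k: int = 15,
    embed: bool = True,
) -> RunResult:
    """Execute one classification design end to end.

    ``embed=False`` skips the UMAP embedding stage (useful for
    calibration sweeps where only the classification statistics are
    needed)."""
    if isinstance(bundle, SynthCohort):
        bundle = CohortBundle.from_synth(bundle)
    seed_split, seed_boost, seed_umap, _ = _substreams(seed)

    labels = design_labels(bundle.meta, design)
    meta = [m for m in bundle.meta if m.patient_id in labels]
    if len(set(labels.values())) < 2:
        raise ValueError(f"design {design}: cohort lacks one of the two classes")
    keep = {m.photo_id for m in meta}
    sub = CohortBundle(
        meta=meta,
        landmarks={k: v for k, v in bundle.landmarks.items() if k[0] in keep},
        images={k: v for k, v in bundle.images.items() if k[0] in keep},
    )

    split = make_validation_split(meta, design, seed_split)
    train_meta = [m for m in meta if m.patient_id in split.train_patients]
    val_meta = [m for m in meta if m.patient_id in split.validation_patients]
    train_ids = [m.photo_id for m in train_meta]

    features = build_features(sub, train_photo_ids=train_ids)

    resid_est = MixedEffectsResidualizer().fit(features.loc[train_ids], train_meta)
    residuals = resid_est.transform(features, meta).to_frame()

    y_train = np.array([labels[m.patient_id] for m in train_meta])
    groups = np.array([m.patient_id for m in train_meta])
    model = GradientBoostedDiagnosis(seed=seed_boost, **(hyper or {}))
    model.fit(residuals.loc[train_ids], y_train, groups=groups)

    neg_class, pos_class = DESIGN_CLASSES[design]
    pos_col = list(model.classes_).index(pos_class)

    if design == 3 or not val_meta:
        probs, eval_meta = _grouped_cv_probs(
            model, residuals.loc[train_ids], y_train, groups, pos_col
        ), train_meta
    else:
        probs = model.predict_proba(
            residuals.loc[[m.photo_id for m in val_meta]]
        )[:, pos_col]
        eval_meta = val_meta

    pat_probs = patient_scores(probs, [m.patient_id for m in eval_meta])
    pat_labels = pd.Series(
        {p: labels[p] for p in pat_probs.index}, name="label"
    ).loc[pat_probs.index]
    predicted = np.where(pat_probs.to_numpy() >= 0.5, pos_class, neg_class)

    report = confusion_and_metrics(predicted, pat_labels.to_numpy(),
                                   positive_class=neg_class)
    roc_points = None
    if len(set(pat_labels)) == 2:
        auc, auc_ci, roc_points = roc_auc(
            pat_probs.to_numpy(), pat_labels.to_numpy(), pos_class
        )
        report.auc, report.auc_ci = auc, auc_ci

    importance = model.importance()
    selected = (
        select_features_by_gain(importance)
        if sum(importance.values()) > 0
        else list(residuals.columns[:1])
    )
    embedding = None
    train_resid = residuals.loc[train_ids, selected]
    if embed and len(train_resid) > umap_k:
        emb = umap_embed(train_resid.to_numpy(), k=umap_k, seed=seed_umap)
        embedding = pd.DataFrame(emb, index=train_ids, columns=["umap1", "umap2"])

    result = RunResult(
        design=design, seed=seed, split=split, features=features,
        residuals=residuals, model=model, report=report,
        patient_probs=pat_probs, patient_labels=pat_labels,
        selected_features=selected, embedding=embedding, roc_points=roc_points,
    )
    if out_dir is not None:
        _write_bundle(result, resid_est, Path(out_dir))
    return result


def _grouped_cv_probs(
    model: GradientBoostedDiagnosis,
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    pos_col: int,
) -> np.ndarray:
    """Out-of-fold probabilities at the CV-selected round count."""
    ybin = (y == model.classes_[1]).astype(int)
    Xm = X.to_numpy(dtype=float)
    probs = np.empty(len(y))
    gkf = GroupKFold(n_splits=min(5, len(np.unique(groups))))
    for tr, te in gkf.split(Xm, ybin, groups):
        dtr = xgb.DMatrix(Xm[tr], label=ybin[tr],
                          feature_names=model.feature_names_, missing=np.nan)
        dte = xgb.DMatrix(Xm[te], feature_names=model.feature_names_,
                          missing=np.nan)
        booster = xgb.train(model._params(), dtr, num_boost_round=model.n_rounds_)
        p1 = booster.predict(dte)
        probs[te] = p1 if pos_col == 1 else 1.0 - p1
    return probs


def _write_bundle(result: RunResult, resid_est: MixedEffectsResidualizer, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv")
    result.residuals.to_csv(out / "residuals.csv")
    resid_est.fit_report().to_csv(out / "mixed_model_fits.csv", index=False)
    result.model.booster_.save_model(out / "model.json")
    result.report.to_json(out / "eval_report.json")
    pd.DataFrame({
        "patient_id": result.patient_probs.index,
        "probability": result.patient_probs.to_numpy(),
        "label": result.patient_labels.to_numpy(),
    }).to_csv(out / "patient_predictions.csv", index=False)
    if result.roc_points is not None:
        result.roc_points.to_csv(out / "roc_points.csv", index=False)
    if result.embedding is not None:
        result.embedding.to_csv(out / "umap_embedding.csv")
    pd.Series(result.selected_features).to_csv(
        out / "selected_features.csv", index=False, header=["feature"]
    )
    log = {
        "design": result.design,
        "seed": result.seed,
        "n_rounds": result.model.n_rounds_,
        "train_patients": sorted(result.split.train_patients),
        "validation_patients": sorted(result.split.validation_patients),
        "features_sha256": hashlib.sha256(
            result.features.round(10).to_csv().encode()
        ).hexdigest(),
        "versions": {
            "ksface": __version__,
            "python": platform.python_version(),
            "xgboost": xgb.__version__,
            "numpy": np.__version__,
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
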