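"""Evaluation statistics: confusion-matrix metrics with exact binomial
inference, empirical ROC/AUC, gain-based feature selection and UMAP
embeddings.

Confusion matrices are reported in the rows-are-predictions
orientation.  Accuracy carries a 95% Clopper-Pearson (exact binomial)
interval and a one-sided exact binomial p-value against the
no-information rate (the prevalence of the most frequent reference
class).  The F1 score is computed for the first-listed (reference)
class of the design.  AUC is the empirical Mann-Whitney statistic with
half credit for ties; its confidence interval uses DeLong's variance
estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "confusion_and_metrics",
    "roc_auc",
    "clopper_pearson",
    "select_features_by_gain",
    "umap_embed",
]


@dataclass
class EvalReport:
    """Classification report for one design on one patient set."""

    classes: tuple                      # (reference-first, other)
    confusion: np.ndarray               # 2x2, rows = predicted, cols = reference
    accuracy: float
    accuracy_ci: tuple                  # 95% exact binomial
    nir: float
    nir_p: float
    f1: float
    auc: float | None = None
    auc_ci: tuple | None = None

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["confusion"] = self.confusion.tolist()
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.classes, name="prediction"),
            columns=pd.Index(self.classes, name="reference"),
        )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def confusion_and_metrics(
    predicted: Sequence,
    reference: Sequence,
    positive_class=None,
) -> EvalReport:
    """Confusion matrix and accuracy/NIR/F1 statistics.

    ``positive_class`` names the class whose F1 is reported; it
    defaults to the first class in sorted order, which for the
    diagnostic designs is the reference-first convention (control in
    KS-vs-control, KS1 in KS1-vs-KS2).
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.size == 0 or pred.shape != ref.shape:
        raise ValueError("need equal-length non-empty label sequences")
    classes = sorted(set(ref) | set(pred))
    if len(classes) > 2:
        raise ValueError(f"expected two classes, got {classes}")
    if len(classes) == 1:
        classes = classes * 2  # degenerate all-one-class input
    if positive_class is None:
        positive_class = classes[0]
    elif positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not present")
    # order rows/cols with the positive (reference-first) class first
    classes = [positive_class] + [c for c in classes if c != positive_class]

    conf = np.zeros((2, 2), dtype=int)
    for p, r in zip(pred, ref):
        conf[classes.index(p), classes.index(r)] += 1

    n = int(conf.sum())
    correct = int(np.trace(conf))
    accuracy = correct / n
    ci = clopper_pearson(correct, n)
    nir = float(conf.sum(axis=0).max() / n)
    nir_p = float(stats.binom.sf(correct - 1, n, nir))  # P(X >= correct)

    tp = conf[0, 0]
    fp = conf[0, 1]
    fn = conf[1, 0]
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    return EvalReport(
        classes=tuple(classes),
        confusion=conf,
        accuracy=float(accuracy),
        accuracy_ci=ci,
        nir=nir,
        nir_p=nir_p,
        f1=float(f1),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rk = _midrank(allv)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    auc = (rk[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk[:m] - rk_pos) / n          # structural components over positives
    v01 = 1.0 - (rk[m:] - rk_neg) / m    # over negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(
    scores: Sequence[float],
    reference: Sequence,
    positive_class,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Empirical AUC with a DeLong confidence interval and ROC points.

    Ties receive half credit (Mann-Whitney convention).  Returns
    ``(auc, (lower, upper), roc_points)`` where the ROC points frame
    has columns fpr/tpr/threshold.
    """
    s = np.asarray(scores, dtype=float)
    ref = np.asarray(reference)
    pos = s[ref == positive_class]
    neg = s[ref != positive_class]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    auc, var = _delong_auc_var(pos, neg)
    if var > 0:
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    else:
        ci = (auc, auc)

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    points = []
    for t in thresholds:
        points.append({
            "threshold": t,
            "tpr": float(np.mean(pos >= t)),
            "fpr": float(np.mean(neg >= t)),
        })
    return auc, ci, pd.DataFrame(points)


# ---------------------------------------------------------------------------
# feature selection and embedding


def select_features_by_gain(
    importance: Mapping[str, float], threshold: float = 0.75
) -> list[str]:
    """Shortest descending-gain prefix with cumulative share > threshold.

    Gains are normalized to sum 1 and sorted descending (ties broken by
    name for determinism); the returned features are those the
    embedding keeps.
    """
    if not importance:
        raise ValueError("empty importance mapping")
    total = float(sum(importance.values()))
    if total <= 0:
        raise ValueError("total gain must be positive")
    items = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    out, cum = [], 0.0
    for name, gain in items:
        out.append(name)
        cum += gain / total
        if cum > threshold + 1e-12:  # strictly exceed, modulo accumulation error
            break
    return out


def umap_embed(
    residual_subset: np.ndarray,
    k: int = 15,
    metric: str = "cosine",
    min_dist: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding of the gain-selected residuals.

    Defaults follow the visual-clustering setup: neighbourhood size 15,
    cosine distances, effective minimum embedded distance 1e-6.
    Deterministic for a fixed seed.
    """
    import umap  # deferred: heavy import

    X = np.asarray(residual_subset, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D residual matrix")
    if X.shape[0] <= k:
        raise ValueError(f"need more than k={k} samples, got {X.shape[0]}")
    reducer = umap.UMAP(
        n_neighbors=k,
        n_components=2,
        metric=metric,
        min_dist=min_dist,
        random_state=int(seed) & 0x7FFFFFFF,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)
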