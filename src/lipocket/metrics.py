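"""Evaluation suite: formula-defined classification metrics, rank-based
AUROC, Cohen's kappa, PCA of descriptor space, and feature importances.

The five confusion-matrix metrics follow the standard definitions with LBP
as the positive class:

    sensitivity = TP / (TP + FN)          specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)          accuracy = (TP+TN) / total
    F1 = 2 / (1/sensitivity + 1/precision)

Metrics whose denominator vanishes are reported as explicit ``None`` flags
rather than silent zeros or NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from lipocket.dataset_curation import DescriptorTable
from lipocket.descriptors import DESCRIPTOR_NAMES

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "classification_metrics",
    "f1_from_rates",
    "confusion_from_predictions",
    "auroc",
    "cohens_kappa",
    "pca_project",
    "permutation_importance",
    "impurity_importance",
    "boxplot_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """A metric is ``None`` when its denominator is zero (undefined)."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None
    auroc: float | None = None
    kappa: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in (
            "sensitivity", "specificity", "precision", "accuracy", "f1",
            "auroc", "kappa")}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def f1_from_rates(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision."""
    if sensitivity <= 0 or precision <= 0:
        raise ValueError("F1 undefined for non-positive sensitivity/precision")
    return 2.0 / (1.0 / sensitivity + 1.0 / precision)


def classification_metrics(counts: ConfusionCounts) -> MetricSet:
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    prec = _ratio(counts.TP, counts.TP + counts.FP)
    acc = _ratio(counts.TP + counts.TN, counts.total)
    f1 = (f1_from_rates(sens, prec)
          if sens and prec and sens > 0 and prec > 0 else None)
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec,
                     accuracy=acc, f1=f1,
                     kappa=cohens_kappa(counts))


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Equivalent to the trapezoidal area over all distinct score thresholds;
    tied scores contribute half-wins.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cohens_kappa(counts: ConfusionCounts) -> float | None:
    """Chance-corrected agreement (p_o - p_e)/(1 - p_e) from the marginals;
    ``None`` when chance agreement is exactly 1."""
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (counts.TP + counts.TN) / n
    pred_pos = (counts.TP + counts.FP) / n
    pred_neg = (counts.TN + counts.FN) / n
    true_pos = (counts.TP + counts.FN) / n
    true_neg = (counts.TN + counts.FP) / n
    p_e = pred_pos * true_pos + pred_neg * true_neg
    if abs(1.0 - p_e) < 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# PCA of descriptor space
# ---------------------------------------------------------------------------

def pca_project(
    table: DescriptorTable,
    n_components: int = 2,
    feature_names: Sequence[str] = DESCRIPTOR_NAMES,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """PCA on standardized descriptors (correlation-matrix convention).

    Descriptors span cubic angstroms to unitless fractions, so columns are
    standardized to zero mean / unit variance first; constant columns are
    dropped with a warning.  Returns (scores, explained-variance fractions,
    loadings DataFrame indexed by descriptor).
    """
    X = table.features(feature_names)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    keep = X.std(axis=0) > 0
    names = [n for n, k in zip(feature_names, keep) if k]
    if not all(keep):
        import warnings

        dropped = [n for n, k in zip(feature_names, keep) if not k]
        warnings.warn(f"dropping constant descriptor columns: {dropped}")
    X = StandardScaler().fit_transform(X[:, keep])
    n_components = min(n_components, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pd.DataFrame(
        pca.components_.T, index=names,
        columns=[f"PC{i + 1}" for i in range(n_components)])
    return scores, pca.explained_variance_ratio_, loadings


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model,
    table: DescriptorTable,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Drop in F1 when one descriptor column is shuffled.

    For each descriptor, the column is permuted ``n_repeats`` times
    (seeded); rows report mean and standard deviation of
    baseline_F1 - permuted_F1.
    """
    X = table.features(model.feature_order)
    y = table.binary_labels()
    rng = np.random.default_rng(seed)

    def f1_of(Xm: np.ndarray) -> float:
        pred = (model.predict_proba(Xm) >= model.threshold).astype(int)
        c = confusion_from_predictions(y, pred)
        m = classification_metrics(c)
        return m.f1 if m.f1 is not None else 0.0

    baseline = f1_of(X)
    rows = []
    for j, name in enumerate(model.feature_order):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - f1_of(Xp))
        rows.append({"descriptor": name,
                     "delta_f1_mean": float(np.mean(drops)),
                     "delta_f1_sd": float(np.std(drops, ddof=0))})
    return pd.DataFrame(rows).set_index("descriptor")


def impurity_importance(model) -> pd.Series:
    """Mean-decrease-in-impurity importances of a tree ensemble, as
    fractions summing to 1."""
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise TypeError(
            "impurity importance requires a tree-ensemble model")
    imp = np.asarray(est.feature_importances_, dtype=float)
    return pd.Series(imp, index=list(model.feature_order), name="mdi")


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def boxplot_summary(values: Sequence[float]) -> dict:
    """Five-number summary with whiskers at the most extreme points within
    1.5 x IQR of the quartiles; points beyond are outliers."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "outliers": [float(x) for x in outliers],
    }
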