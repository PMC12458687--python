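"""Pocket classification: train, compare, tune, and apply models.

The task is binary — lipid-binding pocket (LBP) versus everything else
(nLBP and pseudo pockets jointly negative).  Random forest is the default
algorithm; five alternatives are available for benchmarking.  A pocket is
called positive when its predicted probability is at or above the decision
threshold (inclusive at the default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from lipocket.dataset_curation import DescriptorTable, stratified_split
from lipocket.descriptors import DESCRIPTOR_NAMES
from lipocket.metrics import (
    MetricSet,
    auroc,
    boxplot_summary,
    classification_metrics,
    confusion_from_predictions,
)

__all__ = [
    "ALGORITHMS",
    "TrainedModel",
    "SearchSpec",
    "train_classifier",
    "predict_pocket",
    "predict_table",
    "evaluate_model",
    "compare_algorithms",
    "tune_hyperparameters",
    "REFERENCE_GRID",
]

ALGORITHMS = ("svm", "logistic", "knn", "naive_bayes", "decision_tree",
              "random_forest")

#: the fine grid examined in the second tuning round
REFERENCE_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 400],
    "max_features": [2, 3, 4],
    "max_depth": [50, 70, 90],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "bootstrap": [True],
}

#: the coarse random-search ranges of the first tuning round
RANDOM_SEARCH_RANGES: dict[str, tuple] = {
    "n_estimators": (100, 1000),
    "max_features": (2, 4),
    "max_depth": (10, 100),
    "min_samples_split": (2, 10),
    "min_samples_leaf": (1, 4),
    "bootstrap": (True, False),
}


def _build_estimator(algorithm: str, hyperparameters: Mapping, seed: int):
    hp = dict(hyperparameters)
    if algorithm == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if algorithm == "logistic":
        hp.setdefault("max_iter", 2000)
        return make_pipeline(
            StandardScaler(), LogisticRegression(random_state=seed, **hp))
    if algorithm == "svm":
        hp.setdefault("probability", True)
        return make_pipeline(StandardScaler(), SVC(random_state=seed, **hp))
    if algorithm == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**hp))
    if algorithm == "naive_bayes":
        return GaussianNB(**hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; "
                     f"choose from {ALGORITHMS}")


@dataclass
class TrainedModel:
    algorithm: str
    estimator: object
    hyperparameters: dict
    feature_order: tuple[str, ...]
    threshold: float = 0.5
    train_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly in (0, 1)")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (lipid-binding) class per row."""
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    # -- persistence: JSON manifest + joblib estimator blob ----------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "algorithm": self.algorithm,
            "hyperparameters": self.hyperparameters,
            "feature_order": list(self.feature_order),
            "threshold": self.threshold,
            "train_manifest": self.train_manifest,
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n")
        joblib.dump(self.estimator, directory / "estimator.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        estimator = joblib.load(directory / "estimator.joblib")
        return cls(
            algorithm=manifest["algorithm"],
            estimator=estimator,
            hyperparameters=manifest["hyperparameters"],
            feature_order=tuple(manifest["feature_order"]),
            threshold=manifest["threshold"],
            train_manifest=manifest["train_manifest"],
        )


@dataclass(frozen=True)
class SearchSpec:
    mode: str  # "random" | "grid"
    space: Mapping[str, Sequence]
    n_iterations: int = 100
    cv_folds: int = 3
    objective: str = "f1"

    def __post_init__(self) -> None:
        if self.mode not in ("random", "grid"):
            raise ValueError("mode must be 'random' or 'grid'")
        if not self.space:
            raise ValueError("search space must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def train_classifier(
    train: DescriptorTable,
    algorithm: str = "random_forest",
    hyperparameters: Mapping | None = None,
    seed: int = 0,
    feature_order: Sequence[str] = DESCRIPTOR_NAMES,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit a binary LBP-vs-rest classifier on a descriptor table."""
    y = train.binary_labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    X = train.features(feature_order)
    est = _build_estimator(algorithm, hyperparameters or {}, seed)
    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        hyperparameters=dict(hyperparameters or {}),
        feature_order=tuple(feature_order),
        threshold=threshold,
        train_manifest={
            "seed": seed,
            "n_rows": len(train),
            "class_counts": train.class_counts,
        },
    )


def predict_pocket(model: TrainedModel, vector) -> float:
    """Probability that one pocket binds lipid.

    ``vector`` may be a PocketDescriptorVector or a name->value mapping;
    a missing feature raises a schema error naming the field.
    """
    if hasattr(vector, "as_dict"):
        values = vector.as_dict()
    else:
        values = dict(vector)
    row = []
    for name in model.feature_order:
        if name not in values:
            raise KeyError(f"descriptor vector missing feature {name!r}")
        row.append(float(values[name]))
    return float(model.predict_proba(np.array([row]))[0])


def predict_table(model: TrainedModel, table: DescriptorTable) -> pd.DataFrame:
    """Score every row; adds ``score`` and ``predicted`` (inclusive
    threshold) columns."""
    scores = model.predict_proba(table.features(model.feature_order))
    out = table.df.copy()
    out["score"] = scores
    out["predicted"] = (scores >= model.threshold).astype(int)
    return out


def evaluate_model(model: TrainedModel, test: DescriptorTable) -> MetricSet:
    """All six held-out metrics plus Cohen's kappa."""
    y = test.binary_labels()
    scores = model.predict_proba(test.features(model.feature_order))
    pred = (scores >= model.threshold).astype(int)
    counts = confusion_from_predictions(y, pred)
    m = classification_metrics(counts)
    return MetricSet(**{**m.as_dict(), "auroc": auroc(scores, y)})


# ---------------------------------------------------------------------------
# comparison and tuning
# ---------------------------------------------------------------------------

def compare_algorithms(
    table: DescriptorTable,
    algorithms: Sequence[str] = ALGORITHMS,
    n_repeats: int = 25,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> dict[str, dict[str, dict]]:
    """Benchmark algorithms by repeated stratified shuffle splits.

    Each repeat draws a fresh stratified 90:10 split, fits on the large
    part, and scores the held-out part; summaries report box-plot
    statistics (quartiles, whiskers at 1.5 x IQR, outliers) per metric.
    Training failures are recorded per repeat, never fatal.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    results: dict[str, dict[str, dict]] = {}
    for algorithm in algorithms:
        per_metric: dict[str, list[float]] = {}
        errors: list[str] = []
        for rep in range(n_repeats):
            train, test = stratified_split(
                table, test_fraction, seed=seed + rep)
            try:
                model = train_classifier(train, algorithm, seed=seed + rep)
                m = evaluate_model(model, test)
            except Exception as exc:
                errors.append(f"repeat {rep}: {exc}")
                continue
            for name, value in m.as_dict().items():
                if value is not None:
                    per_metric.setdefault(name, []).append(value)
        results[algorithm] = {
            name: boxplot_summary(vals) for name, vals in per_metric.items()
        }
        if errors:
            results[algorithm]["errors"] = errors  # type: ignore[assignment]
    return results


def _cv_f1(table: DescriptorTable, params: dict, cv_folds: int,
           seed: int) -> float:
    """k-fold cross-validated F1 of a random forest with given params."""
    y = table.binary_labels()
    X = table.features()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv_folds)
    f1s = []
    for k in range(cv_folds):
        test_idx = folds[k]
        train_idx = np.concatenate([folds[j] for j in range(cv_folds) if j != k])
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        est.fit(X[train_idx], y[train_idx])
        pos = list(est.classes_).index(1)
        pred = (est.predict_proba(X[test_idx])[:, pos] >= 0.5).astype(int)
        c = confusion_from_predictions(y[test_idx], pred)
        m = classification_metrics(c)
        f1s.append(m.f1 if m.f1 is not None else 0.0)
    return float(np.mean(f1s))


def enumerate_grid(space: Mapping[str, Sequence]) -> list[dict]:
    """Cross-product of the option lists, in a stable order."""
    names = list(space)
    return [dict(zip(names, combo))
            for combo in product(*(space[n] for n in names))]


def _sample_random(space: Mapping[str, tuple], n: int,
                   rng: np.random.Generator) -> list[dict]:
    """Random-search candidates: log-uniform for tree count and depth,
    uniform integers otherwise, fair coin for booleans."""
    log_uniform_params = {"n_estimators", "max_depth"}
    out = []
    for _ in range(n):
        params: dict = {}
        for name, bounds in space.items():
            lo, hi = bounds
            if isinstance(lo, bool):
                params[name] = bool(rng.integers(2)) if lo != hi else lo
            elif name in log_uniform_params:
                params[name] = int(round(np.exp(
                    rng.uniform(np.log(lo), np.log(hi)))))
            else:
                params[name] = int(rng.integers(lo, hi + 1))
        out.append(params)
    return out


def tune_hyperparameters(
    table: DescriptorTable,
    spec: SearchSpec,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Search random-forest hyperparameters maximizing cross-validated F1.

    ``random`` mode samples ``n_iterations`` candidates from ranges;
    ``grid`` mode enumerates the full cross-product.  Returns the best
    parameter set and a log of every candidate's score.
    """
    if spec.mode == "grid":
        candidates = enumerate_grid(spec.space)
        if not candidates:
            raise ValueError("empty hyperparameter grid")
    else:
        rng = np.random.default_rng(seed)
        candidates = _sample_random(spec.space, spec.n_iterations, rng)

    rows = []
    for i, params in enumerate(candidates):
        score = _cv_f1(table, params, spec.cv_folds, seed)
        rows.append({"candidate": i, **params, "cv_f1": score})
    log = pd.DataFrame(rows)
    best = candidates[int(log["cv_f1"].idxmax())]
    return best, log
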