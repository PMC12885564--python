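"""Brute-force ensemble driver: diverse model suite + importance extraction.

Trains a suite of standard model families (linear, decision tree, random
forest, gradient boosting, kernel SVM) on one tabular dataset, measures
held-out performance by repeated cross-validation, refits each model on the
full data and extracts a per-model feature-importance vector with the
backend appropriate to the family:

* COEFFICIENT_MAGNITUDE — |coefficients| of a (standardized) linear model;
* IMPURITY — mean impurity decrease of tree ensembles;
* PERMUTATION — model-agnostic permutation importance (performance drop
  when one feature column is shuffled), usable with any family.

Held-out discipline: the performance score attached to each model — the
input to softmax weighting — comes exclusively from cross-validation folds,
never from rows the fold's model was fit on.  Importances come from the
full-data refit.  All randomness flows from declared seeds, so a fixed
(data, specs, cv seed) triple reproduces the result exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .core import ModelImportance

__all__ = [
    "ModelFamily",
    "Task",
    "ImportanceBackend",
    "ModelSpec",
    "CVConfig",
    "HarnessResult",
    "default_specs",
    "run_harness",
    "permutation_importance",
]


class ModelFamily(Enum):
    LINEAR = "linear"
    DECISION_TREE = "decision_tree"
    RANDOM_FOREST = "random_forest"
    GRADIENT_BOOSTING = "gradient_boosting"
    KERNEL_SVM = "kernel_svm"


class Task(Enum):
    CLASSIFICATION = "classification"
    REGRESSION = "regression"


class ImportanceBackend(Enum):
    COEFFICIENT_MAGNITUDE = "coefficient_magnitude"
    IMPURITY = "impurity"
    PERMUTATION = "permutation"


_TREE_FAMILIES = {
    ModelFamily.DECISION_TREE,
    ModelFamily.RANDOM_FOREST,
    ModelFamily.GRADIENT_BOOSTING,
}


@dataclass(frozen=True)
class ModelSpec:
    """One member of the brute-force ensemble."""

    family: ModelFamily
    task: Task
    importance_backend: ImportanceBackend
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        b, f = self.importance_backend, self.family
        if b is ImportanceBackend.COEFFICIENT_MAGNITUDE and f is not ModelFamily.LINEAR:
            raise ValueError(f"coefficient-magnitude backend is only valid for LINEAR, not {f.name}")
        if b is ImportanceBackend.IMPURITY and f not in _TREE_FAMILIES:
            raise ValueError(f"impurity backend is only valid for tree families, not {f.name}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    @property
    def model_id(self) -> str:
        return self.name or self.family.value


@dataclass(frozen=True)
class CVConfig:
    folds: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass(frozen=True)
class HarnessResult:
    """Per-model importances (with held-out performance) plus run metadata."""

    importances: tuple[ModelImportance, ...]
    cv_config: CVConfig
    performance_metric: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: model_id, feature, importance, metric, performance."""
        rows = []
        for imp in self.importances:
            for feat, val in imp.values.items():
                rows.append(
                    {
                        "model_id": imp.model_id,
                        "feature": feat,
                        "importance": val,
                        "metric": imp.metric,
                        "performance": imp.performance,
                    }
                )
        return pd.DataFrame(rows)


def default_specs(task: Task = Task.CLASSIFICATION, seed: int = 0) -> list[ModelSpec]:
    """The standard five-family diverse suite.

    Linear model with coefficient magnitudes, shallow decision tree /
    random forest / gradient boosting with impurity importance, and an
    RBF-kernel SVM with model-agnostic permutation importance.
    """
    return [
        ModelSpec(ModelFamily.LINEAR, task, ImportanceBackend.COEFFICIENT_MAGNITUDE, seed=seed),
        ModelSpec(
            ModelFamily.DECISION_TREE,
            task,
            ImportanceBackend.IMPURITY,
            {"max_depth": 5},
            seed=seed + 1,
        ),
        ModelSpec(ModelFamily.RANDOM_FOREST, task, ImportanceBackend.IMPURITY, seed=seed + 2),
        ModelSpec(ModelFamily.GRADIENT_BOOSTING, task, ImportanceBackend.IMPURITY, seed=seed + 3),
        ModelSpec(ModelFamily.KERNEL_SVM, task, ImportanceBackend.PERMUTATION, seed=seed + 4),
    ]


def _build_estimator(spec: ModelSpec):
    cls = spec.task is Task.CLASSIFICATION
    hp = dict(spec.hyperparameters)
    if spec.family is ModelFamily.LINEAR:
        if cls:
            est = LogisticRegression(max_iter=2000, random_state=spec.seed, **hp)
        else:
            est = LinearRegression(**hp)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.family is ModelFamily.DECISION_TREE:
        klass = DecisionTreeClassifier if cls else DecisionTreeRegressor
        return klass(random_state=spec.seed, **hp)
    if spec.family is ModelFamily.RANDOM_FOREST:
        klass = RandomForestClassifier if cls else RandomForestRegressor
        return klass(random_state=spec.seed, **hp)
    if spec.family is ModelFamily.GRADIENT_BOOSTING:
        klass = GradientBoostingClassifier if cls else GradientBoostingRegressor
        return klass(random_state=spec.seed, **hp)
    if spec.family is ModelFamily.KERNEL_SVM:
        if cls:
            est = SVC(kernel="rbf", random_state=spec.seed, **hp)
        else:
            est = SVR(kernel="rbf", **hp)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    raise ValueError(f"unknown model family {spec.family!r}")  # pragma: no cover


def _resolve_metric(metric: str | Callable) -> tuple[str, Callable]:
    if callable(metric):
        return getattr(metric, "__name__", "custom"), metric
    if metric == "accuracy":
        return metric, accuracy_score
    if metric == "r2":
        return metric, r2_score
    raise ValueError(f"unsupported metric {metric!r}; use 'accuracy', 'r2' or a callable")


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    metric: str | Callable = "accuracy",
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Mean performance drop when each feature column is shuffled.

    importance(f) = mean over repeats of (baseline metric - metric after
    permuting column f).  The baseline is computed once; every permutation
    draws from one seeded generator.  A feature the model ignores scores
    approximately zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    metric_name, score = _resolve_metric(metric)
    if metric_name == "accuracy" and np.unique(y).size < 2:
        raise ValueError("metric undefined: outcome has a single class")
    baseline = score(y, model.predict(X))
    rng = np.random.default_rng(seed)
    drops = {}
    work = X.copy()
    for col in X.columns:
        original = work[col].to_numpy().copy()
        vals = np.empty(n_repeats)
        for r in range(n_repeats):
            work[col] = rng.permutation(original)
            vals[r] = baseline - score(y, model.predict(work))
        work[col] = original
        drops[col] = vals.mean()
    return pd.Series(drops, name="permutation")


def _extract_importance(spec: ModelSpec, fitted, X, y, perm_repeats: int) -> tuple[str, pd.Series]:
    features = list(X.columns)
    if spec.importance_backend is ImportanceBackend.COEFFICIENT_MAGNITUDE:
        est = fitted.named_steps["model"] if isinstance(fitted, Pipeline) else fitted
        coef = np.atleast_2d(est.coef_)
        vals = np.abs(coef).mean(axis=0)
        return "abs_coefficient", pd.Series(vals, index=features)
    if spec.importance_backend is ImportanceBackend.IMPURITY:
        return "impurity", pd.Series(fitted.feature_importances_, index=features)
    metric = "accuracy" if spec.task is Task.CLASSIFICATION else "r2"
    vals = permutation_importance(
        fitted, X, y, metric=metric, n_repeats=perm_repeats, seed=spec.seed
    )
    return "permutation", vals


def run_harness(
    X: pd.DataFrame,
    y,
    specs: Sequence[ModelSpec] | None = None,
    cv: CVConfig | None = None,
    metric: str | None = None,
    perm_repeats: int = 5,
) -> HarnessResult:
    """Fit every spec, measure held-out performance, extract importances.

    Performance is the mean score over repeated CV folds (accuracy for
    classification, R² for regression unless overridden); importances come
    from a refit on the full dataset.  The dataset must be fully numeric
    with no missing values — imputation and encoding are the caller's job.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y).ravel())
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if X.isna().to_numpy().any() or y.isna().any():
        raise ValueError("missing values in data; impute before running the harness")

    if specs is None:
        is_cls = y.nunique() <= max(10, int(0.05 * len(y))) and np.allclose(y, y.round())
        specs = default_specs(Task.CLASSIFICATION if is_cls else Task.REGRESSION)
    tasks = {s.task for s in specs}
    if len(tasks) != 1:
        raise ValueError("all specs must share one task")
    task = tasks.pop()
    if task is Task.CLASSIFICATION and y.nunique() < 2:
        raise ValueError("degenerate outcome: a single class cannot be modelled")

    ids = [s.model_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model ids in specs: {ids}; set ModelSpec.name")

    cv = cv or CVConfig()
    metric = metric or ("accuracy" if task is Task.CLASSIFICATION else "r2")
    splitter_cls = RepeatedStratifiedKFold if task is Task.CLASSIFICATION else RepeatedKFold
    splitter = splitter_cls(n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)

    importances = []
    for spec in specs:
        est = _build_estimator(spec)
        scores = cross_val_score(clone(est), X, y, scoring=metric, cv=splitter)
        est.fit(X, y)
        metric_name, vals = _extract_importance(spec, est, X, y, perm_repeats)
        importances.append(
            ModelImportance(
                model_id=spec.model_id,
                values=vals.to_dict(),
                metric=metric_name,
                performance=float(scores.mean()),
            )
        )
    return HarnessResult(
        importances=tuple(importances), cv_config=cv, performance_metric=metric
    )
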