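"""Domain types and normalization of heterogeneous per-model importances.

Different model families report feature importance on incompatible scales
(absolute coefficients, impurity decreases, permutation drops, mean |SHAP|).
Before any cross-model aggregation those outputs must be brought onto a
comparable, per-model scale.  Two normalizations are supported:

* **rank transform** — each model's importances become ranks 1..p
  (1 = most important, average ranks for ties); orientation *lower is better*.
* **sum scaling** — each model's importances become relative shares that
  sum to 1; orientation *higher is better*.

Normalization is always column-wise (per model): models with different
importance scales never contaminate each other.  Signed metrics (e.g. linear
coefficients) are reduced to magnitudes before normalization; sign tracking
is deliberately out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "Orientation",
    "Weighting",
    "Normalization",
    "FillPolicy",
    "ModelImportance",
    "RankMatrix",
    "WeightVector",
    "AggregationConfig",
    "rank_transform",
    "sum_scale",
    "build_rank_matrix",
    "softmax_weights",
    "equal_weights",
]


class Orientation(enum.Enum):
    """Direction of a normalized importance scale."""

    RANK_LOW_BEST = "rank_low_best"
    SCORE_HIGH_BEST = "score_high_best"


class Weighting(enum.Enum):
    EQUAL = "equal"
    SOFTMAX_PERFORMANCE = "softmax"


class Normalization(enum.Enum):
    RANK = "rank"
    SUM_SCALE = "sum"


class FillPolicy(enum.Enum):
    """How to fill a (feature, model) cell when the model never reported it.

    WORST: a model that never surfaces a feature is treated as evidence
    against it — rank p (the union feature count) or share 0.
    EXCLUDE: the cell stays empty and aggregation renormalizes model
    weights per feature over the models that did report it.
    """

    WORST = "worst"
    EXCLUDE = "exclude"


@dataclass(frozen=True)
class ModelImportance:
    """One model's raw importance output.

    Parameters
    ----------
    model_id : str
        Unique identifier of the model (or model/explainer pair).
    values : mapping of feature name -> raw importance
        Metric-specific units; signed values are allowed and reduced to
        magnitudes during matrix construction.
    metric : str
        Name of the importance measure, e.g. ``"abs_coefficient"``,
        ``"impurity"``, ``"permutation"``, ``"mean_abs_shap"``.
    performance : float, optional
        Higher-is-better validation score (accuracy, AUC or R²) measured on
        held-out data.  Required only for performance-based weighting.
        Lower-is-better metrics (error rates) must be negated by the caller.
    """

    model_id: str
    values: Mapping[str, float]
    metric: str = "unknown"
    performance: float | None = None

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be a non-empty string")
        if not self.values:
            raise ValueError(f"model {self.model_id!r}: values must be non-empty")
        for feat, val in self.values.items():
            if not math.isfinite(float(val)):
                raise ValueError(
                    f"model {self.model_id!r}: non-finite importance for "
                    f"feature {feat!r} ({val!r})"
                )
        if self.performance is not None and not math.isfinite(float(self.performance)):
            raise ValueError(
                f"model {self.model_id!r}: performance must be finite, "
                f"got {self.performance!r}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def magnitudes(self) -> dict[str, float]:
        """Absolute importance values (signed metrics lose their sign here)."""
        return {f: abs(float(v)) for f, v in self.values.items()}


@dataclass(frozen=True)
class RankMatrix:
    """Features x models grid of normalized importances.

    ``data`` is a DataFrame indexed by feature name with one column per
    model id.  Under ``RANK_LOW_BEST`` each column holds ranks (1 = best);
    under ``SCORE_HIGH_BEST`` each column holds non-negative shares summing
    to 1 over the features the model reported.  Cells a model never reported
    are filled per ``fill_policy`` (NaN under EXCLUDE).

    ``rank_pool_size`` is the size of the candidate-feature pool the ranks
    refer to; it equals the number of rows except for partial views built
    with :meth:`from_ranks` (e.g. a two-feature excerpt of a 20-feature
    ranking, where observed ranks may exceed the row count).
    """

    data: pd.DataFrame
    orientation: Orientation
    fill_policy: FillPolicy = FillPolicy.WORST
    filled: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    rank_pool_size: int | None = None

    def __post_init__(self) -> None:
        if self.data.empty:
            raise ValueError("rank matrix has no features")
        pool = self.rank_pool_size
        if pool is None:
            pool = self.n_features
            if self.orientation is Orientation.RANK_LOW_BEST:
                observed = float(np.nanmax(self.data.to_numpy()))
                pool = max(pool, int(math.ceil(observed)))
            object.__setattr__(self, "rank_pool_size", pool)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def models(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_models(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_ranks(
        cls,
        ranks: Mapping[str, Sequence[float]],
        model_ids: Sequence[str] | None = None,
        rank_pool_size: int | None = None,
    ) -> "RankMatrix":
        """Build a rank-oriented matrix directly from per-feature rank vectors.

        Intended for externally supplied rank tables (possibly a partial view
        of a larger feature pool), so column-permutation invariants are not
        enforced.
        """
        if not ranks:
            raise ValueError("no rank vectors supplied")
        lengths = {len(v) for v in ranks.values()}
        if len(lengths) != 1:
            raise ValueError("all rank vectors must have the same length")
        n_models = lengths.pop()
        if model_ids is None:
            model_ids = [f"m{i + 1}" for i in range(n_models)]
        if len(model_ids) != n_models:
            raise ValueError("model_ids length does not match rank vectors")
        data = pd.DataFrame(
            {m: [float(ranks[f][j]) for f in ranks] for j, m in enumerate(model_ids)},
            index=list(ranks),
        )
        if (data.to_numpy() < 1).any():
            raise ValueError("ranks must be >= 1")
        return cls(
            data=data,
            orientation=Orientation.RANK_LOW_BEST,
            rank_pool_size=rank_pool_size,
        )


@dataclass(frozen=True)
class WeightVector:
    """Per-model aggregation weights aligned with a :class:`RankMatrix`."""

    model_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.model_ids) != len(self.weights):
            raise ValueError("model_ids and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "model_ids", tuple(self.model_ids))
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    def aligned_to(self, model_ids: Sequence[str]) -> np.ndarray:
        """Weights reordered to match ``model_ids``; error on any mismatch."""
        if set(model_ids) != set(self.model_ids):
            raise ValueError(
                "weight vector models do not match matrix models: "
                f"{sorted(self.model_ids)} vs {sorted(model_ids)}"
            )
        lookup = dict(zip(self.model_ids, self.weights))
        return np.array([lookup[m] for m in model_ids], dtype=float)


@dataclass(frozen=True)
class AggregationConfig:
    """Knobs of the aggregation pipeline.

    k : top-k rank threshold for the frequency count (default 10).
    weighting : EQUAL or SOFTMAX_PERFORMANCE model weights.
    normalization : RANK (ranks 1..p, lower best) or SUM_SCALE (shares).
    fc_threshold : minimum fraction of models voting a feature into their
        top-k for joint selection (default 0.5, i.e. at least half).
    wis_quantile : WIS quantile cut for joint selection (default 0.25 =
        top quartile, inclusive nearest-rank boundary).
    softmax_temperature : temperature of the performance softmax; 1 gives
        weights proportional to exp(performance).
    fill_policy : how missing (feature, model) cells are filled.
    """

    k: int = 10
    weighting: Weighting = Weighting.EQUAL
    normalization: Normalization = Normalization.RANK
    fc_threshold: float = 0.5
    wis_quantile: float = 0.25
    softmax_temperature: float = 1.0
    fill_policy: FillPolicy = FillPolicy.WORST

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must be in [0, 1]")
        if not 0.0 < self.wis_quantile <= 1.0:
            raise ValueError("wis_quantile must be in (0, 1]")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weighting": self.weighting.value,
            "normalization": self.normalization.value,
            "fc_threshold": self.fc_threshold,
            "wis_quantile": self.wis_quantile,
            "softmax_temperature": self.softmax_temperature,
            "fill_policy": self.fill_policy.value,
        }


def rank_transform(raw: ModelImportance) -> pd.Series:
    """Ranks 1..p of one model's importances (1 = most important).

    Ties receive the average of the ranks they span, so the result never
    depends on input order.  Signed metrics are ranked by magnitude.
    """
    mags = raw.magnitudes()
    feats = list(mags)
    vals = np.array([mags[f] for f in feats], dtype=float)
    ranks = rankdata(-vals, method="average")
    return pd.Series(ranks, index=feats, name=raw.model_id)


def sum_scale(raw: ModelImportance) -> pd.Series:
    """Relative importance shares of one model's features (sum to 1)."""
    mags = raw.magnitudes()
    feats = list(mags)
    vals = np.array([mags[f] for f in feats], dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError(
            f"model {raw.model_id!r}: all importances are zero — the model is "
            "uninformative and cannot be sum-scaled"
        )
    return pd.Series(vals / total, index=feats, name=raw.model_id)


def build_rank_matrix(
    outputs: Sequence[ModelImportance],
    config: AggregationConfig | None = None,
) -> RankMatrix:
    """Normalize a set of per-model importance outputs onto one grid.

    Features are the union of all reported feature names (first-seen order).
    Each model's column is normalized over the features that model reported;
    absent cells are then filled per ``config.fill_policy``: worst rank
    (= union feature count) or share 0 under WORST, NaN under EXCLUDE.
    """
    config = config or AggregationConfig()
    if len(outputs) < 2:
        raise ValueError(
            "aggregation needs at least 2 models (one model is not an ensemble)"
        )
    ids = [o.model_id for o in outputs]
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise ValueError(f"duplicate model_id(s): {dupes}")

    features: list[str] = []
    seen: set[str] = set()
    for out in outputs:
        for f in out.values:
            if f not in seen:
                seen.add(f)
                features.append(f)
    p = len(features)

    columns: dict[str, pd.Series] = {}
    filled: dict[str, tuple[str, ...]] = {}
    for out in outputs:
        if config.normalization is Normalization.RANK:
            col = rank_transform(out)
            fill_value = float(p)
        else:
            col = sum_scale(out)
            fill_value = 0.0
        if config.fill_policy is FillPolicy.EXCLUDE:
            fill_value = np.nan
        full = col.reindex(features)
        missing = tuple(f for f in features if f not in col.index)
        if missing:
            filled[out.model_id] = missing
            full = full.fillna(fill_value) if not np.isnan(fill_value) else full
        columns[out.model_id] = full

    data = pd.DataFrame(columns, index=features)
    orientation = (
        Orientation.RANK_LOW_BEST
        if config.normalization is Normalization.RANK
        else Orientation.SCORE_HIGH_BEST
    )
    return RankMatrix(
        data=data,
        orientation=orientation,
        fill_policy=config.fill_policy,
        filled=filled,
        rank_pool_size=p,
    )


def softmax_weights(
    performances: Sequence[float] | Mapping[str, float],
    temperature: float = 1.0,
    model_ids: Sequence[str] | None = None,
) -> WeightVector:
    """Model weights proportional to exp(performance / temperature).

    Performances must be finite, on a common higher-is-better scale and
    evaluated on held-out data — weighting by training-set performance
    overweights whichever model overfits hardest.  The softmax is computed
    with the max subtracted, so weights are invariant under adding a
    constant to every performance.  ``temperature=1`` is the plain
    exp-performance softmax.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(performances, Mapping):
        if model_ids is not None:
            raise ValueError("pass model_ids either in the mapping or separately")
        model_ids = list(performances)
        perf = np.array([performances[m] for m in model_ids], dtype=float)
    else:
        perf = np.asarray(list(performances), dtype=float)
        if model_ids is None:
            model_ids = [f"m{i + 1}" for i in range(len(perf))]
    if perf.size == 0:
        raise ValueError("no performances supplied")
    if not np.all(np.isfinite(perf)):
        raise ValueError("performances must be finite")
    z = (perf - perf.max()) / temperature
    w = np.exp(z)
    w /= w.sum()
    return WeightVector(model_ids=tuple(model_ids), weights=tuple(w))


def equal_weights(model_ids: Sequence[str]) -> WeightVector:
    """Uniform weights 1/N — every model's opinion counts equally."""
    n = len(model_ids)
    if n == 0:
        raise ValueError("no model ids supplied")
    return WeightVector(model_ids=tuple(model_ids), weights=tuple([1.0 / n] * n))
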