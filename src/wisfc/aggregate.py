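"""WIS / FC aggregation: consensus scoring, selection, categories, ranking.

For feature f over N models with normalized importances R_j(f) and model
weights w_j (sum 1):

* weighted importance score   WIS(f) = sum_j w_j R_j(f)
  (under rank orientation this is a weighted average rank, lower = better;
  with equal weights it is exactly the mean rank);
* frequency count             FC(f)  = #{j : rank_j(f) <= k},
  FC%(f) = 100 * FC(f) / N — one model, one vote, regardless of w_j;
* composite                   C(f)   = WIS(f) * FC(f) / N, defined only for
  higher-is-better WIS so that inconsistency genuinely penalizes.

WIS measures average strength, FC measures cross-model consistency; a
feature can score well on one and poorly on the other, which is exactly
the signal the four-way interpretation categories encode.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AggregationConfig,
    ModelImportance,
    Normalization,
    Orientation,
    RankMatrix,
    Weighting,
    WeightVector,
    build_rank_matrix,
    equal_weights,
    softmax_weights,
)

__all__ = [
    "Category",
    "WisVector",
    "AggregationResult",
    "weighted_importance_score",
    "frequency_count",
    "composite_score",
    "invert_wis",
    "joint_select",
    "rank_features",
    "categorize",
    "k_sweep",
    "aggregate",
    "aggregate_matrix",
]


class Category(Enum):
    """Interpretation cell of the WIS x FC matrix."""

    ROBUST = "robust"                        # strong and consistent: report with confidence
    MODEL_SPECIFIC = "model_specific"        # strong in few models: investigate further
    CONSISTENT_MODERATE = "consistent_moderate"  # moderate everywhere: follow-up candidate
    LOW_SIGNAL = "low_signal"


@dataclass(frozen=True)
class WisVector:
    """Per-feature WIS values carrying their orientation.

    The orientation travels with the scores so rank-based (lower is better)
    and share-based (higher is better) WIS can never be mixed silently.
    """

    values: pd.Series
    orientation: Orientation

    @property
    def lower_is_better(self) -> bool:
        return self.orientation is Orientation.RANK_LOW_BEST


def weighted_importance_score(matrix: RankMatrix, weights: WeightVector) -> WisVector:
    """WIS(f) = sum_j w_j R_j(f), carrying the matrix orientation forward.

    Under the EXCLUDE fill policy (NaN cells) the weights are renormalized
    per feature over the models that reported it.
    """
    w = weights.aligned_to(matrix.models)
    grid = matrix.data.to_numpy(dtype=float)
    mask = np.isfinite(grid)
    if mask.all():
        wis = grid @ w
    else:
        if not mask.any(axis=1).all():
            bad = [f for f, ok in zip(matrix.features, mask.any(axis=1)) if not ok]
            raise ValueError(f"feature(s) reported by no model: {bad}")
        wsum = mask @ w
        if (wsum <= 0).any():
            raise ValueError(
                "a feature is reported only by zero-weight models; "
                "WIS is undefined under the exclude fill policy"
            )
        wis = np.nansum(grid * w, axis=1) / wsum
    return WisVector(
        values=pd.Series(wis, index=matrix.features, name="wis"),
        orientation=matrix.orientation,
    )


def frequency_count(matrix: RankMatrix, k: int) -> pd.DataFrame:
    """Top-k vote counts per feature: fc_count, fc_fraction, fc_percent.

    A model votes for feature f when its rank of f is <= k; a missing cell
    (EXCLUDE policy) is a non-vote.  Counting is unweighted by design —
    FC is the consistency axis and every model gets one vote.
    """
    if matrix.orientation is not Orientation.RANK_LOW_BEST:
        raise ValueError(
            "frequency_count needs a rank-oriented matrix (lower = better); "
            "rebuild with rank normalization before counting top-k membership"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    n = matrix.n_models
    count = (matrix.data <= k).sum(axis=1).astype(int)
    frac = count / n
    out = pd.DataFrame(
        {"fc_count": count, "fc_fraction": frac, "fc_percent": 100.0 * frac},
        index=matrix.features,
    )
    return out


def composite_score(
    wis: WisVector, fc_count: pd.Series, n_models: int
) -> pd.Series:
    """C(f) = WIS(f) * FC(f) / N for higher-is-better WIS.

    Refuses rank-oriented WIS: multiplying a lower-is-better score by the
    vote fraction would *reward* inconsistency.  Invert first
    (:func:`invert_wis`).
    """
    if wis.orientation is Orientation.RANK_LOW_BEST:
        raise ValueError(
            "composite_score needs higher-is-better WIS; apply invert_wis to "
            "rank-based scores first (orientations are never mixed silently)"
        )
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    fc = fc_count.reindex(wis.values.index)
    return (wis.values * fc / n_models).rename("composite")


def invert_wis(wis: WisVector, p: int) -> WisVector:
    """Map rank-based WIS onto a higher-is-better scale: p + 1 - WIS.

    An order-reversing bijection of [1, p] onto itself: the best possible
    mean rank 1 maps to p, the worst (p) maps to 1.
    """
    if wis.orientation is not Orientation.RANK_LOW_BEST:
        raise ValueError("invert_wis applies to rank-based (lower-is-better) WIS")
    v = wis.values
    if ((v < 1) | (v > p)).any():
        bad = v[(v < 1) | (v > p)]
        raise ValueError(
            f"WIS values outside [1, {p}]: {dict(bad)} — wrong p or wrong scale?"
        )
    return WisVector(values=(p + 1.0 - v).rename("wis"), orientation=Orientation.SCORE_HIGH_BEST)


def _quantile_threshold(values: np.ndarray, q: float, lower_is_better: bool) -> float:
    """Nearest-rank inclusive threshold for 'best q-fraction of values'."""
    v = np.sort(np.asarray(values, dtype=float))
    m = max(1, math.ceil(q * v.size))
    return float(v[m - 1] if lower_is_better else v[v.size - m])


def joint_select(
    wis: WisVector,
    fc_fraction: pd.Series,
    fc_threshold: float = 0.5,
    wis_quantile: float = 0.25,
) -> pd.Series:
    """Joint-criteria robustness flag.

    selected(f) <=> fc_fraction(f) >= fc_threshold AND wis(f) is at or
    better than the wis_quantile quantile over all candidate features
    (nearest-rank, boundary inclusive).  Defaults: at least half the models
    vote for f, and f sits in the top quartile of WIS.
    """
    if wis.values.empty:
        raise ValueError("empty feature set")
    if not 0.0 <= fc_threshold <= 1.0:
        raise ValueError("fc_threshold must be in [0, 1]")
    if not 0.0 < wis_quantile <= 1.0:
        raise ValueError("wis_quantile must be in (0, 1]")
    cut = _quantile_threshold(wis.values.to_numpy(), wis_quantile, wis.lower_is_better)
    good_wis = wis.values <= cut if wis.lower_is_better else wis.values >= cut
    fc = fc_fraction.reindex(wis.values.index)
    return ((fc >= fc_threshold) & good_wis).rename("selected")


def rank_features(wis: WisVector, fc_count: pd.Series) -> pd.Series:
    """Total order 1..p: sort by WIS (best first), tie-break by higher FC,
    final tie-break lexicographic by feature name (determinism guarantee)."""
    df = pd.DataFrame(
        {
            "wis": wis.values,
            "fc": fc_count.reindex(wis.values.index),
            "feature": wis.values.index,
        }
    )
    df = df.sort_values(
        by=["wis", "fc", "feature"],
        ascending=[wis.lower_is_better, False, True],
        kind="mergesort",
    )
    ranks = pd.Series(
        np.arange(1, len(df) + 1, dtype=int), index=df["feature"], name="final_rank"
    )
    return ranks.reindex(wis.values.index)


def categorize(
    wis: WisVector,
    fc_fraction: pd.Series,
    wis_quantile: float = 0.25,
    fc_split: float = 0.5,
) -> pd.Series:
    """Four-way WIS x FC interpretation.

    High WIS (within the best ``wis_quantile`` fraction, nearest-rank
    inclusive) crossed with high FC (fraction >= ``fc_split``):
    high/high = ROBUST, high/low = MODEL_SPECIFIC, low/high =
    CONSISTENT_MODERATE, low/low = LOW_SIGNAL.
    """
    if wis.values.empty:
        raise ValueError("empty feature set")
    cut = _quantile_threshold(wis.values.to_numpy(), wis_quantile, wis.lower_is_better)
    high_wis = wis.values <= cut if wis.lower_is_better else wis.values >= cut
    high_fc = fc_fraction.reindex(wis.values.index) >= fc_split

    def cell(hw: bool, hf: bool) -> Category:
        if hw and hf:
            return Category.ROBUST
        if hw:
            return Category.MODEL_SPECIFIC
        if hf:
            return Category.CONSISTENT_MODERATE
        return Category.LOW_SIGNAL

    return pd.Series(
        [cell(bool(hw), bool(hf)) for hw, hf in zip(high_wis, high_fc)],
        index=wis.values.index,
        name="category",
    )


def k_sweep(matrix: RankMatrix, ks: Sequence[int] = (3, 5, 10, 15)) -> pd.DataFrame:
    """FC fraction per feature across several k values.

    Truly robust features keep high FC across a reasonable range of k;
    features that hover just outside one cutoff do not.
    """
    cols = {f"fc_fraction_k{k}": frequency_count(matrix, k)["fc_fraction"] for k in ks}
    return pd.DataFrame(cols, index=matrix.features)


@dataclass(frozen=True)
class AggregationResult:
    """Per-feature consensus table plus the configuration that produced it.

    ``table`` columns: feature, wis, fc_count, fc_fraction, fc_percent,
    composite, category, final_rank, selected — sorted by final_rank.
    """

    table: pd.DataFrame
    config: AggregationConfig
    orientation: Orientation
    n_models: int
    weights: WeightVector

    def top(self, k: int) -> list[str]:
        """The k features with the best final rank."""
        head = self.table.nsmallest(k, "final_rank")
        return list(head["feature"])

    def config_hash(self) -> str:
        payload = json.dumps(self.config.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None, seed: int | None = None):
        """JSON report with a config echo so any run is reproducible."""
        doc = {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash(),
            "seed": seed,
            "n_models": self.n_models,
            "orientation": self.orientation.value,
            "model_weights": dict(zip(self.weights.model_ids, self.weights.weights)),
            "features": self.table.to_dict(orient="records"),
        }
        if path is None:
            return doc
        Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def aggregate_matrix(
    matrix: RankMatrix,
    weights: WeightVector | None = None,
    config: AggregationConfig | None = None,
    rank_matrix: RankMatrix | None = None,
) -> AggregationResult:
    """Run the full aggregation on an already-normalized matrix.

    A score-oriented (sum-scaled) matrix carries no top-k notion, so FC
    needs a companion rank-oriented matrix built from the same outputs
    (``rank_matrix``); :func:`aggregate` does this automatically.
    """
    config = config or AggregationConfig()
    if weights is None:
        weights = equal_weights(matrix.models)
    wis = weighted_importance_score(matrix, weights)
    fc = frequency_count(rank_matrix if rank_matrix is not None else matrix, config.k)

    if wis.lower_is_better:
        wis_high = invert_wis(wis, int(matrix.rank_pool_size))
    else:
        wis_high = wis
    composite = composite_score(wis_high, fc["fc_count"], matrix.n_models)

    selected = joint_select(wis, fc["fc_fraction"], config.fc_threshold, config.wis_quantile)
    category = categorize(wis, fc["fc_fraction"], config.wis_quantile, config.fc_threshold)
    final_rank = rank_features(wis, fc["fc_count"])

    table = pd.DataFrame(
        {
            "feature": wis.values.index,
            "wis": wis.values.to_numpy(),
            "fc_count": fc["fc_count"].to_numpy(),
            "fc_fraction": fc["fc_fraction"].to_numpy(),
            "fc_percent": fc["fc_percent"].to_numpy(),
            "composite": composite.to_numpy(),
            "category": [c.value for c in category],
            "final_rank": final_rank.to_numpy(),
            "selected": selected.to_numpy(),
        },
        index=wis.values.index,
    ).sort_values("final_rank")
    return AggregationResult(
        table=table.reset_index(drop=True),
        config=config,
        orientation=matrix.orientation,
        n_models=matrix.n_models,
        weights=weights,
    )


def aggregate(
    outputs: Sequence[ModelImportance],
    config: AggregationConfig | None = None,
) -> AggregationResult:
    """Normalize raw per-model importances and aggregate them end to end.

    With ``weighting=SOFTMAX_PERFORMANCE`` every model must carry a
    held-out performance score; with EQUAL weighting, performances are
    ignored and each model gets weight 1/N.
    """
    from dataclasses import replace

    config = config or AggregationConfig()
    matrix = build_rank_matrix(outputs, config)
    rank_companion = None
    if matrix.orientation is not Orientation.RANK_LOW_BEST:
        rank_companion = build_rank_matrix(
            outputs, replace(config, normalization=Normalization.RANK)
        )
    if config.weighting is Weighting.SOFTMAX_PERFORMANCE:
        missing = [o.model_id for o in outputs if o.performance is None]
        if missing:
            raise ValueError(
                f"softmax weighting requires a performance score for every "
                f"model; missing for {missing}"
            )
        weights = softmax_weights(
            {o.model_id: float(o.performance) for o in outputs},
            temperature=config.softmax_temperature,
        )
    else:
        weights = equal_weights(matrix.models)
    return aggregate_matrix(matrix, weights, config, rank_matrix=rank_companion)
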