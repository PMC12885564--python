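"""Reading and writing the interchange formats.

The importance interchange format is a long CSV with header
``model_id,feature,importance,metric,performance`` (UTF-8, '.' decimal
separator).  Long format keeps heterogeneous feature sets per model
representable; the ``performance`` value is repeated on every row of its
model and may be empty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import AggregationConfig, ModelImportance, Normalization, RankMatrix, Weighting

__all__ = [
    "REQUIRED_COLUMNS",
    "read_importance_table",
    "write_importance_table",
    "write_rank_matrix",
    "RunConfig",
]

REQUIRED_COLUMNS = ("model_id", "feature", "importance", "metric")


def read_importance_table(path) -> list[ModelImportance]:
    """Parse a long-format importance CSV into per-model objects.

    Validation errors name the offending row (1-based, counting the
    header as row 1): duplicate (model_id, feature) pairs, non-numeric
    importances and inconsistent per-model performance are all rejected.
    """
    try:
        df = pd.read_csv(path, dtype={"model_id": str, "feature": str, "metric": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "performance" not in df.columns:
        df["performance"] = float("nan")

    dupes = df.duplicated(subset=["model_id", "feature"], keep=False)
    if dupes.any():
        rows = [int(i) + 2 for i in df.index[dupes]]
        pairs = df.loc[dupes, ["model_id", "feature"]].drop_duplicates().to_records(index=False)
        raise ValueError(
            f"{path}: duplicate (model_id, feature) rows {rows}: {list(map(tuple, pairs))}"
        )

    imp = pd.to_numeric(df["importance"], errors="coerce")
    bad = imp.isna() | ~imp.apply(math.isfinite)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]
        raise ValueError(f"{path}: non-numeric or non-finite importance at row(s) {rows}")
    df["importance"] = imp

    outputs: list[ModelImportance] = []
    for model_id in df["model_id"].drop_duplicates():
        sub = df[df["model_id"] == model_id]
        perf_vals = pd.to_numeric(sub["performance"], errors="coerce").dropna().unique()
        if len(perf_vals) > 1:
            raise ValueError(
                f"{path}: model {model_id!r} has inconsistent performance values {perf_vals}"
            )
        metrics = sub["metric"].dropna().unique()
        outputs.append(
            ModelImportance(
                model_id=str(model_id),
                values=dict(zip(sub["feature"], sub["importance"])),
                metric=str(metrics[0]) if len(metrics) else "unknown",
                performance=float(perf_vals[0]) if len(perf_vals) else None,
            )
        )
    return outputs


def write_importance_table(outputs: Sequence[ModelImportance], path) -> None:
    """Write per-model importances back to the long CSV format."""
    rows = [
        {
            "model_id": o.model_id,
            "feature": f,
            "importance": v,
            "metric": o.metric,
            "performance": o.performance,
        }
        for o in outputs
        for f, v in o.values.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_rank_matrix(matrix: RankMatrix, path) -> None:
    """Wide CSV (rows = features, columns = models) + JSON metadata sidecar."""
    path = Path(path)
    matrix.data.rename_axis("feature").to_csv(path)
    meta = {
        "orientation": matrix.orientation.value,
        "fill_policy": matrix.fill_policy.value,
        "rank_pool_size": matrix.rank_pool_size,
        "filled": {m: list(fs) for m, fs in matrix.filled.items()},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    The effective config is echoed into the output directory so any report
    can be reproduced from its artifacts alone.
    """

    input: str | None = None
    dataset: str | None = None
    outcome: str = "y"
    out_dir: str = "wisfc_out"
    seed: int = 0
    log_level: str = "INFO"
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    cv_folds: int = 5
    cv_repeats: int = 1

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "dataset": self.dataset,
            "outcome": self.outcome,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "aggregation": self.aggregation.to_dict(),
            "cv_folds": self.cv_folds,
            "cv_repeats": self.cv_repeats,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        agg = doc.pop("aggregation", {})
        config = AggregationConfig(
            k=agg.get("k", 10),
            weighting=Weighting(agg.get("weighting", "equal")),
            normalization=Normalization(agg.get("normalization", "rank")),
            fc_threshold=agg.get("fc_threshold", 0.5),
            wis_quantile=agg.get("wis_quantile", 0.25),
            softmax_temperature=agg.get("softmax_temperature", 1.0),
        )
        known = {f for f in cls.__dataclass_fields__ if f != "aggregation"}
        return cls(aggregation=config, **{k: v for k, v in doc.items() if k in known})
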