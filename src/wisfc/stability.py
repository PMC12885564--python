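"""Stability of top-k feature selection under resampling.

A selection procedure is stable when the top-k feature set it returns
barely changes across bootstrap resamples of the rows.  The metric here is
the mean pairwise Jaccard index of the B top-k sets; the experiment
compares the consensus (WISFC) selection against every single model's own
top-k, on the identical sequence of resamples.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import aggregate
from .core import AggregationConfig
from .harness import CVConfig, ModelSpec, run_harness

__all__ = ["StabilityReport", "topk_jaccard", "stability_experiment"]


@dataclass(frozen=True)
class StabilityReport:
    """Mean pairwise Jaccard of top-k sets per method, over B resamples."""

    mean_jaccard: dict[str, float]
    sets: dict[str, tuple[frozenset, ...]]
    B: int
    k: int
    scheme: str
    seed: int

    @property
    def consensus_label(self) -> str:
        return "wisfc"

    def single_model_jaccards(self) -> dict[str, float]:
        return {m: j for m, j in self.mean_jaccard.items() if m != self.consensus_label}

    def to_json(self, path: str | Path | None = None):
        doc = {
            "B": self.B,
            "k": self.k,
            "scheme": self.scheme,
            "seed": self.seed,
            "mean_jaccard": self.mean_jaccard,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc

    def to_frame(self) -> pd.DataFrame:
        return (
            pd.DataFrame(
                {"method": list(self.mean_jaccard), "mean_jaccard": list(self.mean_jaccard.values())}
            )
            .sort_values("mean_jaccard", ascending=False)
            .reset_index(drop=True)
        )


def topk_jaccard(sets: Sequence[set | frozenset]) -> float:
    """Mean Jaccard index |A∩B| / |A∪B| over all unordered pairs of sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    for i, s in enumerate(sets):
        if len(s) == 0:
            raise ValueError(f"set {i} is empty; Jaccard stability is undefined")
    vals = [
        len(a & b) / len(a | b) for a, b in itertools.combinations(map(frozenset, sets), 2)
    ]
    return float(np.mean(vals))


def _single_model_topk(imp, k: int) -> frozenset:
    # best-k by raw magnitude; deterministic (magnitude desc, then name)
    ordered = sorted(imp.values, key=lambda f: (-abs(imp.values[f]), f))
    return frozenset(ordered[:k])


def stability_experiment(
    X: pd.DataFrame,
    y,
    specs: Sequence[ModelSpec] | None = None,
    B: int = 20,
    k: int = 5,
    seed: int = 0,
    cv: CVConfig | None = None,
    config: AggregationConfig | None = None,
    perm_repeats: int = 5,
) -> StabilityReport:
    """Compare WISFC top-k stability against each single model's.

    For each of B seeded bootstrap resamples of the rows, the full harness
    runs once; each model's own top-k (by raw importance magnitude) and the
    WISFC consensus top-k (by final rank) are recorded.  All methods see
    the identical resample sequence, so differences in mean pairwise
    Jaccard reflect the selection procedure, not the data draw.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    X = pd.DataFrame(X).reset_index(drop=True)
    y = pd.Series(np.asarray(y).ravel())
    rng = np.random.default_rng(seed)
    config = config or AggregationConfig()
    cv = cv or CVConfig(folds=3, repeats=1, seed=seed)

    sets: dict[str, list[frozenset]] = {}
    for b in range(B):
        idx = rng.integers(0, len(X), size=len(X))
        Xb, yb = X.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True)
        try:
            result = run_harness(Xb, yb, specs=specs, cv=cv, perm_repeats=perm_repeats)
        except Exception as exc:
            raise RuntimeError(f"harness failed on resample {b}: {exc}") from exc
        for imp in result.importances:
            sets.setdefault(imp.model_id, []).append(_single_model_topk(imp, k))
        agg = aggregate(list(result.importances), config)
        sets.setdefault("wisfc", []).append(frozenset(agg.top(k)))

    mean_j = {m: topk_jaccard(s) for m, s in sets.items()}
    return StabilityReport(
        mean_jaccard=mean_j,
        sets={m: tuple(s) for m, s in sets.items()},
        B=B,
        k=k,
        scheme="bootstrap",
        seed=seed,
    )
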