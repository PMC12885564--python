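"""Synthetic tabular cohorts with planted ground truth, plus packaged fixtures.

Stands in for small clinical registry cohorts (a few hundred patients,
~20 candidate predictors, a handful of genuinely informative ones) so that
recovery and stability claims can be tested without restricted data.

Generative family: features are standard Gaussian, optionally in
equicorrelated blocks (pairwise correlation rho within a block); the
outcome is a linear signal ``X @ beta`` plus Gaussian noise (continuous)
or a Bernoulli draw through a logistic link (binary).  Exactly ``s``
features carry nonzero effects of varying size; the rest are pure noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelImportance, RankMatrix

__all__ = [
    "SyntheticDataset",
    "generate_cohort",
    "disagreement_rankings",
    "load_churn_example",
    "load_worked_example",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated cohort plus the ground truth needed for recovery testing."""

    X: pd.DataFrame
    y: pd.Series
    truth: pd.DataFrame  # columns: feature, beta, informative
    correlation_blocks: tuple[tuple[str, ...], ...] | None
    seed: int

    @property
    def informative_features(self) -> list[str]:
        return list(self.truth.loc[self.truth["informative"], "feature"])

    def to_frame(self) -> pd.DataFrame:
        """X and y in one table (outcome column ``y``), ready for CSV."""
        out = self.X.copy()
        out["y"] = self.y
        return out


def generate_cohort(
    n: int = 300,
    p: int = 20,
    s: int = 5,
    beta_range: tuple[float, float] = (0.5, 1.5),
    rho: float = 0.0,
    block_size: int = 5,
    outcome: str = "binary",
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a small cohort with ``s`` informative features out of ``p``.

    The first ``s`` features carry effects with magnitudes spaced linearly
    over ``beta_range`` and alternating signs; the remaining ``p - s`` are
    noise.  With ``rho > 0`` features are grouped into consecutive blocks
    of ``block_size`` with within-block pairwise correlation rho (marginals
    stay standard normal).  Binary outcomes are Bernoulli draws through a
    logistic link; continuous outcomes add N(0, noise_sd²) noise.
    Everything is reproducible from ``seed``.
    """
    if s > p:
        raise ValueError(f"s={s} informative features cannot exceed p={p}")
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0.0 <= rho <= 0.95:
        raise ValueError("rho must be in [0, 0.95]")
    if outcome not in ("binary", "continuous"):
        raise ValueError("outcome must be 'binary' or 'continuous'")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    features = [f"f{i + 1:02d}" for i in range(p)]

    if rho == 0.0:
        X = rng.standard_normal((n, p))
        blocks = None
    else:
        # equicorrelated block: sqrt(rho)*shared + sqrt(1-rho)*own keeps N(0,1) marginals
        X = np.empty((n, p))
        blocks_ix = [list(range(i, min(i + block_size, p))) for i in range(0, p, block_size)]
        for ix in blocks_ix:
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, len(ix)))
            X[:, ix] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        blocks = tuple(tuple(features[j] for j in ix) for ix in blocks_ix)

    beta = np.zeros(p)
    if s > 0:
        mags = np.linspace(beta_range[0], beta_range[1], s)
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(s)])
        beta[:s] = mags * signs

    signal = X @ beta
    if outcome == "binary":
        prob = 1.0 / (1.0 + np.exp(-signal))
        y = rng.binomial(1, prob).astype(int)
    else:
        y = signal + noise_sd * rng.standard_normal(n)

    truth = pd.DataFrame(
        {"feature": features, "beta": beta, "informative": beta != 0.0}
    )
    return SyntheticDataset(
        X=pd.DataFrame(X, columns=features),
        y=pd.Series(y, name="y"),
        truth=truth,
        correlation_blocks=blocks,
        seed=seed,
    )


def disagreement_rankings(
    p: int = 20,
    n_models: int = 5,
    noise_level: float = 0.0,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> list[ModelImportance]:
    """Synthetic per-model rankings that perturb a shared ground-truth order.

    Emulates the explainer-disagreement setting directly: every model sees
    the same underlying importance order (feature i is the (i+1)-th most
    important) but reports it through seeded Gaussian rank noise of scale
    ``noise_level``.  At ``noise_level=0`` all models agree exactly; as the
    noise grows the rankings approach independent uniform permutations.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if feature_names is None:
        feature_names = [f"f{i + 1:02d}" for i in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length must equal p")
    rng = np.random.default_rng(seed)
    base = np.arange(p, 0, -1, dtype=float)  # feature 0 most important
    outputs = []
    for j in range(n_models):
        scores = base + noise_level * rng.standard_normal(p)
        scores = scores - scores.min() + 1.0  # keep magnitudes positive
        outputs.append(
            ModelImportance(
                model_id=f"sim_model_{j + 1}",
                values=dict(zip(feature_names, scores)),
                metric="synthetic_score",
            )
        )
    return outputs


def load_churn_example() -> list[ModelImportance]:
    """Three-model customer-churn importance fixture (synthetic).

    A hand-written reconstruction of a churn walkthrough: logistic
    regression, decision tree and XGBoost rank six predictors (tenure,
    number of products, balance, credit score, age, online usage), agreeing
    on tenure but disagreeing elsewhere — age is prominent only for
    XGBoost.  The per-model values are synthetic, chosen to reproduce that
    qualitative pattern; the performances are plausible AUCs.
    """
    from .io import read_importance_table

    path = importlib.resources.files("wisfc") / "data" / "churn_synthetic.csv"
    return read_importance_table(path)


def load_worked_example() -> RankMatrix:
    """Two-feature, five-model rank matrix fixture.

    Blood pressure is ranked [1, 2, 4, 1, 3] and cholesterol [1, 8, 2, 15, 1]
    by five models drawn from a 20-feature candidate pool — the textbook
    illustration of a consistently-high feature versus a variable one with
    the same naive top-k membership.
    """
    path = importlib.resources.files("wisfc") / "data" / "worked_example_ranks.csv"
    with importlib.resources.as_file(path) as fp:
        df = pd.read_csv(fp)
    ranks = {row["feature"]: row.iloc[1:].astype(float).tolist() for _, row in df.iterrows()}
    return RankMatrix.from_ranks(ranks, model_ids=list(df.columns[1:]), rank_pool_size=20)
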