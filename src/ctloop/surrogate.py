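"""Surrogate regression: registry, cross-validated selection, importance.

Each round the accumulated (scheme, Ct) records are encoded and fed to every
model in a registry of supervised regressors; the winner by mean k-fold CV R²
(ties: lower CV MSE, then registry order) is refit on all data and handed to
the proposer.  The registry is a representative subset of the model families
commonly screened for this task — tree ensembles, nearest-neighbour, kernel
and linear models, plus a constant baseline — and is fully pluggable.

Per-category *weighting factors* are recovered from a fitted surrogate by
permutation sensitivity on a uniform probe of the space: each category's
feature block is jointly permuted across probe rows, and the mean squared
shift of the surrogate's predictions is recorded.  For an additive response
surface this equals twice the category's contribution variance under the
uniform measure, so normalized sensitivities recover planted variance shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import (
    ExtraTreesRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer

from .condition_space import ConditionSpace, Scheme, encode_many, sample_uniform
from .datasets import Dataset

__all__ = [
    "ModelRegistry",
    "default_registry",
    "TrainedSurrogate",
    "WeightingReport",
    "train_and_select",
    "predict_ct",
    "overfitting_monitor",
    "weighting_factors",
]


class ModelRegistry:
    """Ordered name -> estimator-factory mapping; order breaks exact ties."""

    def __init__(self, factories: dict | None = None):
        self._factories: dict[str, callable] = dict(factories or {})

    def register(self, name: str, factory) -> None:
        self._factories[name] = factory

    def names(self) -> list[str]:
        return list(self._factories)

    def make(self, name: str, seed: int):
        return self._factories[name](seed)

    def __len__(self) -> int:
        return len(self._factories)


def make_mlp(seed: int):
    """Shallow MLP factory; available for registration, not in the default set."""
    return MLPRegressor(
        hidden_layer_sizes=(32,), max_iter=400, tol=1e-3, random_state=seed
    )


def default_registry() -> ModelRegistry:
    return ModelRegistry(
        {
            "random_forest": lambda seed: RandomForestRegressor(
                n_estimators=100, random_state=seed, n_jobs=1
            ),
            "extra_trees": lambda seed: ExtraTreesRegressor(
                n_estimators=100, random_state=seed, n_jobs=1
            ),
            "hist_gbrt": lambda seed: HistGradientBoostingRegressor(
                max_iter=100, random_state=seed
            ),
            "knn": lambda seed: KNeighborsRegressor(n_neighbors=5),
            "kernel_ridge": lambda seed: KernelRidge(alpha=0.05, kernel="rbf"),
            # additive model with curvature: ridge on [X, X^2] captures level
            # effects plus smooth quadratic response of scaled numerics, and
            # extrapolates far more gracefully than trees
            "quad_ridge": lambda seed: make_pipeline(
                FunctionTransformer(lambda X: np.hstack([X, X**2])),
                Ridge(alpha=0.01),
            ),
            "ridge": lambda seed: Ridge(alpha=1.0),
            "lasso": lambda seed: Lasso(alpha=0.01, max_iter=5000),
            "baseline_mean": lambda seed: DummyRegressor(strategy="mean"),
        }
    )


@dataclass
class TrainedSurrogate:
    """A fitted winner plus the CV metrics that selected it."""

    model_id: str
    model: object
    space: ConditionSpace
    cv_r2: float
    cv_r2_folds: list[float]
    cv_mse: float
    train_mse: float
    training_round: int = 0
    all_scores: dict[str, dict] = field(default_factory=dict)


def train_and_select(
    dataset: Dataset,
    space: ConditionSpace,
    registry: ModelRegistry | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    training_round: int = 0,
) -> TrainedSurrogate:
    """Fit every registered model with k-fold CV and return the R²-best, refit on all data."""
    if registry is None:
        registry = default_registry()
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if len(dataset) < cv_folds or cv_folds < 2:
        raise ValueError("need |dataset| >= cv_folds >= 2")
    X = encode_many(space, dataset.schemes())
    y = dataset.cts()
    if float(np.var(y)) == 0.0:
        raise ValueError("degenerate labels: zero variance")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    scores: dict[str, dict] = {}
    for name in registry.names():
        fold_r2, fold_mse = [], []
        for tr, te in splits:
            model = registry.make(name, seed)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            fold_r2.append(r2_score(y[te], pred))
            fold_mse.append(mean_squared_error(y[te], pred))
        scores[name] = {
            "cv_r2": float(np.mean(fold_r2)),
            "cv_r2_folds": [float(v) for v in fold_r2],
            "cv_mse": float(np.mean(fold_mse)),
        }
    order = {name: i for i, name in enumerate(registry.names())}
    winner = min(
        scores, key=lambda name: (-scores[name]["cv_r2"], scores[name]["cv_mse"], order[name])
    )
    model = registry.make(winner, seed)
    model.fit(X, y)
    train_mse = float(mean_squared_error(y, model.predict(X)))
    return TrainedSurrogate(
        model_id=winner,
        model=model,
        space=space,
        cv_r2=scores[winner]["cv_r2"],
        cv_r2_folds=scores[winner]["cv_r2_folds"],
        cv_mse=scores[winner]["cv_mse"],
        train_mse=train_mse,
        training_round=training_round,
        all_scores=scores,
    )


def predict_ct(surrogate: TrainedSurrogate, schemes: list[Scheme]) -> np.ndarray:
    """Predict Ct for a batch of schemes; deterministic given the fitted state."""
    X = encode_many(surrogate.space, schemes)
    return np.asarray(surrogate.model.predict(X), dtype=float)


def overfitting_monitor(
    history: list[TrainedSurrogate], ratio_threshold: float = 0.25
) -> dict:
    """Track train/CV error across rounds and flag sustained divergence.

    A train/CV MSE ratio below ``ratio_threshold`` for two consecutive rounds
    flags likely overfitting (training error collapsing while held-out error
    does not follow).
    """
    if not history:
        raise ValueError("history must contain at least one round")
    train_mse = [h.train_mse for h in history]
    cv_mse = [h.cv_mse for h in history]
    cv_r2 = [h.cv_r2 for h in history]
    ratios = [
        (t / c) if c > 0 else 1.0 for t, c in zip(train_mse, cv_mse)
    ]
    low = [r < ratio_threshold for r in ratios]
    flagged_rounds = [
        i + 1 for i in range(1, len(low)) if low[i] and low[i - 1]
    ]
    return {
        "rounds": list(range(1, len(history) + 1)),
        "train_mse": train_mse,
        "cv_mse": cv_mse,
        "cv_r2": cv_r2,
        "ratio": ratios,
        "flag": bool(flagged_rounds),
        "flagged_rounds": flagged_rounds,
    }


@dataclass
class WeightingReport:
    """Normalized per-category importance weights from a fitted surrogate."""

    weights: dict[str, float]
    method: str = "block_permutation"
    probe_n: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"category": list(self.weights), "weight": list(self.weights.values())}
        )


def weighting_factors(
    surrogate: TrainedSurrogate,
    space: ConditionSpace,
    probe_n: int = 2000,
    seed: int = 0,
) -> WeightingReport:
    """Permutation sensitivity of the surrogate per category, on a uniform probe.

    For each category, the probe rows of that category's feature block are
    jointly permuted and the mean squared change of the surrogate's own
    predictions is taken as the category's raw importance; weights are the
    raw importances normalized to sum to 1.
    """
    if probe_n < 500:
        raise ValueError("probe_n must be >= 500")
    probe = sample_uniform(space, probe_n, seed=seed)
    X = encode_many(space, probe)
    base = np.asarray(surrogate.model.predict(X), dtype=float)
    rng = np.random.default_rng([seed, 23])
    raw: dict[str, float] = {}
    for cat, block in space.blocks().items():
        perm = rng.permutation(probe_n)
        Xp = X.copy()
        Xp[:, block] = X[perm, block]
        shifted = np.asarray(surrogate.model.predict(Xp), dtype=float)
        raw[cat] = float(np.mean((shifted - base) ** 2))
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("uninformative surrogate: all permutation importances are zero")
    weights = {cat: v / total for cat, v in raw.items()}
    return WeightingReport(weights=weights, probe_n=probe_n)
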