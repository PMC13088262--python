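"""Post-hoc analysis: replicate consistency, dataset geometry, campaign and
weighting-profile comparison.

* ``consistency_score`` — the platform's replicate-reproducibility metric:
  ``1 - sigma`` where sigma is the sample standard deviation of replicate Ct
  values across batches.  Tight automated batches (sigma ~0.08) score >= 0.9;
  manual-execution variability (sigma ~0.3-0.5) lands in the 0.5-0.7 band.
* ``pca_compactness`` — projects encoded schemes of several datasets onto two
  principal components (for visualization) and scores each dataset's
  compactness as the mean Euclidean distance to its centroid in the *full*
  encoded space, where the number is projection-independent.
* ``compare_campaigns`` — aligns best-so-far trajectories of several
  campaigns (last value carried forward) and summarizes final gaps.
* ``weighting_profile_report`` — places a recovered weighting report next to
  named reference profiles, with per-category absolute differences and a
  Gini sharpness statistic (0 for perfectly uniform weights).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .condition_space import ConditionSpace, encode_many
from .datasets import Dataset
from .loop import CampaignState, best_trajectory
from .surrogate import WeightingReport

__all__ = [
    "consistency_score",
    "pca_compactness",
    "compare_campaigns",
    "gini",
    "weighting_profile_report",
]


def consistency_score(ct_values) -> float:
    """Replicate consistency: 1 minus the sample (n-1) standard deviation.

    Not clamped: wildly scattered replicates legitimately score below 0.
    """
    values = np.asarray(list(ct_values), dtype=float)
    if values.size < 2:
        raise ValueError("consistency score needs >= 2 replicate values")
    if np.ptp(values) == 0.0:  # identical replicates: exactly 1, no float dust
        return 1.0
    return float(1.0 - np.std(values, ddof=1))


def pca_compactness(
    datasets: dict[str, Dataset], space: ConditionSpace
) -> tuple[pd.DataFrame, dict[str, float]]:
    """2-component projection of all datasets plus per-dataset compactness.

    Returns ``(projection, compactness)`` where ``projection`` has columns
    ``dataset_label, pc1, pc2`` and ``compactness`` maps each label to the
    mean distance to the dataset centroid in the full encoded space.
    Component signs follow a fixed convention (largest-|loading| positive),
    so the projection is deterministic.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    encoded = {}
    for label, ds in datasets.items():
        if len(ds) < 3:
            raise ValueError(f"dataset {label!r} has fewer than 3 records")
        encoded[label] = encode_many(space, ds.schemes())
    union = np.vstack(list(encoded.values()))
    if np.allclose(union.var(axis=0), 0.0):
        raise ValueError("all features are constant across the union")
    pca = PCA(n_components=2, random_state=0)
    pca.fit(union)
    # sign convention: the largest-magnitude loading of each component is positive
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    rows = []
    compactness = {}
    for label, X in encoded.items():
        proj = (X - pca.mean_) @ components.T
        for p in proj:
            rows.append({"dataset_label": label, "pc1": float(p[0]), "pc2": float(p[1])})
        centroid = X.mean(axis=0)
        compactness[label] = float(np.mean(np.linalg.norm(X - centroid, axis=1)))
    return pd.DataFrame(rows), compactness


def compare_campaigns(states: dict[str, CampaignState]) -> pd.DataFrame:
    """Align best-so-far trajectories of several campaigns round by round.

    All campaigns must share the same requirement.  Shorter trajectories are
    padded with their last value (a finished campaign's best does not change).
    The final row carries the per-campaign endpoint; gaps are reported
    relative to the best endpoint among the campaigns.
    """
    if not states:
        raise ValueError("no campaigns to compare")
    reqs = {
        (s.requirement.target_ct, s.requirement.conc) for s in states.values()
    }
    if len(reqs) != 1:
        raise ValueError(f"campaigns have mismatched requirements: {sorted(reqs)}")
    trajectories = {label: best_trajectory(s) for label, s in states.items()}
    max_rounds = max(len(t) for t in trajectories.values())
    aligned = {
        label: t + [t[-1]] * (max_rounds - len(t)) for label, t in trajectories.items()
    }
    df = pd.DataFrame(aligned, index=pd.RangeIndex(1, max_rounds + 1, name="round"))
    finals = df.iloc[-1]
    best_final = finals.min()
    df.attrs["final_gap"] = {label: float(finals[label] - best_final) for label in df}
    return df


def gini(weights) -> float:
    """Gini coefficient of a nonnegative weight vector; 0 iff uniform."""
    w = np.sort(np.asarray(list(weights), dtype=float))
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    n = w.size
    total = w.sum()
    if total == 0:
        raise ValueError("weights sum to 0")
    cum = np.cumsum(w)
    return float((n + 1 - 2 * (cum / total).sum()) / n)


def weighting_profile_report(
    report: WeightingReport, references: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Side-by-side comparison of a recovered weighting report with references.

    Each reference profile must be normalized.  The returned frame has one
    row per category with the recovered weight, each reference's weight and
    absolute difference; a ``gini`` row summarizes the sharpness of each
    profile.
    """
    for name, profile in references.items():
        total = sum(profile.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"reference profile {name!r} sums to {total}, expected 1")
    categories = list(report.weights)
    data = {"recovered": [report.weights[c] for c in categories]}
    for name, profile in references.items():
        data[name] = [profile.get(c, 0.0) for c in categories]
        data[f"abs_diff_{name}"] = [
            abs(report.weights[c] - profile.get(c, 0.0)) for c in categories
        ]
    df = pd.DataFrame(data, index=pd.Index(categories, name="category"))
    sharpness = {"recovered": gini(report.weights.values())}
    for name, profile in references.items():
        sharpness[name] = gini(profile.values())
    df.attrs["gini"] = sharpness
    return df
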