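"""Genetic-algorithm batch proposal of candidate schemes.

Each round the proposer searches the condition space for up to ``batch_k``
(default 48) schemes whose surrogate-predicted Ct best fits the requirement —
either closest to a target Ct or simply minimal.  The GA works directly on
schemes: tournament selection, per-category uniform crossover, per-category
mutation (level resampling for categorical axes, clipped Gaussian jitter for
numeric ones), elitism, and optional advisor suggestions injected into the
initial population.  Every scheme scored during the run is kept in an
archive; the returned batch is the fitness-sorted archive filtered for
validity, novelty (never re-proposing an evaluated scheme when dedup is on)
and pairwise categorical diversity.

On an all-categorical space small enough to enumerate, generation zero is
seeded with the full enumeration, so with diversity and dedup disabled the
batch provably equals the exhaustive top-k by fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .condition_space import (
    ConditionSpace,
    Scheme,
    encode,
    enumerate_space,
    sample_uniform,
    validate_scheme,
)
from .datasets import Dataset
from .surrogate import TrainedSurrogate, predict_ct

__all__ = ["GAConfig", "fitness", "propose_batch", "rule_advisor", "SpaceExhaustedError"]


class SpaceExhaustedError(RuntimeError):
    """No unseen scheme is left to propose."""


@dataclass(frozen=True)
class GAConfig:
    batch_k: int = 48
    population: int = 256
    generations: int = 60
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15  # per category
    elitism: int = 8
    tournament: int = 3
    min_diversity: int = 1  # pairwise Hamming distance on categorical assignments
    dedup: bool = True
    fitness_mode: str = "closest"  # or "minimize"
    # sub-grouped exploration: this many of the batch_k slots vary one
    # category at a time around an incumbent scheme (active only when the
    # caller supplies a probe base), categories prioritized by the
    # surrogate's weighting factors
    explore_k: int = 12
    # epsilon exploration: this many slots hold uniformly random unseen
    # schemes, keeping the accumulated store informative across the whole
    # space (honest held-out signal for the overfitting monitor and for
    # post-campaign importance analysis)
    explore_random_k: int = 8

    def __post_init__(self) -> None:
        if self.batch_k < 1:
            raise ValueError("batch_k must be >= 1")
        if self.population < self.batch_k:
            raise ValueError("population must be >= batch_k")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.fitness_mode not in ("closest", "minimize"):
            raise ValueError(f"unknown fitness mode {self.fitness_mode!r}")


def fitness(
    surrogate: TrainedSurrogate,
    scheme: Scheme,
    target_ct: float = 0.0,
    mode: str = "closest",
) -> float:
    """Score one scheme (lower is better): |pred - target| or the raw prediction."""
    pred = float(predict_ct(surrogate, [scheme])[0])
    if mode == "closest":
        return abs(pred - target_ct)
    if mode == "minimize":
        return pred
    raise ValueError(f"unknown fitness mode {mode!r}")


def _categorical_hamming(a: Scheme, b: Scheme, space: ConditionSpace) -> int:
    return sum(
        1
        for cat in space.categories
        if cat.kind == "categorical"
        and a.assignments[cat.name] != b.assignments[cat.name]
    )


def _crossover(a: Scheme, b: Scheme, space: ConditionSpace, rng) -> Scheme:
    assignments = {
        cat.name: (a if rng.random() < 0.5 else b).assignments[cat.name]
        for cat in space.categories
    }
    return Scheme(assignments=assignments)


def _mutate(s: Scheme, space: ConditionSpace, rate: float, rng) -> Scheme:
    assignments = dict(s.assignments)
    for cat in space.categories:
        if rng.random() >= rate:
            continue
        if cat.kind == "categorical":
            assignments[cat.name] = cat.levels[int(rng.integers(len(cat.levels)))]
        else:
            lo, hi = cat.range
            jitter = rng.normal(0.0, 0.1 * (hi - lo))
            assignments[cat.name] = float(np.clip(float(assignments[cat.name]) + jitter, lo, hi))
    return Scheme(assignments=assignments)


def _subgroup_probes(
    space: ConditionSpace,
    base: Scheme,
    category_order: list[str],
    k: int,
    rng,
) -> list[Scheme]:
    """One-condition-at-a-time variations of an incumbent scheme.

    For each category in priority order, every alternative level (or, for a
    numeric category, a small local + coarse value grid) is substituted into
    the base scheme; the first ``k`` variations are returned.
    """
    probes: list[Scheme] = []
    for name in category_order:
        cat = space.category(name)
        base_value = base.assignments[name]
        if cat.kind == "categorical":
            candidates = [lvl for lvl in cat.levels if lvl != base_value]
        else:
            lo, hi = cat.range
            span = hi - lo
            candidates = [
                float(np.clip(v, lo, hi))
                for v in (
                    float(base_value) - 0.04 * span,
                    float(base_value) + 0.04 * span,
                    float(base_value) - 0.12 * span,
                    float(base_value) + 0.12 * span,
                    lo + 0.25 * span,
                    lo + 0.5 * span,
                    lo + 0.75 * span,
                )
                if not np.isclose(v, float(base_value))
            ]
        for value in candidates:
            probes.append(Scheme(assignments={**base.assignments, name: value}))
            if len(probes) >= k:
                return probes
    return probes


def propose_batch(
    surrogate: TrainedSurrogate,
    space: ConditionSpace,
    config: GAConfig,
    evaluated: set[Scheme] | None = None,
    advisor_suggestions: list[Scheme] | None = None,
    target_ct: float = 0.0,
    seed: int = 0,
    probe_base: Scheme | None = None,
) -> list[Scheme]:
    """Propose up to ``batch_k`` unseen, diverse schemes sorted by fitness.

    When ``probe_base`` is given, ``config.explore_k`` of the slots are
    reserved for sub-grouped probes: single-category variations of the base
    scheme, with categories prioritized by the surrogate's weighting
    factors.  The remaining slots are filled by the GA's fitness ranking.
    """
    evaluated = evaluated or set()
    advisor_suggestions = advisor_suggestions or []
    rng = np.random.default_rng([seed, 29])

    def batch_fitness(schemes: list[Scheme]) -> np.ndarray:
        preds = predict_ct(surrogate, schemes)
        if config.fitness_mode == "closest":
            return np.abs(preds - target_ct)
        return preds

    # archive of every scheme scored during the run: scheme -> fitness
    archive: dict[Scheme, float] = {}

    def score(schemes: list[Scheme]) -> None:
        fresh = [s for s in dict.fromkeys(schemes) if s not in archive]
        if fresh:
            for s, f in zip(fresh, batch_fitness(fresh)):
                archive[s] = float(f)

    # generation 0: advisor suggestions, full enumeration when cheap, then random fill
    population: list[Scheme] = [
        s for s in advisor_suggestions if validate_scheme(space, s)
    ]
    all_categorical = all(c.kind == "categorical" for c in space.categories)
    if all_categorical:
        total = math.prod(len(c.levels) for c in space.categories)
        if total <= config.population:
            population.extend(enumerate_space(space, limit=config.population))
    fill = config.population - len(population)
    if fill > 0:
        population.extend(sample_uniform(space, fill, seed=int(rng.integers(2**31 - 1))))
    population = population[: max(config.population, len(population))]
    score(population)

    def sorted_by_fitness(schemes: list[Scheme]) -> list[Scheme]:
        return sorted(
            schemes, key=lambda s: (archive[s], tuple(encode(space, s)))
        )

    for _ in range(config.generations):
        ranked = sorted_by_fitness(population)
        next_pop: list[Scheme] = ranked[: config.elitism]
        while len(next_pop) < config.population:
            contenders = [
                population[int(rng.integers(len(population)))]
                for _ in range(config.tournament)
            ]
            parent_a = min(contenders, key=lambda s: archive[s])
            contenders = [
                population[int(rng.integers(len(population)))]
                for _ in range(config.tournament)
            ]
            parent_b = min(contenders, key=lambda s: archive[s])
            child = (
                _crossover(parent_a, parent_b, space, rng)
                if rng.random() < config.crossover_rate
                else parent_a
            )
            child = _mutate(child, space, config.mutation_rate, rng)
            next_pop.append(child)
        score(next_pop)
        population = next_pop

    # sub-grouped probe slice around the incumbent, most influential first
    probes: list[Scheme] = []
    if probe_base is not None and config.explore_k > 0:
        from .surrogate import weighting_factors

        try:
            weights = weighting_factors(
                surrogate, space, probe_n=500, seed=int(rng.integers(2**31 - 1))
            ).weights
        except ValueError:  # uninformative surrogate: fall back to declared order
            weights = {name: 0.0 for name in space.category_names}
        order = sorted(weights, key=lambda c: -weights[c])
        raw_probes = _subgroup_probes(space, probe_base, order, 4 * config.explore_k, rng)
        score(raw_probes)
        for cand in raw_probes:
            if (config.dedup and cand in evaluated) or cand in probes:
                continue
            probes.append(cand)
            if len(probes) >= config.explore_k:
                break

    # epsilon slice: uniform random unseen schemes (campaign mode only)
    randoms: list[Scheme] = []
    if probe_base is not None and config.explore_random_k > 0:
        pool = sample_uniform(space, 4 * config.explore_random_k, seed=int(rng.integers(2**31 - 1)))
        score(pool)
        for cand in pool:
            if (config.dedup and cand in evaluated) or cand in probes or cand in randoms:
                continue
            randoms.append(cand)
            if len(randoms) >= config.explore_random_k:
                break

    # fill the remaining slots from the archive by fitness, under the
    # novelty and diversity constraints
    candidates = sorted_by_fitness(list(archive))
    chosen: list[Scheme] = list(probes) + randoms
    for cand in candidates:
        if len(chosen) >= config.batch_k:
            break
        if config.dedup and cand in evaluated:
            continue
        if cand in chosen:
            continue
        if config.min_diversity > 0 and any(
            _categorical_hamming(cand, c, space) < config.min_diversity
            for c in chosen[len(probes) :]
        ):
            continue
        chosen.append(cand)
    if not chosen:
        raise SpaceExhaustedError("no unseen scheme satisfies the batch constraints")
    return sorted_by_fitness(chosen)


def rule_advisor(
    space: ConditionSpace,
    dataset: Dataset,
    top_fraction: float = 0.1,
    n_suggestions: int = 4,
    seed: int = 0,
) -> list[Scheme]:
    """Deterministic marginal-recombination advisor (LLM-suggestion stand-in).

    From the ``top_fraction`` lowest-Ct records, the per-category marginal
    mean Ct of each observed level is computed; the first suggestion combines
    every category's best marginal level, and further suggestions resample
    each category among its two best marginals (numerics: jitter around the
    top records' median value).
    """
    if not dataset.records:
        raise ValueError("dataset is empty")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if n_suggestions == 0:
        return []
    k = max(1, math.ceil(top_fraction * len(dataset)))
    top = sorted(dataset.records, key=lambda r: r.ct)[:k]
    rng = np.random.default_rng([seed, 31])

    best_levels: dict[str, list] = {}
    numeric_stats: dict[str, tuple[float, float]] = {}
    for cat in space.categories:
        if cat.kind == "categorical":
            by_level: dict[str, list[float]] = {}
            for r in top:
                by_level.setdefault(r.scheme.assignments[cat.name], []).append(r.ct)
            ranked = sorted(by_level, key=lambda lvl: float(np.mean(by_level[lvl])))
            best_levels[cat.name] = ranked[:2]
        else:
            values = np.array([float(r.scheme.assignments[cat.name]) for r in top])
            numeric_stats[cat.name] = (float(np.median(values)), float(np.std(values)))

    suggestions: list[Scheme] = []
    for i in range(n_suggestions):
        assignments: dict[str, object] = {}
        for cat in space.categories:
            if cat.kind == "categorical":
                ranked = best_levels[cat.name]
                if i == 0 or len(ranked) == 1:
                    assignments[cat.name] = ranked[0]
                else:
                    assignments[cat.name] = ranked[int(rng.integers(len(ranked)))]
            else:
                med, sd = numeric_stats[cat.name]
                lo, hi = cat.range
                value = med if i == 0 else rng.normal(med, max(sd, 1e-9))
                assignments[cat.name] = float(np.clip(value, lo, hi))
        suggestions.append(Scheme(assignments=assignments))
    return suggestions
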