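import numpy as np
import pytest
from sklearn.neighbors import KNeighborsRegressor

from ctloop.condition_space import Scheme, encode, enumerate_space, sample_uniform
from ctloop.datasets import Dataset, ExperimentRecord
from ctloop.oracle import true_ct
from ctloop.proposer import (
    GAConfig,
    SpaceExhaustedError,
    fitness,
    propose_batch,
    rule_advisor,
)
from ctloop.surrogate import ModelRegistry, train_and_select


@pytest.fixture
def oracle_surrogate(tiny_space, tiny_oracle):
    """1-NN surrogate trained on the full enumeration: predicts true Ct exactly."""
    ds = Dataset(space_id=tiny_space.space_id)
    for scheme in enumerate_space(tiny_space):
        ds.append(ExperimentRecord(scheme=scheme, ct=true_ct(tiny_oracle, scheme), conc=1e5))
    registry = ModelRegistry({"knn1": lambda seed: KNeighborsRegressor(n_neighbors=1)})
    return train_and_select(ds, tiny_space, registry, cv_folds=3, seed=0)


class TestFitness:
    def test_closest_is_absolute_distance(self, oracle_surrogate, tiny_oracle):
        assert fitness(
            oracle_surrogate, tiny_oracle.optimum, target_ct=26.5, mode="closest"
        ) == pytest.approx(0.5)

    def test_exact_target_scores_zero(self, oracle_surrogate, tiny_oracle):
        assert fitness(
            oracle_surrogate, tiny_oracle.optimum, target_ct=26.0, mode="closest"
        ) == pytest.approx(0.0)

    def test_minimize_ranking_matches_raw_predictions(
        self, tiny_space, tiny_oracle, oracle_surrogate
    ):
        schemes = enumerate_space(tiny_space)
        by_fitness = sorted(
            schemes, key=lambda s: fitness(oracle_surrogate, s, mode="minimize")
        )
        by_truth = sorted(schemes, key=lambda s: true_ct(tiny_oracle, s))
        assert [true_ct(tiny_oracle, s) for s in by_fitness] == [
            true_ct(tiny_oracle, s) for s in by_truth
        ]


class TestProposeBatch:
    def _config(self, **kw):
        base = dict(
            batch_k=5,
            population=64,
            generations=15,
            min_diversity=0,
            dedup=False,
            fitness_mode="minimize",
            explore_k=0,
            explore_random_k=0,
        )
        base.update(kw)
        return GAConfig(**base)

    def test_equals_brute_force_top_k(self, tiny_space, tiny_oracle, oracle_surrogate):
        proposals = propose_batch(
            oracle_surrogate, tiny_space, self._config(), target_ct=26.0, seed=1
        )
        truth = sorted(
            enumerate_space(tiny_space),
            key=lambda s: (true_ct(tiny_oracle, s), tuple(encode(tiny_space, s))),
        )[:5]
        assert proposals == truth

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_brute_force_equivalence_closest_mode(
        self, tiny_space, tiny_oracle, oracle_surrogate, seed
    ):
        cfg = self._config(fitness_mode="closest")
        proposals = propose_batch(
            oracle_surrogate, tiny_space, cfg, target_ct=27.5, seed=seed
        )
        truth = sorted(
            enumerate_space(tiny_space),
            key=lambda s: (abs(true_ct(tiny_oracle, s) - 27.5), tuple(encode(tiny_space, s))),
        )[:5]
        assert proposals == truth

    def test_k_exceeding_unseen_returns_all_unseen(
        self, tiny_space, tiny_oracle, oracle_surrogate
    ):
        all_schemes = enumerate_space(tiny_space)
        evaluated = set(all_schemes[:24])
        cfg = self._config(batch_k=10, dedup=True)
        proposals = propose_batch(
            oracle_surrogate, tiny_space, cfg, evaluated=evaluated, target_ct=26.0, seed=2
        )
        assert set(proposals) == set(all_schemes) - evaluated

    def test_never_reproposes_evaluated_schemes(self, tiny_space, oracle_surrogate):
        evaluated = set(enumerate_space(tiny_space)[:10])
        cfg = self._config(batch_k=5, dedup=True)
        proposals = propose_batch(
            oracle_surrogate, tiny_space, cfg, evaluated=evaluated, target_ct=26.0, seed=3
        )
        assert not set(proposals) & evaluated

    def test_space_exhausted_raises(self, tiny_space, oracle_surrogate):
        cfg = self._config(batch_k=5, dedup=True)
        with pytest.raises(SpaceExhaustedError):
            propose_batch(
                oracle_surrogate,
                tiny_space,
                cfg,
                evaluated=set(enumerate_space(tiny_space)),
                target_ct=26.0,
                seed=4,
            )

    def test_reproducible_per_seed(self, tiny_space, oracle_surrogate):
        cfg = self._config(batch_k=5)
        a = propose_batch(oracle_surrogate, tiny_space, cfg, target_ct=26.0, seed=7)
        b = propose_batch(oracle_surrogate, tiny_space, cfg, target_ct=26.0, seed=7)
        assert a == b

    def test_min_diversity_enforced_on_categoricals(self, tiny_space, oracle_surrogate):
        cfg = self._config(batch_k=5, min_diversity=2)
        proposals = propose_batch(oracle_surrogate, tiny_space, cfg, target_ct=26.0, seed=5)
        for i, a in enumerate(proposals):
            for b in proposals[i + 1 :]:
                hamming = sum(a.assignments[k] != b.assignments[k] for k in a.assignments)
                assert hamming >= 2

    def test_default_config_proposes_48_on_ample_space(self):
        import ctloop as cl

        space = cl.default_space()
        oracle = cl.default_oracle()
        ds = cl.gen_literature(space, oracle, n=64, seed=1)
        surrogate = cl.train_and_select(ds, space, seed=1)
        proposals = propose_batch(
            surrogate,
            space,
            GAConfig(population=128, generations=10),
            evaluated=set(ds.schemes()),
            target_ct=26.5,
            seed=1,
            probe_base=ds.best().scheme,
        )
        assert len(proposals) == 48
        assert len(set(proposals)) == 48


class TestRuleAdvisor:
    def test_dominant_top_record_scheme_among_suggestions(self, tiny_space, tiny_oracle):
        ds = Dataset(space_id=tiny_space.space_id)
        for scheme in enumerate_space(tiny_space):
            ds.append(
                ExperimentRecord(scheme=scheme, ct=true_ct(tiny_oracle, scheme), conc=1e5)
            )
        suggestions = rule_advisor(tiny_space, ds, top_fraction=0.05, n_suggestions=3, seed=0)
        assert tiny_oracle.optimum in suggestions

    def test_zero_suggestions_gives_empty_list(self, tiny_space, tiny_oracle):
        ds = Dataset(space_id=tiny_space.space_id)
        ds.append(
            ExperimentRecord(scheme=tiny_oracle.optimum, ct=26.0, conc=1e5)
        )
        assert rule_advisor(tiny_space, ds, n_suggestions=0, seed=0) == []

    def test_marginal_recombination_beats_best_observed_on_additive_surface(
        self, tiny_space, tiny_oracle
    ):
        # leave the optimum itself out of the data: marginal recombination of
        # the top records should still assemble a scheme at least as good
        schemes = [s for s in enumerate_space(tiny_space) if s != tiny_oracle.optimum]
        ds = Dataset(space_id=tiny_space.space_id)
        for scheme in schemes:
            ds.append(
                ExperimentRecord(scheme=scheme, ct=true_ct(tiny_oracle, scheme), conc=1e5)
            )
        suggestions = rule_advisor(tiny_space, ds, top_fraction=0.3, n_suggestions=4, seed=1)
        best_observed = min(true_ct(tiny_oracle, s) for s in schemes)
        best_suggested = min(true_ct(tiny_oracle, s) for s in suggestions)
        assert best_suggested <= best_observed

    def test_deterministic_per_seed(self, tiny_space, tiny_oracle):
        ds = Dataset(space_id=tiny_space.space_id)
        for scheme in enumerate_space(tiny_space):
            ds.append(
                ExperimentRecord(scheme=scheme, ct=true_ct(tiny_oracle, scheme), conc=1e5)
            )
        a = rule_advisor(tiny_space, ds, n_suggestions=4, seed=9)
        b = rule_advisor(tiny_space, ds, n_suggestions=4, seed=9)
        assert a == b


def test_ga_config_invariants():
    with pytest.raises(ValueError):
        GAConfig(batch_k=0)
    with pytest.raises(ValueError):
        GAConfig(batch_k=10, population=5)
    with pytest.raises(ValueError):
        GAConfig(crossover_rate=1.5)
    with pytest.raises(ValueError):
        GAConfig(fitness_mode="maximize")
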