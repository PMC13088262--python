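import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctloop.analysis import (
    compare_campaigns,
    consistency_score,
    gini,
    pca_compactness,
    weighting_profile_report,
)
from ctloop.condition_space import Scheme, sample_uniform
from ctloop.datasets import Dataset, ExperimentRecord
from ctloop.defaults import (
    DATA_DRIVEN_WEIGHT_PROFILE,
    UNIFORM_WEIGHT_PROFILE,
    default_oracle,
    default_space,
)
from ctloop.loop import CampaignState, Requirement, RoundLog
from ctloop.surrogate import WeightingReport


class TestConsistencyScore:
    def test_identical_replicates_score_one(self):
        assert consistency_score([26.4, 26.4, 26.4]) == 1.0

    def test_worked_example_scores_exactly_09(self):
        # sample sd of {26.0, 26.1, 26.2} is exactly 0.1
        assert consistency_score([26.0, 26.1, 26.2]) == pytest.approx(0.9, abs=1e-12)

    def test_not_clamped_below_zero(self):
        assert consistency_score([20.0, 30.0]) < 0.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            consistency_score([26.0])

    @settings(derandomize=True, max_examples=30)
    @given(
        values=st.lists(st.floats(20.0, 40.0), min_size=2, max_size=8),
        shift=st.floats(-5.0, 5.0),
    )
    def test_invariant_to_constant_shift(self, values, shift):
        shifted = [v + shift for v in values]
        assert consistency_score(shifted) == pytest.approx(
            consistency_score(values), abs=1e-9
        )

    def test_automated_regime_scores_above_09_in_most_panels(self, tiny_oracle):
        from ctloop.oracle import measure_ct

        scores = [
            consistency_score(
                measure_ct(tiny_oracle, tiny_oracle.optimum, n_rep=5, regime="auto", seed=s)
            )
            for s in range(1000)
        ]
        assert np.mean(np.array(scores) >= 0.9) >= 0.9

    def test_hitl_regime_scores_in_low_band(self, tiny_oracle):
        from ctloop.oracle import measure_ct

        scores = [
            consistency_score(
                measure_ct(tiny_oracle, tiny_oracle.optimum, n_rep=5, regime="hitl", seed=s)
            )
            for s in range(300)
        ]
        assert 0.4 < float(np.median(scores)) < 0.8


def _dataset_of(space, schemes):
    ds = Dataset(space_id=space.space_id)
    for s in schemes:
        ds.append(ExperimentRecord(scheme=s, ct=30.0, conc=1e5))
    return ds


class TestPcaCompactness:
    def test_identical_schemes_have_zero_compactness(self):
        space = default_space()
        fixed = sample_uniform(space, 1, seed=1)[0]
        varied = _dataset_of(space, sample_uniform(space, 30, seed=2))
        constant = _dataset_of(space, [fixed] * 5)
        _, compactness = pca_compactness({"constant": constant, "varied": varied}, space)
        assert compactness["constant"] == pytest.approx(0.0, abs=1e-12)
        assert compactness["varied"] > 0

    def test_cloud_spread_ratio_recovered(self, mixed_space):
        # two numeric clouds with sd 0.1 vs 1.0 in nm units around mid-range
        rng = np.random.default_rng(3)

        def cloud(sd_frac, n=200):
            schemes = []
            for _ in range(n):
                value = float(np.clip(rng.normal(600.0, sd_frac * 800.0), 200, 1000))
                schemes.append(Scheme(assignments={"A": "level1", "B": value}))
            return _dataset_of(mixed_space, schemes)

        _, compactness = pca_compactness(
            {"tight": cloud(0.01), "wide": cloud(0.10)}, mixed_space
        )
        assert compactness["tight"] / compactness["wide"] == pytest.approx(0.1, rel=0.2)

    def test_invariant_to_record_order(self):
        space = default_space()
        schemes = sample_uniform(space, 40, seed=4)
        forward = _dataset_of(space, schemes)
        backward = _dataset_of(space, list(reversed(schemes)))
        proj_f, comp_f = pca_compactness({"d": forward}, space)
        proj_b, comp_b = pca_compactness({"d": backward}, space)
        assert comp_f["d"] == pytest.approx(comp_b["d"])
        assert np.allclose(
            np.sort(proj_f[["pc1", "pc2"]].values, axis=0),
            np.sort(proj_b[["pc1", "pc2"]].values, axis=0),
        )

    def test_constant_union_rejected(self):
        space = default_space()
        fixed = sample_uniform(space, 1, seed=5)[0]
        ds = _dataset_of(space, [fixed] * 5)
        with pytest.raises(ValueError, match="constant"):
            pca_compactness({"a": ds, "b": ds}, space)

    def test_industrial_more_compact_than_literature(self):
        from ctloop.datasets import gen_industrial, gen_literature

        space = default_space()
        oracle = default_oracle()
        ind = gen_industrial(space, oracle, n=96, seed=1)
        lit = gen_literature(space, oracle, n=96, seed=1)
        _, compactness = pca_compactness({"industrial": ind, "literature": lit}, space)
        assert compactness["industrial"] < compactness["literature"]


def _state_with_trajectory(space, values, target=26.5):
    ds = Dataset(space_id=space.space_id)
    ds.append(
        ExperimentRecord(
            scheme=sample_uniform(space, 1, seed=1)[0], ct=values[0], conc=1e5
        )
    )
    logs = [
        RoundLog(
            round=i + 1, model_id="m", cv_r2=0.9, cv_mse=0.1, train_mse=0.05,
            n_proposals=8, best_measured=v, best_so_far=v,
        )
        for i, v in enumerate(values)
    ]
    return CampaignState(
        requirement=Requirement(target_ct=target, conc=1e5, max_rounds=9),
        space=space,
        dataset=ds,
        seed=0,
        logs=logs,
        status="exhausted",
    )


class TestCompareCampaigns:
    def test_self_comparison_has_zero_gap(self):
        space = default_space()
        state = _state_with_trajectory(space, [30.0, 28.0, 27.0])
        table = compare_campaigns({"a": state, "b": state})
        assert table.attrs["final_gap"] == {"a": 0.0, "b": 0.0}

    def test_shorter_trajectory_padded_with_last_value(self):
        space = default_space()
        short = _state_with_trajectory(space, [30.0, 27.0])
        long = _state_with_trajectory(space, [31.0, 29.0, 28.0, 28.0])
        table = compare_campaigns({"short": short, "long": long})
        assert len(table) == 4
        assert list(table["short"]) == [30.0, 27.0, 27.0, 27.0]

    def test_final_gap_is_relative_to_best(self):
        space = default_space()
        a = _state_with_trajectory(space, [30.0, 26.0])
        b = _state_with_trajectory(space, [30.0, 28.5])
        table = compare_campaigns({"a": a, "b": b})
        assert table.attrs["final_gap"]["a"] == 0.0
        assert table.attrs["final_gap"]["b"] == pytest.approx(2.5)

    def test_mismatched_requirements_rejected(self):
        space = default_space()
        a = _state_with_trajectory(space, [30.0], target=26.5)
        b = _state_with_trajectory(space, [30.0], target=28.0)
        with pytest.raises(ValueError, match="requirement"):
            compare_campaigns({"a": a, "b": b})


class TestWeightingProfileReport:
    def test_report_against_itself_has_zero_differences(self):
        report = WeightingReport(weights=dict(DATA_DRIVEN_WEIGHT_PROFILE))
        table = weighting_profile_report(report, {"self": DATA_DRIVEN_WEIGHT_PROFILE})
        assert np.allclose(table["abs_diff_self"], 0.0)

    def test_uniform_profile_has_zero_gini(self):
        assert gini(UNIFORM_WEIGHT_PROFILE.values()) == pytest.approx(0.0, abs=1e-12)

    def test_data_driven_profile_sharper_than_uniform(self):
        report = WeightingReport(weights=dict(DATA_DRIVEN_WEIGHT_PROFILE))
        table = weighting_profile_report(
            report,
            {"data_driven": DATA_DRIVEN_WEIGHT_PROFILE, "uniform": UNIFORM_WEIGHT_PROFILE},
        )
        sharpness = table.attrs["gini"]
        assert sharpness["data_driven"] > sharpness["uniform"]

    def test_unnormalized_reference_rejected(self):
        report = WeightingReport(weights=dict(UNIFORM_WEIGHT_PROFILE))
        with pytest.raises(ValueError, match="sums to"):
            weighting_profile_report(report, {"bad": {"particle_size": 0.5}})

    def test_gini_zero_iff_uniform(self):
        assert gini([0.25, 0.25, 0.25, 0.25]) == 0.0
        assert gini([0.7, 0.1, 0.1, 0.1]) > 0.0
        with pytest.raises(ValueError):
            gini([-0.1, 1.1])
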