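"""Recover per-category weighting factors from a finished campaign.

The oracle's per-category variance shares are first calibrated to the
data-driven importance profile (particle size 0.357, functional group 0.264,
molecular crowding 0.151, salting out 0.125); a campaign is run to the
efficiency-grade target, a surrogate is trained on all accumulated data, and
block-permutation sensitivity on a uniform probe recovers the weights.
"""

import ctloop as cl

space = cl.default_space()
oracle = cl.calibrate_variance_shares(
    cl.default_oracle(), cl.DATA_DRIVEN_WEIGHT_PROFILE, mc_n=20_000, seed=7
)

requirement = cl.Requirement(target_ct=26.0, conc=1e5, max_rounds=9)
initial = cl.gen_industrial(space, oracle, n=192, seed=1)
state = cl.run_campaign(
    requirement, space, initial, oracle, advisor=cl.rule_advisor, seed=1
)
print(f"campaign: {state.status} after {state.rounds_run} rounds, "
      f"{len(state.dataset)} records accumulated")

surrogate = cl.train_and_select(state.dataset, space, seed=1)
print(f"selected surrogate: {surrogate.model_id} (CV R2 {surrogate.cv_r2:.4f})")

report = cl.weighting_factors(surrogate, space, probe_n=2000, seed=1)
table = cl.weighting_profile_report(
    report,
    {"planted": cl.DATA_DRIVEN_WEIGHT_PROFILE, "uniform": cl.UNIFORM_WEIGHT_PROFILE},
)
print(table.round(3).to_string())
print("sharpness (Gini):", {k: round(v, 3) for k, v in table.attrs["gini"].items()})
# The recovered column should match the planted profile within a few
# hundredths; the Gini coefficient shows the recovered profile is as
# sharply concentrated as the planted one (a uniform profile scores 0).
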