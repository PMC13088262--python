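"""Benchmark-oracle quality-control views: replicate consistency, dilution
linearity and the Ct-to-efficiency conversion.
"""

import numpy as np

import ctloop as cl

oracle = cl.default_oracle()
scheme = oracle.optimum

# Replicate consistency: automated platform vs human-in-the-loop noise.
for regime in ("auto", "hitl"):
    reps = cl.measure_ct(oracle, scheme, n_rep=5, regime=regime, seed=2)
    print(
        f"{regime:>4}: replicates {np.round(reps, 2)} -> "
        f"consistency score {cl.consistency_score(reps):.3f}"
    )

# Dilution series: mean Ct vs log10 concentration should be linear with
# slope -log2(10) = -3.32 (one extra cycle per halving of template).
panel = cl.dilution_panel(oracle, scheme, concs=[1e5, 1e4, 1e3, 1e2], n_rep=3, seed=2)
print("\ndilution panel:")
print(panel.round(3).to_string(index=False))
slope = np.polyfit(np.log10(panel["conc_copies_per_ml"]), panel["mean_ct"], 1)[0]
print(f"fitted slope: {slope:.3f} Ct per decade")

# Efficiency: a measured Ct within a hundredth of the no-loss reference
# corresponds to essentially complete recovery (>99%).
for ct in (26.0, 27.0, 29.0):
    eff = cl.efficiency_from_ct(ct, ct_ref=25.99, base=2.0)
    print(f"Ct {ct:.2f} -> extraction efficiency {100 * eff:.1f}%")
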