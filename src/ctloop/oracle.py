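"""Synthetic ground-truth Ct response surface.

The closed loop needs something to optimize against.  In the real platform a
proposed formulation is synthesized, used to extract viral nucleic acid, and
scored by the qPCR cycle threshold (Ct) of the eluate — lower Ct means more
template recovered.  Here that whole wet path is replaced by a calibrated
response surface:

    true_ct(scheme) = ct_opt + sum of per-category penalties
                             + sum of pairwise interaction penalties

All penalties are >= 0 and vanish at the planted optimum, so the global
minimum is exactly ``ct_opt`` at ``optimum``.  Measurement adds the standard
qPCR concentration term ``slope * log10(ref_conc / conc)`` (one extra cycle
per halving of template at slope = log2(10)) and Gaussian replicate noise in
one of two regimes: ``auto`` (automated platform, tight) or ``hitl``
(human-in-the-loop, loose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .condition_space import ConditionSpace, Scheme, SchemeError, validate_scheme

__all__ = [
    "Interaction",
    "CoherenceTerm",
    "NumericPenalty",
    "OracleParams",
    "true_ct",
    "measure_ct",
    "variance_shares_mc",
    "calibrate_variance_shares",
    "efficiency_from_ct",
    "dilution_panel",
]

LOG2_10 = math.log2(10.0)  # Ct per decade at perfect doubling efficiency


@dataclass(frozen=True)
class Interaction:
    """Extra penalty when two specific categorical levels co-occur."""

    category_a: str
    level_a: str
    category_b: str
    level_b: str
    penalty: float

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("interaction penalty must be >= 0")


@dataclass(frozen=True)
class CoherenceTerm:
    """Penalty applied only when a scheme matches a full joint configuration.

    Unlike pairwise interactions, this term is invisible to marginal and
    pairwise statistics away from the exact configuration — it models
    all-or-nothing chemistry effects such as an internally consistent but
    inferior reagent family.
    """

    assignments: dict  # category -> level; all must match
    penalty: float

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("coherence penalty must be >= 0")
        if not self.assignments:
            raise ValueError("coherence term needs at least one assignment")

    def active(self, scheme) -> bool:
        return all(scheme.assignments.get(c) == l for c, l in self.assignments.items())


@dataclass(frozen=True)
class NumericPenalty:
    """Convex quadratic penalty for a numeric category.

    ``amplitude * ((x - optimum) / half_width)**2`` — zero at the optimal
    value, ``amplitude`` Ct at a deviation of ``half_width``.
    """

    optimum: float
    half_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("penalty amplitude must be >= 0")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")

    def __call__(self, x: float) -> float:
        return self.amplitude * ((x - self.optimum) / self.half_width) ** 2


@dataclass
class OracleParams:
    """Full parameterization of the synthetic benchmark surface."""

    space: ConditionSpace
    optimum: Scheme
    ct_opt: float = 26.0
    # categorical: {category: {level: penalty}}, 0 at the optimal level
    level_penalties: dict[str, dict[str, float]] = field(default_factory=dict)
    # numeric: {category: NumericPenalty}
    numeric_penalties: dict[str, NumericPenalty] = field(default_factory=dict)
    interactions: tuple[Interaction, ...] = ()
    coherence_terms: tuple[CoherenceTerm, ...] = ()
    noise_sigma_auto: float = 0.065
    noise_sigma_hitl: float = 0.40
    ref_conc: float = 1e5  # copies/mL at which true_ct is defined
    slope: float = LOG2_10  # Ct per log10(concentration)

    def __post_init__(self) -> None:
        if self.noise_sigma_auto < 0 or self.noise_sigma_hitl < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.ref_conc <= 0:
            raise ValueError("ref_conc must be > 0")
        res = validate_scheme(self.space, self.optimum)
        if not res:
            raise SchemeError("optimum scheme invalid: " + "; ".join(res.problems))
        for cat, table in self.level_penalties.items():
            if any(p < 0 for p in table.values()):
                raise ValueError(f"negative level penalty in category {cat!r}")
            opt_level = self.optimum.assignments[cat]
            if table.get(opt_level, 0.0) != 0.0:
                raise ValueError(f"penalty at optimal level of {cat!r} must be 0")

    def category_contribution(self, scheme: Scheme, category: str) -> float:
        """Penalty contributed by one category for this scheme."""
        value = scheme.assignments[category]
        if category in self.level_penalties:
            return self.level_penalties[category].get(value, 0.0)
        if category in self.numeric_penalties:
            return self.numeric_penalties[category](float(value))
        return 0.0

    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "optimum": dict(self.optimum.assignments),
            "ct_opt": self.ct_opt,
            "level_penalties": {c: dict(t) for c, t in self.level_penalties.items()},
            "numeric_penalties": {
                c: {"optimum": p.optimum, "half_width": p.half_width, "amplitude": p.amplitude}
                for c, p in self.numeric_penalties.items()
            },
            "interactions": [
                [i.category_a, i.level_a, i.category_b, i.level_b, i.penalty]
                for i in self.interactions
            ],
            "coherence_terms": [
                [dict(t.assignments), t.penalty] for t in self.coherence_terms
            ],
            "noise_sigma_auto": self.noise_sigma_auto,
            "noise_sigma_hitl": self.noise_sigma_hitl,
            "ref_conc": self.ref_conc,
            "slope": self.slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OracleParams":
        space = ConditionSpace.from_dict(d["space"])
        return cls(
            space=space,
            optimum=Scheme(assignments=dict(d["optimum"])),
            ct_opt=d["ct_opt"],
            level_penalties={c: dict(t) for c, t in d["level_penalties"].items()},
            numeric_penalties={
                c: NumericPenalty(**p) for c, p in d["numeric_penalties"].items()
            },
            interactions=tuple(Interaction(*i) for i in d["interactions"]),
            coherence_terms=tuple(
                CoherenceTerm(assignments=dict(a), penalty=p)
                for a, p in d.get("coherence_terms", [])
            ),
            noise_sigma_auto=d["noise_sigma_auto"],
            noise_sigma_hitl=d["noise_sigma_hitl"],
            ref_conc=d["ref_conc"],
            slope=d["slope"],
        )


def true_ct(params: OracleParams, scheme: Scheme) -> float:
    """Noise-free Ct of a scheme at the reference concentration."""
    res = validate_scheme(params.space, scheme)
    if not res:
        raise SchemeError("; ".join(res.problems))
    ct = params.ct_opt
    for cat in params.space.category_names:
        ct += params.category_contribution(scheme, cat)
    for inter in params.interactions:
        if (
            scheme.assignments.get(inter.category_a) == inter.level_a
            and scheme.assignments.get(inter.category_b) == inter.level_b
        ):
            ct += inter.penalty
    for term in params.coherence_terms:
        if term.active(scheme):
            ct += term.penalty
    return ct


def _sigma(params: OracleParams, regime: str) -> float:
    if regime == "auto":
        return params.noise_sigma_auto
    if regime == "hitl":
        return params.noise_sigma_hitl
    raise ValueError(f"unknown noise regime {regime!r}")


def measure_ct(
    params: OracleParams,
    scheme: Scheme,
    conc: float = None,
    n_rep: int = 1,
    regime: str = "auto",
    seed: int = 0,
) -> np.ndarray:
    """Simulate ``n_rep`` replicate Ct measurements of a scheme.

    Each replicate is ``true_ct + slope * log10(ref_conc / conc) + N(0, sigma)``
    with sigma set by the noise regime.  Reproducible per seed.
    """
    if conc is None:
        conc = params.ref_conc
    if conc <= 0:
        raise ValueError("concentration must be > 0 copies/mL")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    base = true_ct(params, scheme) + params.slope * math.log10(params.ref_conc / conc)
    rng = np.random.default_rng(seed)
    sigma = _sigma(params, regime)
    return base + rng.normal(0.0, sigma, size=n_rep) if sigma > 0 else np.full(n_rep, base)


def variance_shares_mc(
    params: OracleParams, mc_n: int = 20_000, seed: int = 0
) -> dict[str, float]:
    """Monte-Carlo estimate of each category's share of total effect variance.

    Shares are Var(category contribution) under uniform scheme sampling,
    normalized over categories; interactions are excluded from the shares
    (they are a deliberate non-additive perturbation, not a main effect).
    """
    from .condition_space import sample_uniform

    schemes = sample_uniform(params.space, mc_n, seed)
    contribs = {
        cat: np.array([params.category_contribution(s, cat) for s in schemes])
        for cat in params.space.category_names
    }
    variances = {cat: float(np.var(v)) for cat, v in contribs.items()}
    total = sum(variances.values())
    if total == 0:
        raise ValueError("oracle has no effect variance")
    return {cat: v / total for cat, v in variances.items()}


def calibrate_variance_shares(
    params: OracleParams,
    target_shares: dict[str, float],
    mc_n: int = 20_000,
    seed: int = 0,
    zero_interactions: bool = True,
    tol: float = 0.02,
) -> OracleParams:
    """Rescale per-category penalty magnitudes to plant a variance profile.

    Because each category's contribution scales linearly with a common factor,
    its variance scales with the square; solving ``c_i = sqrt(t_i / V_i)``
    (then renormalizing so total variance is preserved) matches the target
    shares exactly in the Monte-Carlo estimate.  The optimum's location is
    unchanged (zero penalties stay zero).  Verified to ``tol`` before return.
    """
    if mc_n < 1000:
        raise ValueError("mc_n must be >= 1000")
    total_t = sum(target_shares.values())
    if not math.isclose(total_t, 1.0, abs_tol=1e-9):
        raise ValueError(f"target shares sum to {total_t}, expected 1")
    current = variance_shares_mc(params, mc_n=mc_n, seed=seed)
    # raw variances, pre-normalization
    from .condition_space import sample_uniform

    schemes = sample_uniform(params.space, mc_n, seed)
    raw_var = {
        cat: float(
            np.var([params.category_contribution(s, cat) for s in schemes])
        )
        for cat in params.space.category_names
    }
    total_var = sum(raw_var.values())
    factors: dict[str, float] = {}
    for cat in params.space.category_names:
        t = target_shares.get(cat, 0.0)
        if t > 0 and raw_var[cat] == 0.0:
            raise ValueError(
                f"target share {t} for category {cat!r} with all-zero penalties"
            )
        factors[cat] = math.sqrt(t * total_var / raw_var[cat]) if raw_var[cat] > 0 else 0.0

    new_level = {
        cat: {lvl: p * factors.get(cat, 0.0) for lvl, p in table.items()}
        for cat, table in params.level_penalties.items()
    }
    new_numeric = {
        cat: NumericPenalty(p.optimum, p.half_width, p.amplitude * factors.get(cat, 0.0))
        for cat, p in params.numeric_penalties.items()
    }
    new_params = OracleParams(
        space=params.space,
        optimum=params.optimum,
        ct_opt=params.ct_opt,
        level_penalties=new_level,
        numeric_penalties=new_numeric,
        interactions=() if zero_interactions else params.interactions,
        coherence_terms=() if zero_interactions else params.coherence_terms,
        noise_sigma_auto=params.noise_sigma_auto,
        noise_sigma_hitl=params.noise_sigma_hitl,
        ref_conc=params.ref_conc,
        slope=params.slope,
    )
    achieved = variance_shares_mc(new_params, mc_n=mc_n, seed=seed + 1)
    for cat, t in target_shares.items():
        if abs(achieved.get(cat, 0.0) - t) > tol:
            raise RuntimeError(
                f"calibration failed for {cat!r}: achieved "
                f"{achieved.get(cat, 0.0):.4f}, target {t:.4f} (current was "
                f"{current.get(cat, 0.0):.4f})"
            )
    return new_params


def efficiency_from_ct(ct: float, ct_ref: float, base: float = 2.0) -> float:
    """Convert a measured Ct to an extraction-efficiency fraction.

    Under ideal amplification each cycle multiplies template by ``base``, so a
    Ct exceeding the no-loss reference ``ct_ref`` by d cycles corresponds to a
    recovered fraction ``base**(-d)``, capped at 1.
    """
    if base <= 1:
        raise ValueError("base must be > 1")
    return min(1.0, base ** (-(ct - ct_ref)))


def dilution_panel(
    params: OracleParams,
    scheme: Scheme,
    concs: list[float],
    n_rep: int = 3,
    regime: str = "auto",
    seed: int = 0,
):
    """Simulate a dilution series; returns a DataFrame ordered by descending conc.

    Columns: ``conc_copies_per_ml, mean_ct, sd_ct, n_rep``.  On a noise-free
    panel, regressing mean Ct on log10(conc) recovers ``-slope`` exactly.
    """
    import pandas as pd

    if len(concs) == 0:
        raise ValueError("concs must be non-empty")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be > 0")
    rows = []
    for i, conc in enumerate(sorted(concs, reverse=True)):
        reps = measure_ct(params, scheme, conc=conc, n_rep=n_rep, regime=regime, seed=seed + i)
        rows.append(
            {
                "conc_copies_per_ml": conc,
                "mean_ct": float(np.mean(reps)),
                "sd_ct": float(np.std(reps, ddof=1)) if n_rep > 1 else 0.0,
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)
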