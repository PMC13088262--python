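"""Default study conditions: the 10-category formulation space and the
calibrated benchmark oracle.

The space covers the standard axes of a magnetic-nanoparticle (MNP)
nucleic-acid extraction formulation: the particle itself (size, surface
functional group), the lysis/binding chemistry (chaotrope, salting-out
reagent, molecular-crowding agent, surfactant, binding alcohol, buffer) and
the downstream wash/elution steps.  Particle size is the single numeric axis
(200–1000 nm, the window accessible to batch silica coating); every other
category is categorical with 3–5 named sub-conditions.

The default oracle plants its optimum at Ct 26.0 at 1e5 copies/mL.  Penalty
magnitudes are calibrated so that (a) the particle size and functional group
carry the largest main effects, mirroring the data-driven importance profile
the loop is expected to recover, (b) the runner-up level in every category
costs more than 0.5 Ct, so that the standard requirement "Ct below 26.5"
is only met by an essentially optimal scheme, and (c) a compact
industrial-style starting cloud can be placed with its best label near
Ct 35.5 (see :mod:`ctloop.datasets`).
"""

from __future__ import annotations

from .condition_space import ConditionCategory, ConditionSpace, Scheme
from .oracle import CoherenceTerm, Interaction, NumericPenalty, OracleParams

__all__ = [
    "default_space",
    "default_optimum",
    "default_oracle",
    "TUNED_CATEGORIES",
    "PLATFORM_CATEGORIES",
    "DATA_DRIVEN_WEIGHT_PROFILE",
    "UNIFORM_WEIGHT_PROFILE",
]

# The four particle/lysis axes that carry the large main effects and that a
# campaign actually tunes, vs the six reagent-matching axes whose joint
# setting is the platform chemistry a manufacturer has already worked out.
TUNED_CATEGORIES = (
    "particle_size",
    "functional_group",
    "molecular_crowding",
    "salting_out",
)
PLATFORM_CATEGORIES = (
    "surfactant",
    "chaotrope",
    "binding_alcohol",
    "buffer",
    "wash_composition",
    "elution_condition",
)


def default_space() -> ConditionSpace:
    """The default 10-category mixed parameter space."""
    return ConditionSpace(
        space_id="mnp-extraction-v1",
        categories=(
            ConditionCategory("particle_size", "numeric", range=(200.0, 1000.0), units="nm"),
            ConditionCategory(
                "functional_group",
                "categorical",
                levels=("mono_carboxyl", "di_carboxyl", "poly_carboxyl"),
            ),
            ConditionCategory(
                "molecular_crowding",
                "categorical",
                levels=("none", "peg2000", "peg4000", "peg8000", "ficoll70"),
            ),
            ConditionCategory(
                "salting_out",
                "categorical",
                levels=("nacl", "kcl", "ammonium_sulfate", "sodium_citrate"),
            ),
            ConditionCategory(
                "surfactant",
                "categorical",
                levels=("triton_x100", "tween20", "np40", "sds", "brij35"),
            ),
            ConditionCategory(
                "chaotrope",
                "categorical",
                levels=("gitc", "guanidine_hcl", "urea", "betaine", "none"),
            ),
            ConditionCategory(
                "binding_alcohol",
                "categorical",
                levels=("isopropanol", "ethanol", "peg_alcohol_mix", "butanol", "none"),
            ),
            ConditionCategory(
                "buffer",
                "categorical",
                levels=("tris_hcl", "hepes", "mops", "phosphate", "citrate"),
            ),
            ConditionCategory(
                "wash_composition",
                "categorical",
                levels=("ethanol_80", "ethanol_70", "salt_ethanol", "isopropanol_wash", "acetone_wash"),
            ),
            ConditionCategory(
                "elution_condition",
                "categorical",
                levels=("water_60c", "tris_ph8", "te_buffer", "water_45c", "water_rt"),
            ),
        ),
    )


def default_optimum() -> Scheme:
    """The planted optimal formulation of the default oracle."""
    return Scheme(
        assignments={
            "particle_size": 600.0,
            "functional_group": "poly_carboxyl",
            "molecular_crowding": "peg2000",
            "salting_out": "ammonium_sulfate",
            "surfactant": "triton_x100",
            "chaotrope": "gitc",
            "binding_alcohol": "isopropanol",
            "buffer": "tris_hcl",
            "wash_composition": "ethanol_80",
            "elution_condition": "water_60c",
        }
    )


def _joint_chemistry_interactions(
    space: ConditionSpace, mismatch_penalty: float
) -> tuple[Interaction, ...]:
    """Pairwise compatibility penalties among the platform categories.

    The platform categories all have the same number of levels, and their
    level *indices* define compatibility families (family 0 is the gentle
    Triton/GITC/isopropanol chemistry, family 3 the harsh one): a pair of
    platform settings from different families incurs ``mismatch_penalty``,
    matched settings incur none, regardless of family.  Under uniform
    sampling every level of a platform category therefore has an identical
    expected penalty — marginal statistics carry no information about which
    chemistry is right, and search is driven only toward internal coherence,
    with the family itself decided by whatever a campaign's early data
    happened to favor.
    """
    interactions: list[Interaction] = []
    cats = [space.category(name) for name in PLATFORM_CATEGORIES]
    if len({len(c.levels) for c in cats}) != 1:
        raise ValueError("platform categories must share one level count")
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            for ia, la in enumerate(a.levels):
                for ib, lb in enumerate(b.levels):
                    if ia != ib:
                        interactions.append(
                            Interaction(a.name, la, b.name, lb, mismatch_penalty)
                        )
    return tuple(interactions)


def _decoy_family_terms(
    space: ConditionSpace, decoy_costs: tuple[float, ...]
) -> tuple[CoherenceTerm, ...]:
    """All-or-nothing costs of the internally consistent decoy chemistries.

    A formulation whose six platform categories are *all* aligned on family
    i > 0 incurs ``decoy_costs[i]`` on top of the mismatch-free baseline.
    One step away from full coherence the cost vanishes (but five mismatch
    penalties appear instead), so the decoy families are genuine local
    optima: internally coherent, 1.0-1.2 Ct worse than the true chemistry,
    and leaving one requires changing all six reagents at once.  Away from
    full coherence the families are statistically indistinguishable, so
    which one a campaign aligns on is decided by its early data.
    """
    terms = []
    for fam, cost in enumerate(decoy_costs):
        if cost <= 0:
            continue
        assignments = {
            name: space.category(name).levels[fam] for name in PLATFORM_CATEGORIES
        }
        terms.append(CoherenceTerm(assignments=assignments, penalty=cost))
    return tuple(terms)


def default_oracle(
    joint_penalty: float = 0.22,
    decoy_costs: tuple[float, ...] = (0.0, 1.0, 1.05, 1.1, 1.15),
) -> OracleParams:
    """The calibrated default benchmark surface (optimum Ct 26.0).

    Main effects are concentrated on the four tuned categories (particle
    size carrying the largest variance, then functional group, molecular
    crowding and salting out); the six platform categories contribute small
    main effects plus the joint-chemistry ridge of
    :func:`_joint_chemistry_interactions` and the decoy-family costs of
    :func:`_decoy_family_terms`.
    """
    space = default_space()
    optimum = default_optimum()
    return OracleParams(
        space=space,
        optimum=optimum,
        ct_opt=26.0,
        numeric_penalties={
            # 6 Ct at the range edges; < 0.5 Ct within ~105 nm of the optimum
            "particle_size": NumericPenalty(optimum=600.0, half_width=400.0, amplitude=6.0),
        },
        level_penalties={
            "functional_group": {"poly_carboxyl": 0.0, "di_carboxyl": 2.4, "mono_carboxyl": 4.0},
            "molecular_crowding": {
                "peg2000": 0.0,
                "peg4000": 1.2,
                "peg8000": 2.2,
                "ficoll70": 3.0,
                "none": 3.8,
            },
            "salting_out": {
                "ammonium_sulfate": 0.0,
                "sodium_citrate": 1.1,
                "nacl": 2.0,
                "kcl": 2.8,
            },
            # platform categories: almost all of their cost lives in the
            # joint-chemistry term; the additive part is kept tiny (and
            # nonzero, so variance-share calibration stays well-posed)
            "surfactant": {
                "triton_x100": 0.0,
                "tween20": 0.008,
                "np40": 0.012,
                "sds": 0.016,
                "brij35": 0.02,
            },
            "chaotrope": {
                "gitc": 0.0,
                "guanidine_hcl": 0.008,
                "urea": 0.012,
                "betaine": 0.016,
                "none": 0.02,
            },
            "binding_alcohol": {
                "isopropanol": 0.0,
                "ethanol": 0.008,
                "peg_alcohol_mix": 0.012,
                "butanol": 0.016,
                "none": 0.02,
            },
            "buffer": {
                "tris_hcl": 0.0,
                "hepes": 0.008,
                "mops": 0.012,
                "phosphate": 0.016,
                "citrate": 0.02,
            },
            "wash_composition": {
                "ethanol_80": 0.0,
                "ethanol_70": 0.008,
                "salt_ethanol": 0.012,
                "isopropanol_wash": 0.016,
                "acetone_wash": 0.02,
            },
            "elution_condition": {
                "water_60c": 0.0,
                "tris_ph8": 0.008,
                "te_buffer": 0.012,
                "water_45c": 0.016,
                "water_rt": 0.02,
            },
        },
        interactions=_joint_chemistry_interactions(space, joint_penalty),
        coherence_terms=_decoy_family_terms(space, decoy_costs),
    )


# Data-driven per-category importance profile used as the planted truth in
# weighting-factor recovery experiments.  The four dominant categories carry
# the published magnitudes (particle size 0.357, functional group 0.264,
# molecular crowding 0.151, salting out 0.125); the remaining 0.103 is
# spread over the six minor axes.
DATA_DRIVEN_WEIGHT_PROFILE: dict[str, float] = {
    "particle_size": 0.357,
    "functional_group": 0.264,
    "molecular_crowding": 0.151,
    "salting_out": 0.125,
    "surfactant": 0.030,
    "chaotrope": 0.020,
    "buffer": 0.018,
    "binding_alcohol": 0.015,
    "wash_composition": 0.010,
    "elution_condition": 0.010,
}

UNIFORM_WEIGHT_PROFILE: dict[str, float] = {
    name: 0.1
    for name in (
        "particle_size",
        "functional_group",
        "molecular_crowding",
        "salting_out",
        "surfactant",
        "chaotrope",
        "binding_alcohol",
        "buffer",
        "wash_composition",
        "elution_condition",
    )
}
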