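"""Closed-loop campaign orchestration.

One campaign implements the platform's decision cycle: a requirement (target
Ct at a fixed template concentration) is first checked against the initial
store; if unmet, the loop iterates train -> propose -> evaluate -> append ->
decide until the requirement is met or the round budget is exhausted.
Evaluation of a proposed scheme is the mean of triplicate simulated
measurements under the automated-platform noise regime — the loop stops on
what it *observes*, not on the oracle's hidden truth.

Determinism: a single campaign seed derives an independent sub-seed for every
(round, stream) pair — surrogate training, advisor, GA, and measurement —
so a resumed campaign continues bit-identically to an uninterrupted run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .condition_space import ConditionSpace, Scheme
from .datasets import Dataset, ExperimentRecord, lookup_meeting_requirement
from .oracle import OracleParams, measure_ct
from .proposer import GAConfig, propose_batch
from .surrogate import ModelRegistry, TrainedSurrogate, train_and_select

__all__ = [
    "Requirement",
    "RoundLog",
    "CampaignState",
    "CampaignError",
    "run_campaign",
    "best_trajectory",
    "save_campaign",
    "load_campaign",
]

STATE_FORMAT_VERSION = "1"


class CampaignError(RuntimeError):
    pass


@dataclass(frozen=True)
class Requirement:
    """What the campaign must achieve: a Ct bound at a fixed concentration."""

    target_ct: float = 26.5
    conc: float = 1e5
    max_rounds: int = 9
    categories_in_scope: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.target_ct <= 0:
            raise ValueError("target_ct must be > 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.conc <= 0:
            raise ValueError("conc must be > 0")


@dataclass
class RoundLog:
    round: int
    model_id: str
    cv_r2: float
    cv_mse: float
    train_mse: float
    n_proposals: int
    best_measured: float
    best_so_far: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "RoundLog":
        return cls(**d)


@dataclass
class CampaignState:
    """Full closed-loop history: store, per-round logs, status, seed."""

    requirement: Requirement
    space: ConditionSpace
    dataset: Dataset
    seed: int
    logs: list[RoundLog] = field(default_factory=list)
    status: str = "running"  # running | met | exhausted
    n_rep: int = 3
    # surrogate metric history for the overfitting monitor (in-memory only
    # beyond the metrics captured in logs)
    surrogate_history: list[TrainedSurrogate] = field(default_factory=list, repr=False)

    @property
    def rounds_run(self) -> int:
        return len(self.logs)

    def best_ct(self) -> float:
        return float(min(r.ct for r in self.dataset.records))

    def rounds_to_met(self) -> int | None:
        """First round whose best-so-far satisfies the requirement, or None."""
        if lookup_meeting_requirement(self.dataset, self.requirement.target_ct) is None:
            return None
        for log in self.logs:
            if log.best_so_far <= self.requirement.target_ct:
                return log.round
        return 0  # satisfied by the initial data

    def to_dict(self) -> dict:
        return {
            "format_version": STATE_FORMAT_VERSION,
            "requirement": {
                "target_ct": self.requirement.target_ct,
                "conc": self.requirement.conc,
                "max_rounds": self.requirement.max_rounds,
                "categories_in_scope": (
                    list(self.requirement.categories_in_scope)
                    if self.requirement.categories_in_scope
                    else None
                ),
            },
            "space": self.space.to_dict(),
            "seed": self.seed,
            "status": self.status,
            "n_rep": self.n_rep,
            "logs": [l.to_dict() for l in self.logs],
            "records": [
                {
                    "assignments": dict(r.scheme.assignments),
                    "ct": r.ct,
                    "ct_sd": r.ct_sd,
                    "n_rep": r.n_rep,
                    "conc": r.conc,
                    "round": r.round,
                    "source": r.source,
                }
                for r in self.dataset.records
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignState":
        if d.get("format_version") != STATE_FORMAT_VERSION:
            raise CampaignError(
                f"unsupported campaign state version {d.get('format_version')!r}"
            )
        space = ConditionSpace.from_dict(d["space"])
        req = d["requirement"]
        requirement = Requirement(
            target_ct=req["target_ct"],
            conc=req["conc"],
            max_rounds=req["max_rounds"],
            categories_in_scope=(
                tuple(req["categories_in_scope"]) if req.get("categories_in_scope") else None
            ),
        )
        dataset = Dataset(space_id=space.space_id)
        for rd in d["records"]:
            dataset.append(
                ExperimentRecord(
                    scheme=Scheme(assignments=dict(rd["assignments"])),
                    ct=rd["ct"],
                    ct_sd=rd["ct_sd"],
                    n_rep=rd["n_rep"],
                    conc=rd["conc"],
                    round=rd["round"],
                    source=rd["source"],
                )
            )
        return cls(
            requirement=requirement,
            space=space,
            dataset=dataset,
            seed=d["seed"],
            logs=[RoundLog.from_dict(ld) for ld in d["logs"]],
            status=d["status"],
            n_rep=d["n_rep"],
        )


# stream tags for per-round sub-seed derivation
_STREAM_TRAIN, _STREAM_ADVISOR, _STREAM_GA, _STREAM_MEASURE = 0, 1, 2, 3


def _subseed(seed: int, round_idx: int, stream: int) -> int:
    """Deterministic sub-seed for a (round, stream) pair; < 2**31."""
    ss = np.random.SeedSequence([seed, round_idx, stream])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_campaign(
    requirement: Requirement,
    space: ConditionSpace,
    initial: Dataset,
    oracle: OracleParams,
    registry: ModelRegistry | None = None,
    ga_config: GAConfig | None = None,
    advisor=None,
    cv_folds: int = 5,
    seed: int = 0,
    resume_from: CampaignState | None = None,
) -> CampaignState:
    """Run (or resume) a closed-loop optimization campaign.

    ``advisor`` is an optional callable ``(space, dataset, seed) -> [Scheme]``
    whose suggestions are injected into the proposer's initial population.
    Resuming from a saved state continues with the same per-round sub-seeds,
    so the final state is identical to an uninterrupted run.
    """
    ga_config = ga_config or GAConfig()
    if initial.space_id != space.space_id:
        raise CampaignError(
            f"dataset belongs to space {initial.space_id!r}, expected {space.space_id!r}"
        )
    if resume_from is not None:
        state = resume_from
        if state.status != "running":
            return state
    else:
        state = CampaignState(
            requirement=requirement, space=space, dataset=initial.copy(), seed=seed
        )
        hit = lookup_meeting_requirement(state.dataset, requirement.target_ct)
        if hit is not None:
            state.status = "met"
            return state

    start_round = state.rounds_run + 1
    seed = state.seed
    requirement = state.requirement
    best_so_far = state.best_ct()
    for round_idx in range(start_round, requirement.max_rounds + 1):
        surrogate = train_and_select(
            state.dataset,
            space,
            registry=registry,
            cv_folds=cv_folds,
            seed=_subseed(seed, round_idx, _STREAM_TRAIN),
            training_round=round_idx,
        )
        state.surrogate_history.append(surrogate)
        suggestions = (
            advisor(space, state.dataset, seed=_subseed(seed, round_idx, _STREAM_ADVISOR))
            if advisor is not None
            else []
        )
        proposals = propose_batch(
            surrogate,
            space,
            ga_config,
            evaluated=set(state.dataset.schemes()),
            advisor_suggestions=suggestions,
            target_ct=requirement.target_ct,
            seed=_subseed(seed, round_idx, _STREAM_GA),
            probe_base=state.dataset.best().scheme,
        )
        measure_rng = np.random.default_rng(
            [_subseed(seed, round_idx, _STREAM_MEASURE)]
        )
        round_best = np.inf
        for scheme in proposals:
            reps = measure_ct(
                oracle,
                scheme,
                conc=requirement.conc,
                n_rep=state.n_rep,
                regime="auto",
                seed=int(measure_rng.integers(2**31 - 1)),
            )
            mean_ct = float(np.mean(reps))
            state.dataset.append(
                ExperimentRecord(
                    scheme=scheme,
                    ct=mean_ct,
                    ct_sd=float(np.std(reps, ddof=1)) if state.n_rep > 1 else 0.0,
                    n_rep=state.n_rep,
                    conc=requirement.conc,
                    round=round_idx,
                    source="loop",
                )
            )
            round_best = min(round_best, mean_ct)
        best_so_far = min(best_so_far, round_best)
        state.logs.append(
            RoundLog(
                round=round_idx,
                model_id=surrogate.model_id,
                cv_r2=surrogate.cv_r2,
                cv_mse=surrogate.cv_mse,
                train_mse=surrogate.train_mse,
                n_proposals=len(proposals),
                best_measured=float(round_best),
                best_so_far=float(best_so_far),
            )
        )
        if best_so_far <= requirement.target_ct:
            state.status = "met"
            return state
    state.status = "exhausted"
    return state


def best_trajectory(state: CampaignState) -> list[float]:
    """Per-round best-so-far measured Ct; monotone non-increasing."""
    if not state.logs:
        raise ValueError("campaign has no completed rounds")
    return [log.best_so_far for log in state.logs]


def save_campaign(state: CampaignState, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(state.to_dict(), fh, sort_keys=True)


def load_campaign(path) -> CampaignState:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CampaignError(f"corrupt campaign file: {exc}") from exc
    if not isinstance(payload, dict):
        raise CampaignError("corrupt campaign file: not a JSON object")
    try:
        return CampaignState.from_dict(payload)
    except (KeyError, TypeError) as exc:
        raise CampaignError(f"corrupt campaign file: missing field {exc}") from exc
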