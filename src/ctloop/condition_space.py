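"""Mixed categorical/continuous formulation space ("Conditions") and scheme encoding.

A *condition space* is an ordered set of named categories.  Each category is
either categorical, with a fixed ordered list of named sub-condition levels
(e.g. the surfactant used), or numeric, with a closed ``[min, max]`` range and
units (e.g. particle size in nm).  A *scheme* is one complete formulation: one
sub-condition choice per category.  Schemes are the unit that is proposed,
"synthesized" (here: evaluated against a response-surface oracle) and stored.

Schemes are encoded to fixed-length numeric feature vectors — one-hot blocks
for categorical categories, min–max scaling to ``[0, 1]`` for numeric ones —
which is the representation every downstream regression model and the PCA
projection consume.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConditionCategory",
    "ConditionSpace",
    "Scheme",
    "ValidationResult",
    "SchemeError",
    "validate_scheme",
    "encode",
    "decode",
    "encode_many",
    "scheme_to_json",
    "scheme_from_json",
    "sample_uniform",
    "enumerate_space",
]

SCHEME_FORMAT_VERSION = "1"


class SchemeError(ValueError):
    """Raised when a scheme violates its space's invariants."""


@dataclass(frozen=True)
class ConditionCategory:
    """One optimization axis: either a set of named levels or a numeric range."""

    name: str
    kind: str  # "categorical" | "numeric"
    levels: tuple[str, ...] | None = None
    range: tuple[float, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"unknown category kind {self.kind!r}")
        if self.kind == "categorical":
            if self.range is not None or not self.levels:
                raise ValueError(f"categorical category {self.name!r} needs levels only")
            if len(self.levels) < 2:
                raise ValueError(f"category {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"category {self.name!r} has duplicate levels")
        else:
            if self.levels is not None or self.range is None:
                raise ValueError(f"numeric category {self.name!r} needs a range only")
            lo, hi = self.range
            if not lo < hi:
                raise ValueError(f"category {self.name!r} requires min < max")

    @property
    def width(self) -> int:
        """Number of feature-vector columns this category occupies."""
        return len(self.levels) if self.kind == "categorical" else 1


@dataclass(frozen=True)
class ConditionSpace:
    """Ordered collection of categories; fixes the feature encoding."""

    categories: tuple[ConditionCategory, ...]
    space_id: str = "default"

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        if not self.categories:
            raise ValueError("a space needs at least one category")

    @property
    def dimension(self) -> int:
        return sum(c.width for c in self.categories)

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def category(self, name: str) -> ConditionCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def blocks(self) -> dict[str, slice]:
        """Feature-column slice per category, in declared order."""
        out: dict[str, slice] = {}
        start = 0
        for c in self.categories:
            out[c.name] = slice(start, start + c.width)
            start += c.width
        return out

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for c in self.categories:
            if c.kind == "categorical":
                names.extend(f"{c.name}={lvl}" for lvl in c.levels)
            else:
                names.append(c.name)
        return names

    def to_dict(self) -> dict:
        return {
            "space_id": self.space_id,
            "categories": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    **({"levels": list(c.levels)} if c.kind == "categorical" else {}),
                    **({"range": list(c.range), "units": c.units} if c.kind == "numeric" else {}),
                }
                for c in self.categories
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpace":
        cats = []
        for cd in d["categories"]:
            cats.append(
                ConditionCategory(
                    name=cd["name"],
                    kind=cd["kind"],
                    levels=tuple(cd["levels"]) if cd.get("levels") else None,
                    range=tuple(cd["range"]) if cd.get("range") else None,
                    units=cd.get("units", ""),
                )
            )
        return cls(categories=tuple(cats), space_id=d.get("space_id", "default"))


@dataclass(frozen=True)
class Scheme:
    """One complete formulation: a sub-condition choice per category.

    ``assignments`` maps category name to a level name (categorical) or a
    float (numeric).  Schemes are hashable via :meth:`key` so campaign
    bookkeeping (deduplication against already-evaluated schemes) is exact.
    """

    assignments: dict[str, object]
    label: str | None = None

    def key(self) -> tuple:
        return tuple(sorted((k, v) for k, v in self.assignments.items()))

    def __hash__(self) -> int:  # assignments dict is conventionally not mutated
        return hash(self.key())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Scheme) and self.key() == other.key()


@dataclass
class ValidationResult:
    ok: bool
    problems: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_scheme(space: ConditionSpace, scheme: Scheme) -> ValidationResult:
    """Check a scheme against its space; violations are returned, not raised."""
    problems: list[str] = []
    seen = set(scheme.assignments)
    for cat in space.categories:
        if cat.name not in scheme.assignments:
            problems.append(f"missing category {cat.name!r}")
            continue
        value = scheme.assignments[cat.name]
        if cat.kind == "categorical":
            if value not in cat.levels:
                problems.append(f"unknown level {value!r} for category {cat.name!r}")
        else:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                problems.append(f"non-numeric value {value!r} for category {cat.name!r}")
            elif not math.isfinite(float(value)):
                problems.append(f"non-finite value for category {cat.name!r}")
            else:
                lo, hi = cat.range
                if not lo <= float(value) <= hi:
                    problems.append(
                        f"value {value!r} out of range [{lo}, {hi}] for category {cat.name!r}"
                    )
    extra = seen - set(space.category_names)
    for name in sorted(extra):
        problems.append(f"unknown category {name!r}")
    return ValidationResult(ok=not problems, problems=problems)


def _require_valid(space: ConditionSpace, scheme: Scheme) -> None:
    res = validate_scheme(space, scheme)
    if not res:
        raise SchemeError("; ".join(res.problems))


def encode(space: ConditionSpace, scheme: Scheme) -> np.ndarray:
    """Encode a valid scheme as a feature vector.

    One-hot per categorical level; numerics min–max scaled to [0, 1].
    Deterministic, and bijective with :func:`decode` on valid schemes.
    """
    _require_valid(space, scheme)
    vec = np.zeros(space.dimension, dtype=float)
    pos = 0
    for cat in space.categories:
        value = scheme.assignments[cat.name]
        if cat.kind == "categorical":
            vec[pos + cat.levels.index(value)] = 1.0
            pos += len(cat.levels)
        else:
            lo, hi = cat.range
            vec[pos] = (float(value) - lo) / (hi - lo)
            pos += 1
    return vec


def decode(space: ConditionSpace, vector: np.ndarray) -> Scheme:
    """Invert :func:`encode`; one-hot blocks must sum to exactly 1."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (space.dimension,):
        raise SchemeError(
            f"feature vector has dimension {vector.shape}, expected ({space.dimension},)"
        )
    assignments: dict[str, object] = {}
    pos = 0
    for cat in space.categories:
        if cat.kind == "categorical":
            block = vector[pos : pos + len(cat.levels)]
            if not np.isclose(block.sum(), 1.0):
                raise SchemeError(f"one-hot block for {cat.name!r} does not sum to 1")
            assignments[cat.name] = cat.levels[int(np.argmax(block))]
            pos += len(cat.levels)
        else:
            lo, hi = cat.range
            assignments[cat.name] = lo + vector[pos] * (hi - lo)
            pos += 1
    return Scheme(assignments=assignments)


def encode_many(space: ConditionSpace, schemes: list[Scheme]) -> np.ndarray:
    """Stack encodings of several schemes into an (n, dimension) matrix."""
    return np.array([encode(space, s) for s in schemes], dtype=float)


def scheme_to_json(space: ConditionSpace, scheme: Scheme, meta: dict | None = None) -> str:
    """Serialize a scheme to the package's JSON scheme-code dialect.

    Keys are sorted and floats keep full precision, so serializing the same
    scheme twice yields byte-identical text.
    """
    _require_valid(space, scheme)
    payload = {
        "format_version": SCHEME_FORMAT_VERSION,
        "space_id": space.space_id,
        "assignments": dict(sorted(scheme.assignments.items())),
        "meta": meta or {},
    }
    if scheme.label is not None:
        payload["meta"] = {**payload["meta"], "label": scheme.label}
    return json.dumps(payload, sort_keys=True, separators=(",", ":"), allow_nan=False)


def scheme_from_json(space: ConditionSpace, text: str) -> Scheme:
    """Parse a JSON scheme code back to a :class:`Scheme`, validating it."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemeError(f"malformed scheme JSON at position {exc.pos}: {exc.msg}") from exc
    for field_name in ("format_version", "space_id", "assignments"):
        if field_name not in payload:
            raise SchemeError(f"scheme JSON missing field {field_name!r}")
    if payload["space_id"] != space.space_id:
        raise SchemeError(
            f"scheme belongs to space {payload['space_id']!r}, expected {space.space_id!r}"
        )
    label = payload.get("meta", {}).get("label")
    scheme = Scheme(assignments=dict(payload["assignments"]), label=label)
    res = validate_scheme(space, scheme)
    if not res:
        raise SchemeError("; ".join(res.problems))
    return scheme


def sample_uniform(space: ConditionSpace, n: int, seed: int) -> list[Scheme]:
    """Draw ``n`` schemes uniformly: levels equiprobable, numerics uniform on range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    schemes = []
    for _ in range(n):
        assignments: dict[str, object] = {}
        for cat in space.categories:
            if cat.kind == "categorical":
                assignments[cat.name] = cat.levels[int(rng.integers(len(cat.levels)))]
            else:
                lo, hi = cat.range
                assignments[cat.name] = float(rng.uniform(lo, hi))
        schemes.append(Scheme(assignments=assignments))
    return schemes


def enumerate_space(space: ConditionSpace, limit: int = 100_000) -> list[Scheme]:
    """Full Cartesian product of an all-categorical space, in declared order.

    Serves as the brute-force oracle against which the genetic-algorithm
    proposer is checked on small spaces.
    """
    for cat in space.categories:
        if cat.kind != "categorical":
            raise ValueError(f"cannot enumerate numeric category {cat.name!r}")
    total = math.prod(len(c.levels) for c in space.categories)
    if total > limit:
        raise ValueError(f"space has {total} schemes, exceeding limit {limit}")
    names = space.category_names
    out = []
    for combo in itertools.product(*(c.levels for c in space.categories)):
        out.append(Scheme(assignments=dict(zip(names, combo))))
    return out
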