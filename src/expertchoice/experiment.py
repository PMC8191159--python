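"""Declaration and validation of the decision problem.

An :class:`ExperimentSpec` describes an expert decision as a set of named
factors (decision criteria) with ordered, discrete levels, a coding scheme
per factor, feasibility constraints, and optional pairwise interactions.
It enumerates the feasible profiles (hypothetical cases) and encodes them
into the numeric rows used by the design and estimation machinery.

Coding conventions
------------------
* ``dummy`` coding: a factor with L levels contributes L-1 indicator
  parameters; the first listed level is the reference, its weight fixed
  at zero.
* ``linear`` coding: a single parameter multiplying the level index
  0..L-1 in listed order (levels are listed worst-to-best, so a positive
  coefficient means the factor pushes toward the action as it improves).

The total parameter count is 1 (intercept) + per-factor parameters +
interaction parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .exceptions import (
    EmptyFeasibleSetError,
    InfeasibleProfileError,
    UnknownLevelError,
)

CODINGS = ("dummy", "linear")
RESPONSE_TYPES = ("binary", "multinomial")

__all__ = [
    "Factor",
    "Constraint",
    "ExperimentSpec",
    "Profile",
    "validate_spec",
    "enumerate_profiles",
    "encode_profile",
]


@dataclass(frozen=True)
class Factor:
    """A decision criterion with ordered discrete levels.

    Parameters
    ----------
    name : str
        Short identifier, unique within a spec.
    levels : tuple of str
        Ordered level labels (>= 2, unique). The listed order matters:
        the first level is the dummy-coding reference, and linear coding
        assigns integer codes 0..L-1 in this order.
    coding : {"dummy", "linear"}
    """

    name: str
    levels: tuple[str, ...]
    coding: str = "dummy"

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_params(self) -> int:
        """Number of model parameters this factor contributes."""
        return (self.n_levels - 1) if self.coding == "dummy" else 1

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise UnknownLevelError(self.name, label) from None

    def param_names(self) -> list[str]:
        if self.coding == "dummy":
            return [f"{self.name}[{lv}]" for lv in self.levels[1:]]
        return [self.name]

    def coded_columns(self, label: str) -> np.ndarray:
        """Coded values this factor contributes for the given level."""
        idx = self.level_index(label)
        if self.coding == "dummy":
            cols = np.zeros(self.n_levels - 1)
            if idx > 0:
                cols[idx - 1] = 1.0
            return cols
        return np.array([float(idx)])


@dataclass(frozen=True)
class Constraint:
    """A conjunctive forbidden combination of (factor, level) pairs.

    A profile is infeasible if it matches *every* pair in ``forbidden``.
    """

    forbidden: tuple[tuple[str, str], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "forbidden", tuple((f, l) for f, l in self.forbidden)
        )

    def forbids(self, assignment: Mapping[str, str]) -> bool:
        return all(assignment.get(f) == l for f, l in self.forbidden)

    def __str__(self) -> str:
        return " & ".join(f"{f}={l}" for f, l in self.forbidden)


@dataclass(frozen=True)
class Profile:
    """One complete assignment of a level to every factor of a spec.

    Stored as the tuple of level labels in the spec's factor order, so
    profiles are hashable and comparable.
    """

    levels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))

    def as_dict(self, spec: "ExperimentSpec") -> dict[str, str]:
        return dict(zip(spec.factor_names, self.levels))


@dataclass(frozen=True)
class ExperimentSpec:
    """The decision problem: factors, coding, constraints, interactions."""

    decision_label: str
    factors: tuple[Factor, ...]
    response_type: str = "binary"
    constraints: tuple[Constraint, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        object.__setattr__(
            self, "interactions", tuple((a, b) for a, b in self.interactions)
        )

    # ------------------------------------------------------------------
    # basic structure
    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")

    @property
    def n_params(self) -> int:
        """Intercept + per-factor parameters + interaction parameters."""
        n = 1 + sum(f.n_params for f in self.factors)
        for a, b in self.interactions:
            n += self.factor(a).n_params * self.factor(b).n_params
        return n

    @property
    def param_names(self) -> list[str]:
        names = ["const"]
        for f in self.factors:
            names.extend(f.param_names())
        for a, b in self.interactions:
            for pa in self.factor(a).param_names():
                for pb in self.factor(b).param_names():
                    names.append(f"{pa}:{pb}")
        return names

    # ------------------------------------------------------------------
    # profiles
    def profile(self, assignment: Mapping[str, str]) -> Profile:
        """Build a Profile from a factor->level mapping (validated)."""
        missing = [n for n in self.factor_names if n not in assignment]
        if missing:
            raise KeyError(f"missing assignment for factor(s): {missing}")
        levels = []
        for f in self.factors:
            f.level_index(assignment[f.name])  # raises UnknownLevelError
            levels.append(assignment[f.name])
        return Profile(tuple(levels))

    def reference_profile(self) -> Profile:
        """Every factor at its first listed level."""
        return Profile(tuple(f.levels[0] for f in self.factors))

    def best_profile(self) -> Profile:
        """Every factor at its last listed level."""
        return Profile(tuple(f.levels[-1] for f in self.factors))

    def violated_constraints(self, profile: Profile) -> list[Constraint]:
        assignment = profile.as_dict(self)
        return [c for c in self.constraints if c.forbids(assignment)]

    def is_feasible(self, profile: Profile) -> bool:
        return not self.violated_constraints(profile)

    def require_feasible(self, profile: Profile) -> None:
        violated = self.violated_constraints(profile)
        if violated:
            raise InfeasibleProfileError(violated)

    def iter_profiles(self) -> Iterator[Profile]:
        """Lazily yield feasible profiles in lexicographic level-index order."""
        for combo in itertools.product(*(f.levels for f in self.factors)):
            p = Profile(combo)
            if self.is_feasible(p):
                yield p

    def count_profiles(self) -> int:
        """Number of feasible profiles (product shortcut when unconstrained)."""
        if not self.constraints:
            return int(np.prod([f.n_levels for f in self.factors]))
        return sum(1 for _ in self.iter_profiles())

    # ------------------------------------------------------------------
    # encoding
    def encode(self, profile: Profile) -> np.ndarray:
        """Coded row vector: intercept, factor codes, interaction products."""
        per_factor = {}
        row = [np.ones(1)]
        for f, label in zip(self.factors, profile.levels):
            cols = f.coded_columns(label)
            per_factor[f.name] = cols
            row.append(cols)
        for a, b in self.interactions:
            row.append(np.outer(per_factor[a], per_factor[b]).ravel())
        return np.concatenate(row)

    def encode_many(self, profiles: Sequence[Profile]) -> np.ndarray:
        return np.array([self.encode(p) for p in profiles])


# ----------------------------------------------------------------------
# module-level operations

def validate_spec(spec: ExperimentSpec) -> list[str]:
    """Check every structural invariant; return one finding per violation.

    An empty list means the spec is valid. Findings are returned rather
    than raised so callers can report all problems at once.
    """
    findings: list[str] = []
    names = [f.name for f in spec.factors]
    if not spec.factors:
        findings.append("spec has no factors")
    for n in sorted({n for n in names if names.count(n) > 1}):
        findings.append(f"duplicate factor name {n!r}")
    for f in spec.factors:
        if f.n_levels < 2:
            findings.append(f"factor {f.name!r} has <2 levels")
        if len(set(f.levels)) != f.n_levels:
            findings.append(f"factor {f.name!r} has duplicate level labels")
        if f.coding not in CODINGS:
            findings.append(
                f"factor {f.name!r} has unknown coding {f.coding!r}"
            )
    if spec.response_type not in RESPONSE_TYPES:
        findings.append(f"unknown response_type {spec.response_type!r}")
    by_name = {f.name: f for f in spec.factors}
    for i, c in enumerate(spec.constraints):
        referenced = set()
        for fac, lev in c.forbidden:
            if fac not in by_name:
                findings.append(
                    f"constraint {i} references unknown factor {fac!r}"
                )
                continue
            referenced.add(fac)
            if lev not in by_name[fac].levels:
                findings.append(
                    f"constraint {i} references unknown level {lev!r} "
                    f"of factor {fac!r}"
                )
        if len(referenced) < 2:
            findings.append(
                f"constraint {i} must name >=2 distinct factors"
            )
    for a, b in spec.interactions:
        for fac in (a, b):
            if fac not in by_name:
                findings.append(
                    f"interaction ({a!r}, {b!r}) references unknown "
                    f"factor {fac!r}"
                )
        if a == b:
            findings.append(
                f"interaction ({a!r}, {b!r}) must name two distinct factors"
            )
    return findings


def enumerate_profiles(spec: ExperimentSpec) -> list[Profile]:
    """All feasible profiles, lexicographic in level indices.

    Raises :class:`EmptyFeasibleSetError` if constraints exclude everything.
    """
    profiles = list(spec.iter_profiles())
    if not profiles:
        raise EmptyFeasibleSetError(
            "constraints leave no feasible profile"
        )
    return profiles


def encode_profile(spec: ExperimentSpec, profile: Profile) -> np.ndarray:
    """Coded row vector for a profile (see :meth:`ExperimentSpec.encode`)."""
    return spec.encode(profile)
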