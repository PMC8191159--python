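"""D-efficient experimental designs for single-conjoint (yes/no) experiments.

A design is an ordered set of scenarios (profiles) shown to every expert.
Its statistical quality is judged by the D-error
``det(I(beta))**(-1/K)`` where ``I`` is the Fisher information of the
binary logit under prior weights ``beta`` and ``K`` the parameter count;
lower is better. With all-zero priors every scenario has choice
probability 1/2 and the information matrix reduces to ``0.25 * X'X``
(the utility-neutral design criterion).

Designs are constructed by coordinate exchange with multi-start: sweep
scenario x factor cells, replacing each level with the feasible
alternative that most reduces the D-error, until a full pass brings no
improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.special import expit

from .exceptions import EmptyFeasibleSetError, SingularDesignError
from .experiment import ExperimentSpec, Profile

__all__ = [
    "Design",
    "zero_priors",
    "information_matrix",
    "d_error",
    "random_design",
    "generate_design",
    "design_diagnostics",
]


@dataclass
class Design:
    """An ordered set of feasible scenarios plus creation metadata."""

    spec: ExperimentSpec
    scenarios: tuple[Profile, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scenarios = tuple(self.scenarios)

    def __len__(self) -> int:
        return len(self.scenarios)

    def coded_matrix(self) -> np.ndarray:
        return self.spec.encode_many(self.scenarios)

    def is_identifiable(self, priors=None) -> bool:
        """Full column rank of the weighted coded matrix."""
        M = information_matrix(self, zero_priors(self.spec) if priors is None else priors)
        return np.linalg.matrix_rank(M) == self.spec.n_params


def zero_priors(spec: ExperimentSpec) -> np.ndarray:
    """Utility-neutral prior weights (every choice probability 1/2)."""
    return np.zeros(spec.n_params)


def _as_priors(spec: ExperimentSpec, priors) -> np.ndarray:
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (spec.n_params,):
        raise ValueError(
            f"priors must have length {spec.n_params} (one per parameter, "
            f"intercept included); got shape {priors.shape}"
        )
    return priors


def _info_from_matrix(X: np.ndarray, priors: np.ndarray) -> np.ndarray:
    p = expit(X @ priors)
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def information_matrix(design: Design, priors) -> np.ndarray:
    """Fisher information of the binary logit: sum of p(1-p) x x'."""
    if len(design) == 0:
        raise ValueError("design is empty")
    priors = _as_priors(design.spec, priors)
    return _info_from_matrix(design.coded_matrix(), priors)


def _d_error_from_info(M: np.ndarray) -> float:
    K = M.shape[0]
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        return np.inf
    return float(np.exp(-logdet / K))


def d_error(design: Design, priors) -> float:
    """det(information)^(-1/K); lower means a more informative design.

    Raises :class:`SingularDesignError` when the information matrix is
    singular (the design cannot identify all parameters).
    """
    value = _d_error_from_info(information_matrix(design, priors))
    if not np.isfinite(value):
        raise SingularDesignError(
            "information matrix is singular; the design is non-identifiable"
        )
    return value


# ----------------------------------------------------------------------
# random designs

_MAX_REJECTION_FACTOR = 1000
_ENUMERATION_CEILING = 100_000


def random_design(spec: ExperimentSpec, n_scenarios: int, seed: int) -> Design:
    """Uniform draw of ``n_scenarios`` feasible profiles without replacement."""
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be positive")
    rng = np.random.default_rng(seed)
    n_full = int(np.prod([f.n_levels for f in spec.factors]))
    if n_full <= _ENUMERATION_CEILING:
        feasible = list(spec.iter_profiles())
        if not feasible:
            raise EmptyFeasibleSetError("constraints leave no feasible profile")
        if n_scenarios > len(feasible):
            raise ValueError(
                f"n_scenarios={n_scenarios} exceeds the feasible-profile "
                f"count {len(feasible)}"
            )
        idx = rng.choice(len(feasible), size=n_scenarios, replace=False)
        scenarios = tuple(feasible[i] for i in sorted(idx))
    else:
        # profile space too large to enumerate: rejection-sample levels
        scenarios_set: dict[Profile, None] = {}
        attempts = 0
        limit = _MAX_REJECTION_FACTOR * n_scenarios
        while len(scenarios_set) < n_scenarios:
            if attempts >= limit:
                raise EmptyFeasibleSetError(
                    "could not draw a feasible design within the attempt "
                    "budget; constraints may be too restrictive"
                )
            attempts += 1
            combo = tuple(
                f.levels[rng.integers(f.n_levels)] for f in spec.factors
            )
            p = Profile(combo)
            if spec.is_feasible(p) and p not in scenarios_set:
                scenarios_set[p] = None
        scenarios = tuple(scenarios_set)
    return Design(
        spec,
        scenarios,
        metadata={"algorithm": "random", "seed": int(seed)},
    )


# ----------------------------------------------------------------------
# coordinate exchange


def generate_design(
    spec: ExperimentSpec,
    n_scenarios: int,
    priors=None,
    seed: int = 0,
    n_starts: int = 10,
    max_passes: int = 20,
) -> Design:
    """D-efficient design by coordinate exchange with multi-start.

    Each restart begins from ``random_design(spec, n_scenarios, seed + r)``
    and sweeps scenario x factor cells, keeping the feasible level that
    most reduces the D-error (ties keep the incumbent). The best design
    over all restarts is returned. Deterministic given ``seed``.
    """
    priors = zero_priors(spec) if priors is None else _as_priors(spec, priors)
    K = spec.n_params
    if n_scenarios < K:
        warnings.warn(
            f"n_scenarios={n_scenarios} < parameter count {K}: the design "
            "cannot be identifiable from a single expert; replicated "
            "experts may still identify the model",
            stacklevel=2,
        )
    best_scenarios = None
    best_err = np.inf
    best_meta = {}
    for start in range(n_starts):
        start_design = random_design(spec, n_scenarios, seed + start)
        scenarios = list(start_design.scenarios)
        X = spec.encode_many(scenarios)
        err = _d_error_from_info(_info_from_matrix(X, priors))
        passes = 0
        improved = True
        while improved and passes < max_passes:
            improved = False
            passes += 1
            for i in range(n_scenarios):
                for fi, fac in enumerate(spec.factors):
                    current = scenarios[i]
                    for level in fac.levels:
                        if level == current.levels[fi]:
                            continue
                        cand_levels = list(current.levels)
                        cand_levels[fi] = level
                        cand = Profile(tuple(cand_levels))
                        if not spec.is_feasible(cand):
                            continue
                        X[i] = spec.encode(cand)
                        cand_err = _d_error_from_info(
                            _info_from_matrix(X, priors)
                        )
                        if cand_err < err - 1e-12:
                            err = cand_err
                            current = cand
                            scenarios[i] = cand
                            improved = True
                        else:
                            X[i] = spec.encode(current)
        if err < best_err:
            best_err = err
            best_scenarios = tuple(scenarios)
            best_meta = {"start": start, "passes": passes}
    if best_scenarios is None or not np.isfinite(best_err):
        raise SingularDesignError(
            "every candidate design had a singular information matrix; "
            "increase n_scenarios"
        )
    return Design(
        spec,
        best_scenarios,
        metadata={
            "algorithm": "coordinate-exchange",
            "seed": int(seed),
            "n_starts": int(n_starts),
            "max_passes": int(max_passes),
            "d_error": float(best_err),
            "priors": [float(v) for v in priors],
            **best_meta,
        },
    )


def design_diagnostics(design: Design) -> dict:
    """Level-balance counts, zero-prior D-error, and coded-matrix rank."""
    spec = design.spec
    balance = {}
    for fi, fac in enumerate(spec.factors):
        counts = {lv: 0 for lv in fac.levels}
        for s in design.scenarios:
            counts[s.levels[fi]] += 1
        balance[fac.name] = counts
    X = design.coded_matrix()
    M = _info_from_matrix(X, zero_priors(spec))
    return {
        "n_scenarios": len(design),
        "level_balance": balance,
        "d_error_zero_priors": _d_error_from_info(M),
        "rank": int(np.linalg.matrix_rank(X)),
        "n_params": spec.n_params,
    }
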