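"""Maximum-likelihood estimation of expert choice models.

The central objects follow the statsmodels convention: a model class
(:class:`ChoiceLogit` for the single-conjoint yes/no response,
:class:`MultinomialChoiceLogit` for choices among alternative sets) is
built from a :class:`ChoiceDataset`; its :meth:`fit` runs Newton-Raphson
on the log-likelihood and returns a :class:`ChoiceLogitResults` carrying
the estimated weights, their covariance (inverse observed information),
log-likelihoods, McFadden's rho-squared and Wald inference, with a
:meth:`~ChoiceLogitResults.summary` table.

The binary model is

    P(yes | x) = exp(x'b) / (1 + exp(x'b)),

with x the coded profile (intercept included). Observations are treated
as independent across experts and scenarios; panel correlation is out of
scope. The null model for rho-squared is all-weights-zero (every
alternative equally likely), so the null log-likelihood of n binary
observations is n*ln(1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
)
from .experiment import ExperimentSpec, Profile

__all__ = [
    "ChoiceObservation",
    "MultinomialObservation",
    "ChoiceDataset",
    "MultinomialChoiceDataset",
    "ChoiceLogit",
    "MultinomialChoiceLogit",
    "ChoiceLogitResults",
    "log_likelihood",
    "fit_logit",
    "wald_inference",
    "predicted_observed_mad",
]

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
SEPARATION_BOUND = 50.0


@dataclass(frozen=True)
class ChoiceObservation:
    """One expert's yes/no answer to one scenario."""

    expert_id: str
    profile: Profile
    choice: int  # 1 = recommend the action, 0 = not

    def __post_init__(self):
        if self.choice not in (0, 1):
            raise ValueError(f"binary choice must be 0 or 1, got {self.choice}")


@dataclass(frozen=True)
class MultinomialObservation:
    """One expert's pick from a set of alternative profiles.

    ``None`` in ``alternatives`` denotes an opt-out alternative whose
    utility is fixed at zero (its coded row is all zeros).
    """

    expert_id: str
    alternatives: tuple[Optional[Profile], ...]
    choice: int  # index into alternatives

    def __post_init__(self):
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        if not 0 <= self.choice < len(self.alternatives):
            raise ValueError(
                f"choice index {self.choice} outside the alternative set "
                f"of size {len(self.alternatives)}"
            )


@dataclass
class ChoiceDataset:
    """Expert x scenario binary observations sharing one spec."""

    spec: ExperimentSpec
    observations: tuple[ChoiceObservation, ...]

    def __post_init__(self):
        self.observations = tuple(self.observations)
        if not self.observations:
            raise ValueError("dataset must contain at least one observation")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def design_matrix(self) -> np.ndarray:
        return self.spec.encode_many([o.profile for o in self.observations])

    def responses(self) -> np.ndarray:
        return np.array([o.choice for o in self.observations], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            row = {"expert_id": o.expert_id}
            row.update(o.profile.as_dict(self.spec))
            row["choice"] = o.choice
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spec: ExperimentSpec) -> "ChoiceDataset":
        obs = []
        for _, row in df.iterrows():
            profile = spec.profile({n: str(row[n]) for n in spec.factor_names})
            obs.append(
                ChoiceObservation(str(row["expert_id"]), profile, int(row["choice"]))
            )
        return cls(spec, tuple(obs))

    def as_multinomial(self) -> "MultinomialChoiceDataset":
        """Recast yes/no data as a 2-alternative choice: {opt-out, profile}."""
        obs = tuple(
            MultinomialObservation(
                o.expert_id, (None, o.profile), int(o.choice)
            )
            for o in self.observations
        )
        return MultinomialChoiceDataset(self.spec, obs)


@dataclass
class MultinomialChoiceDataset:
    """Choice-set observations; every set must have the same size."""

    spec: ExperimentSpec
    observations: tuple[MultinomialObservation, ...]

    def __post_init__(self):
        self.observations = tuple(self.observations)
        if not self.observations:
            raise ValueError("dataset must contain at least one observation")
        sizes = {len(o.alternatives) for o in self.observations}
        if len(sizes) != 1:
            raise ValueError(
                f"all choice sets must share one size; found sizes {sorted(sizes)}"
            )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_alternatives(self) -> int:
        return len(self.observations[0].alternatives)

    def coded_array(self) -> np.ndarray:
        """(n_obs, n_alternatives, n_params) array of alternative codings."""
        K = self.spec.n_params
        zero = np.zeros(K)
        rows = []
        for o in self.observations:
            rows.append(
                [zero if p is None else self.spec.encode(p) for p in o.alternatives]
            )
        return np.asarray(rows)

    def responses(self) -> np.ndarray:
        return np.array([o.choice for o in self.observations], dtype=int)


# ----------------------------------------------------------------------
# shared numerics


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # pivoted QR identifies which columns are linearly dependent
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(sorted(bad))


def _check_perfect_prediction(miss_probs: np.ndarray) -> None:
    # the gradient tolerance is met before weights reach the divergence
    # bound under complete separation, so check the solution directly:
    # every observed choice predicted with probability ~1 means no finite MLE
    if float(np.max(miss_probs)) < 1e-6:
        raise SeparationError(
            "every observation is perfectly predicted at the solution: "
            "complete separation, no finite MLE exists"
        )


def _newton(loglike, score_hess, k, tol, max_iter, bound):
    """Damped Newton-Raphson from zero start; LL is non-decreasing."""
    w = np.zeros(k)
    ll = loglike(w)
    trace = [ll]
    for it in range(1, max_iter + 1):
        g, H = score_hess(w)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < tol:
            return w, ll, it - 1, gnorm, trace, True
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "Hessian became singular during iteration: possible "
                "complete separation"
            ) from None
        t = 1.0
        while t > 1e-10:
            cand = w + t * step
            cand_ll = loglike(cand)
            if cand_ll >= ll - 1e-12:
                break
            t *= 0.5
        w = w + t * step
        ll = loglike(w)
        trace.append(ll)
        if np.max(np.abs(w)) > bound:
            raise SeparationError(
                f"weight magnitude exceeded {bound} during iteration: "
                "possible complete separation"
            )
    g, _ = score_hess(w)
    gnorm = float(np.max(np.abs(g)))
    if gnorm < tol:
        return w, ll, max_iter, gnorm, trace, True
    raise ConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations "
        f"(gradient max-norm {gnorm:.3e}); LL trace: "
        + ", ".join(f"{v:.4f}" for v in trace[-5:]),
        trace=trace,
    )


# ----------------------------------------------------------------------
# models


class ChoiceLogit:
    """Binary logit model of expert yes/no recommendations."""

    def __init__(self, dataset: ChoiceDataset):
        self.dataset = dataset
        self.spec = dataset.spec
        self.X = dataset.design_matrix()
        self.y = dataset.responses()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ExperimentSpec) -> "ChoiceLogit":
        return cls(ChoiceDataset.from_frame(df, spec))

    def loglike(self, weights) -> float:
        v = self.X @ np.asarray(weights, dtype=float)
        # y*v - log(1 + exp(v)), stable for |v| up to ~700
        return float(np.sum(self.y * v + log_expit(-v)))

    def loglike_null(self) -> float:
        return len(self.y) * np.log(0.5)

    def score(self, weights) -> np.ndarray:
        p = expit(self.X @ np.asarray(weights, dtype=float))
        return self.X.T @ (self.y - p)

    def hessian(self, weights) -> np.ndarray:
        p = expit(self.X @ np.asarray(weights, dtype=float))
        w = p * (1.0 - p)
        return -(self.X * w[:, None]).T @ self.X

    def fit(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        separation_bound: float = SEPARATION_BOUND,
    ) -> "ChoiceLogitResults":
        _check_rank(self.X, self.spec.param_names)
        w, ll, niter, gnorm, trace, conv = _newton(
            self.loglike,
            lambda b: (self.score(b), self.hessian(b)),
            self.spec.n_params,
            tol,
            max_iter,
            separation_bound,
        )
        p = expit(self.X @ w)
        _check_perfect_prediction(np.where(self.y == 1, 1.0 - p, p))
        cov = np.linalg.inv(-self.hessian(w))
        return ChoiceLogitResults(
            spec=self.spec,
            params=w,
            cov_params=cov,
            llf=ll,
            llnull=self.loglike_null(),
            n_obs=len(self.y),
            niter=niter,
            grad_norm=gnorm,
            converged=conv,
            ll_trace=tuple(trace),
            dataset=self.dataset,
            model_kind="binary logit",
        )


class MultinomialChoiceLogit:
    """Conditional (multinomial) logit over alternative sets.

    P(i) = exp(V_i) / sum_j exp(V_j) with V_j = x_j'b. With 2
    alternatives {opt-out, profile} this reduces exactly to the binary
    model; both are implemented independently so they can cross-check
    each other.
    """

    def __init__(self, dataset: MultinomialChoiceDataset):
        self.dataset = dataset
        self.spec = dataset.spec
        self.A = dataset.coded_array()  # (n, J, K)
        self.y = dataset.responses()
        n = len(self.y)
        self._chosen = self.A[np.arange(n), self.y, :]  # (n, K)

    def loglike(self, weights) -> float:
        V = self.A @ np.asarray(weights, dtype=float)  # (n, J)
        chosen_v = V[np.arange(len(self.y)), self.y]
        return float(np.sum(chosen_v - logsumexp(V, axis=1)))

    def loglike_null(self) -> float:
        return -len(self.y) * np.log(self.dataset.n_alternatives)

    def _probs(self, weights) -> np.ndarray:
        V = self.A @ np.asarray(weights, dtype=float)
        V = V - V.max(axis=1, keepdims=True)
        e = np.exp(V)
        return e / e.sum(axis=1, keepdims=True)

    def score(self, weights) -> np.ndarray:
        P = self._probs(weights)  # (n, J)
        xbar = np.einsum("nj,njk->nk", P, self.A)
        return (self._chosen - xbar).sum(axis=0)

    def hessian(self, weights) -> np.ndarray:
        P = self._probs(weights)
        xbar = np.einsum("nj,njk->nk", P, self.A)  # (n, K)
        second = np.einsum("nj,njk,njl->kl", P, self.A, self.A)
        outer = np.einsum("nk,nl->kl", xbar, xbar)
        return -(second - outer)

    def fit(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        separation_bound: float = SEPARATION_BOUND,
    ) -> "ChoiceLogitResults":
        # identification check on the stacked alternative-difference matrix
        diffs = (self.A - self.A[:, :1, :]).reshape(-1, self.spec.n_params)
        _check_rank(diffs, self.spec.param_names)
        w, ll, niter, gnorm, trace, conv = _newton(
            self.loglike,
            lambda b: (self.score(b), self.hessian(b)),
            self.spec.n_params,
            tol,
            max_iter,
            separation_bound,
        )
        P = self._probs(w)
        _check_perfect_prediction(1.0 - P[np.arange(len(self.y)), self.y])
        cov = np.linalg.inv(-self.hessian(w))
        return ChoiceLogitResults(
            spec=self.spec,
            params=w,
            cov_params=cov,
            llf=ll,
            llnull=self.loglike_null(),
            n_obs=len(self.y),
            niter=niter,
            grad_norm=gnorm,
            converged=conv,
            ll_trace=tuple(trace),
            dataset=self.dataset,
            model_kind="multinomial logit",
        )


# ----------------------------------------------------------------------
# results


@dataclass
class ChoiceLogitResults:
    """Estimated weights with uncertainty, fit statistics and reporting.

    Can also be constructed from stored estimates (a fit file) without
    refitting; in that case ``cov_params`` may be absent and Wald
    inference falls back to any stored p-values.
    """

    spec: ExperimentSpec
    params: np.ndarray
    llf: Optional[float] = None
    llnull: Optional[float] = None
    cov_params: Optional[np.ndarray] = None
    n_obs: Optional[int] = None
    niter: Optional[int] = None
    grad_norm: Optional[float] = None
    converged: Optional[bool] = None
    ll_trace: tuple = ()
    dataset: object = None
    model_kind: str = "binary logit"
    stored_pvalues: Optional[np.ndarray] = None

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} weights, got {self.params.shape}"
            )
        if self.cov_params is not None:
            self.cov_params = np.asarray(self.cov_params, dtype=float)
        if self.stored_pvalues is not None:
            self.stored_pvalues = np.asarray(self.stored_pvalues, dtype=float)

    # -- construction from stored estimates ----------------------------
    @classmethod
    def from_estimates(
        cls,
        spec: ExperimentSpec,
        weights,
        llf: Optional[float] = None,
        llnull: Optional[float] = None,
        cov_params=None,
        pvalues=None,
        n_obs: Optional[int] = None,
        model_kind: str = "binary logit",
    ) -> "ChoiceLogitResults":
        """Build a results object from a weight mapping or array."""
        names = spec.param_names
        if isinstance(weights, dict):
            missing = [n for n in names if n not in weights]
            if missing:
                raise ValueError(f"missing weight(s) for parameter(s): {missing}")
            extra = [n for n in weights if n not in names]
            if extra:
                raise ValueError(f"unknown parameter name(s): {extra}")
            arr = np.array([float(weights[n]) for n in names])
        else:
            arr = np.asarray(weights, dtype=float)
        pv = None
        if pvalues is not None:
            if isinstance(pvalues, dict):
                pv = np.array([float(pvalues.get(n, np.nan)) for n in names])
            else:
                pv = np.asarray(pvalues, dtype=float)
        return cls(
            spec=spec,
            params=arr,
            llf=llf,
            llnull=llnull,
            cov_params=None if cov_params is None else np.asarray(cov_params),
            stored_pvalues=pv,
            n_obs=n_obs,
            model_kind=model_kind,
        )

    # -- basic accessors ------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names, name="weight")

    @property
    def bse(self) -> Optional[np.ndarray]:
        if self.cov_params is None:
            return None
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> Optional[np.ndarray]:
        se = self.bse
        if se is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / se

    @property
    def pvalues(self) -> Optional[np.ndarray]:
        z = self.zvalues
        if z is None:
            return self.stored_pvalues
        return 2.0 * norm.sf(np.abs(z))

    @property
    def prsquared(self) -> Optional[float]:
        """McFadden's rho-squared: 1 - LL / LL_null."""
        if self.llf is None or self.llnull is None:
            return None
        return 1.0 - self.llf / self.llnull

    # -- prediction ------------------------------------------------------
    def linear_utility(self, profile: Profile) -> float:
        self.spec.require_feasible(profile)
        return float(self.spec.encode(profile) @ self.params)

    def predict(self, profile: Profile) -> float:
        """P(recommend the action) for one feasible profile."""
        return float(expit(self.linear_utility(profile)))

    def predict_many(self, profiles: Sequence[Profile]) -> np.ndarray:
        for p in profiles:
            self.spec.require_feasible(p)
        return expit(self.spec.encode_many(profiles) @ self.params)

    # -- importance / assessment (delegated) ------------------------------
    def part_worth_range(self, factor_name: str) -> float:
        from .importance import part_worth_range

        return part_worth_range(self, self.spec.factor(factor_name))

    def relative_importance(self):
        from .importance import relative_importance

        return relative_importance(self)

    def assess(self, profile: Profile, significance_mask: bool = False):
        from .importance import assess_profile

        return assess_profile(self, profile, significance_mask=significance_mask)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = []
        lines.append(f"Expert choice model: {self.model_kind}")
        lines.append(f"Decision: {self.spec.decision_label}")
        if self.n_obs is not None:
            lines.append(f"Number of observations (N) = {self.n_obs}")
        if self.llnull is not None:
            lines.append(f"Null log-likelihood = {self.llnull:.2f}")
        if self.llf is not None:
            lines.append(f"Log-likelihood of estimated model = {self.llf:.2f}")
        if self.prsquared is not None:
            lines.append(f"McFadden's rho-squared = {self.prsquared:.2f}")
        lines.append("")
        header = f"{'Factor':<42}{'Level':<30}{'Weight':>9}  {'P value':>8}"
        lines.append(header)
        lines.append("-" * len(header))
        pv = self.pvalues
        idx = 1
        lines.append(self._row("Constant", "", self.params[0],
                               None if pv is None else pv[0]))
        for f in self.spec.factors:
            if f.coding == "dummy":
                lines.append(self._row(f.name, f.levels[0], 0.0, None))
                for lv in f.levels[1:]:
                    lines.append(
                        self._row("", lv, self.params[idx],
                                  None if pv is None else pv[idx])
                    )
                    idx += 1
            else:
                lines.append(
                    self._row(f.name, "(per level step)", self.params[idx],
                              None if pv is None else pv[idx])
                )
                idx += 1
        for name in self.param_names[idx:]:
            lines.append(
                self._row(name, "", self.params[idx],
                          None if pv is None else pv[idx])
            )
            idx += 1
        return "\n".join(lines)

    @staticmethod
    def _row(factor, level, weight, p) -> str:
        ptxt = "" if p is None or not np.isfinite(p) else f"{p:.3g}"
        return f"{factor:<42}{level:<30}{weight:>9.3f}  {ptxt:>8}"

    def to_dict(self) -> dict:
        d = {
            "model_kind": self.model_kind,
            "weights": {n: float(v) for n, v in zip(self.param_names, self.params)},
            "log_likelihood": self.llf,
            "null_log_likelihood": self.llnull,
            "mcfadden_rho2": self.prsquared,
            "n_observations": self.n_obs,
            "converged": self.converged,
            "n_iterations": self.niter,
            "gradient_max_norm": self.grad_norm,
        }
        pv = self.pvalues
        if pv is not None:
            d["p_values"] = {
                n: (None if not np.isfinite(v) else float(v))
                for n, v in zip(self.param_names, pv)
            }
        if self.cov_params is not None:
            d["covariance"] = self.cov_params.tolist()
        return d


# ----------------------------------------------------------------------
# module-level operations mirroring the functional surface


def log_likelihood(weights, dataset) -> float:
    """Log-likelihood of ``weights`` on a binary or multinomial dataset."""
    if isinstance(dataset, MultinomialChoiceDataset):
        return MultinomialChoiceLogit(dataset).loglike(weights)
    return ChoiceLogit(dataset).loglike(weights)


def fit_logit(
    dataset,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ChoiceLogitResults:
    """Fit the appropriate logit model for the dataset type."""
    if isinstance(dataset, MultinomialChoiceDataset):
        return MultinomialChoiceLogit(dataset).fit(tol=tol, max_iter=max_iter)
    return ChoiceLogit(dataset).fit(tol=tol, max_iter=max_iter)


def mcfadden_rho2(fit: ChoiceLogitResults) -> float:
    """1 - LL/LL_null with the all-weights-zero (equal shares) null."""
    if fit.llf is None or fit.llnull is None:
        raise ValueError("fit does not carry both log-likelihoods")
    return 1.0 - fit.llf / fit.llnull


def wald_inference(fit: ChoiceLogitResults) -> pd.DataFrame:
    """Per-parameter standard error, z statistic and two-sided p-value."""
    se = fit.bse
    if se is None:
        raise ValueError(
            "fit carries no covariance matrix; Wald inference unavailable"
        )
    z = fit.params / se
    return pd.DataFrame(
        {"weight": fit.params, "se": se, "z": z, "p": 2.0 * norm.sf(np.abs(z))},
        index=fit.param_names,
    )


def predicted_observed_mad(fit: ChoiceLogitResults, dataset: ChoiceDataset) -> float:
    """Mean absolute deviation, in percentage points, between the model's
    predicted P(yes) and the observed share of yes per unique scenario."""
    groups: dict[Profile, list[int]] = {}
    for o in dataset.observations:
        groups.setdefault(o.profile, []).append(o.choice)
    devs = []
    for profile, choices in groups.items():
        predicted = fit.predict(profile)
        observed = float(np.mean(choices))
        devs.append(abs(predicted - observed) * 100.0)
    return float(np.mean(devs))
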