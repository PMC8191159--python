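"""Synthetic expert panels with known ground truth.

Every downstream module is testable without real study data: a
simulated panel of experts answers a design's scenarios according to a
binary logit with known true weights. Optional expert heterogeneity
perturbs each expert's weight vector with independent Gaussian noise (a
simple stand-in for a mixed-logit data-generating process; the
*estimator* remains a plain logit).

`parameter_recovery` runs the full simulate-and-refit loop across
replicates and reports bias, RMSE and Wald-interval coverage per
parameter — the end-to-end check that estimation recovers what the
panel encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .design import Design
from .estimation import ChoiceDataset, ChoiceLogit, ChoiceObservation
from .exceptions import ExpertChoiceError
from .experiment import ExperimentSpec

__all__ = ["SimulationConfig", "RecoveryReport", "simulate_choices", "parameter_recovery"]

_Z975 = norm.ppf(0.975)


@dataclass
class SimulationConfig:
    """A simulated panel: who answers, what they answer, and how noisily.

    Parameters
    ----------
    spec, design : the decision problem and the scenarios presented.
    true_weights : array of length spec.n_params (intercept first),
        in utility units per coded unit.
    n_experts : panel size; every expert answers every scenario.
    heterogeneity_sd : standard deviation of the independent Gaussian
        perturbation added to each weight for each expert; 0 gives a
        homogeneous panel.
    seed : master seed; all randomness derives from it.
    """

    spec: ExperimentSpec
    design: Design
    true_weights: np.ndarray
    n_experts: int = 15
    heterogeneity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if self.true_weights.shape != (self.spec.n_params,):
            raise ValueError(
                f"true_weights must have length {self.spec.n_params}, "
                f"got shape {self.true_weights.shape}"
            )
        if self.n_experts < 1:
            raise ValueError("n_experts must be positive")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be nonnegative")


def simulate_choices(config: SimulationConfig) -> ChoiceDataset:
    """Draw one full panel's worth of choices; deterministic given seed.

    Output contains n_experts * n_scenarios observations, ordered by
    expert then scenario.
    """
    for p in config.design.scenarios:
        config.spec.require_feasible(p)
    rng = np.random.default_rng(config.seed)
    X = config.design.coded_matrix()
    n = X.shape[0]
    observations = []
    width = max(2, len(str(config.n_experts)))
    for e in range(config.n_experts):
        w = config.true_weights
        if config.heterogeneity_sd > 0:
            w = w + rng.normal(0.0, config.heterogeneity_sd, size=w.shape)
        p_yes = expit(X @ w)
        draws = rng.random(n)
        expert_id = f"expert_{e + 1:0{width}d}"
        for s, scenario in enumerate(config.design.scenarios):
            observations.append(
                ChoiceObservation(expert_id, scenario, int(draws[s] < p_yes[s]))
            )
    return ChoiceDataset(config.spec, tuple(observations))


@dataclass
class RecoveryReport:
    """Aggregate simulate-and-refit performance per parameter."""

    param_names: tuple[str, ...]
    true: np.ndarray
    mean_estimate: np.ndarray
    bias: np.ndarray
    sd: np.ndarray  # empirical SD of estimates (population form)
    rmse: np.ndarray  # satisfies rmse**2 = bias**2 + sd**2
    coverage: np.ndarray  # share of nominal 95% Wald intervals covering truth
    n_replicates: int
    n_failed: int
    seeds: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true": self.true,
                "mean": self.mean_estimate,
                "bias": self.bias,
                "sd": self.sd,
                "rmse": self.rmse,
                "coverage95": self.coverage,
            },
            index=list(self.param_names),
        )


def parameter_recovery(
    config: SimulationConfig, n_replicates: int, tol: float = 1e-8, max_iter: int = 100
) -> RecoveryReport:
    """Simulate + fit across replicates; aggregate bias, RMSE, coverage.

    Replicate r uses seed ``config.seed + r`` so each replicate is
    individually reproducible. Replicates whose fit fails (separation,
    non-convergence, rank deficiency) are excluded from the aggregates
    and counted in ``n_failed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    estimates, ses, seeds = [], [], []
    n_failed = 0
    for r in range(n_replicates):
        rep = replace(config, seed=config.seed + r)
        dataset = simulate_choices(rep)
        try:
            fit = ChoiceLogit(dataset).fit(tol=tol, max_iter=max_iter)
        except ExpertChoiceError:
            n_failed += 1
            continue
        estimates.append(fit.params)
        ses.append(fit.bse)
        seeds.append(rep.seed)
    if not estimates:
        raise ExpertChoiceError(
            f"all {n_replicates} replicates failed to converge"
        )
    est = np.asarray(estimates)
    se = np.asarray(ses)
    truth = config.true_weights
    mean_est = est.mean(axis=0)
    bias = mean_est - truth
    sd = est.std(axis=0, ddof=0)
    rmse = np.sqrt(bias**2 + sd**2)
    covered = np.abs(est - truth) <= _Z975 * se
    return RecoveryReport(
        param_names=tuple(config.spec.param_names),
        true=truth,
        mean_estimate=mean_est,
        bias=bias,
        sd=sd,
        rmse=rmse,
        coverage=covered.mean(axis=0),
        n_replicates=len(estimates),
        n_failed=n_failed,
        seeds=tuple(seeds),
    )
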