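# Methods

## The choice model

The core model is a binary logit of an expert's yes/no recommendation.
A profile assigns one level to each of F factors; the coded row
`x = (1, c₁, …)` contains an intercept and per-factor codes:

* **dummy coding** — a factor with L levels contributes L−1 indicators;
  the first listed level is the reference with part-worth fixed at 0.
  Use when the effect of moving across levels may be nonlinear.
* **linear coding** — one coefficient multiplying the level index
  0..L−1 in listed order. Levels are listed from least to most
  favourable for the action, so the index is an equally spaced "score".
  The three-level cerebral-oxygen-saturation factor (NIRS 40/60/80) is
  likewise coded by level index, not per physical unit: its published
  weight is per step of the range, and step coding keeps all linear
  factors on a common scale.
* **interactions** — optional pairwise products of the two factors'
  coded columns (one term for linear×linear, a block for dummy
  factors). Attribution reports them as their own row rather than
  splitting them between the parent factors.

The probability of a "yes" is `expit(x'β)`. Multinomial (conditional)
logit generalises to choice sets: `P(i) = exp(x_i'β)/Σ_j exp(x_j'β)`,
with an optional opt-out alternative of fixed zero utility. A set made
only of real profiles cannot identify the intercept (it cancels in
utility differences); the rank check rejects such data, and the
single-conjoint case corresponds to the set {opt-out, profile}.

Observations are treated as independent across experts and scenarios.
Panel correlation (mixed logit) is deliberately out of scope as an
estimator; the simulator can still *generate* heterogeneous panels to
study the consequences.

## Estimation

Newton–Raphson from a zero start on the exact log-likelihood
(gradient `Σ(y−p)x`, Hessian `−Σp(1−p)xx'` for the binary model),
with step-halving whenever a full step would decrease the
log-likelihood — the likelihood is concave, so iterates are then
monotonically non-decreasing by construction. Convergence is declared
at gradient max-norm < 1e−8 (default) within 100 iterations. The
covariance matrix is the inverse negative Hessian at the solution;
p-values are two-sided Wald against the standard normal.

Degenerate inputs are diagnosed rather than repaired:

* rank-deficient coded matrices are rejected with the collinear
  columns named (pivoted QR);
* complete separation is flagged two ways: any weight exceeding 50 in
  magnitude during iteration, and — because the gradient tolerance is
  typically met near |w| ≈ 20 before that bound — a post-convergence
  check that raises when every observation's observed choice is
  predicted with probability within 1e−6 of 1. No penalised fallback is
  provided; with small expert panels, separation is a finding.

McFadden's ρ² uses the all-weights-zero null (every alternative equally
likely), not an intercept-only null: the equal-shares null makes
`LL₀ = N·ln(1/2)` for binary data, e.g. −363.90 for N = 525, and is the
convention under which the bundled case-study numbers are coherent.

Model calibration is summarised by the mean absolute deviation, in
percentage points, between predicted choice probability and the
observed "yes" share per unique scenario (unweighted over scenarios).

## Efficient design

Scenario sets are scored by the D-error `det(I(β₀))^(−1/K)` of the
binary-logit Fisher information `I = Σ p(1−p)xx'` under prior weights
β₀. Defaults are utility-neutral priors (all zero, every p = 1/2);
informative priors may be supplied. The search is coordinate exchange
with multi-start: begin at a uniform random feasible design, sweep
scenario×factor cells replacing each level by the feasible alternative
that strictly reduces D-error (ties keep the incumbent, for
determinism), stop when a pass brings no improvement or after
`max_passes`; the best of `n_starts` restarts wins. Restart r uses seed
`seed + r`, so the first restart's starting point is exactly
`random_design(spec, n, seed)` — the returned design can never be worse
than that baseline. `n_scenarios < K` triggers a warning (a replicated
panel can still identify the model) but any all-singular search errors
out. On small problems the exchange recovers the exhaustively verified
optimum in the large majority of seeded runs; this is a heuristic, not
a guarantee.

Random feasible designs are drawn uniformly without replacement —
directly when the unconstrained profile space is small enough to
enumerate (≤100,000), by rejection sampling of level combinations
otherwise.

## Simulated panels and parameter recovery

`simulate_choices` draws, per expert, a weight vector
`β_e = β + N(0, σ²I)` (σ = `heterogeneity_sd`, default 0) and Bernoulli
choices at `expit(Xβ_e)` for every scenario. All randomness flows from
one `numpy` Generator seeded with the master seed; replicate r of a
recovery study reuses the config with seed `seed + r` so any replicate
can be reproduced alone. The defaults mirror the bundled case study's
panel: 15 experts, 35 scenarios, hence 525 observations.

`parameter_recovery` reports per parameter the mean estimate, bias,
empirical SD (population form, so RMSE² = bias² + SD² holds exactly),
RMSE and the coverage of nominal 95% Wald intervals; replicates whose
fit fails (separation, rank deficiency, non-convergence) are excluded
from the aggregates but counted — at expert-panel sizes the failure
rate is itself informative.

What the simulator does **not** emulate: response fatigue, learning or
inattention; within-expert correlation beyond the weight perturbation;
real patients (scenario profiles are hypothetical by design). Passing
recovery tests therefore demonstrate the statistical machinery under
the model's own assumptions, not clinical validity of any fitted model.

## Importance and assessments

A factor's part-worth range is `max − min` over its level part-worths
(dummy: the level weights with 0 for the reference; linear:
`coefficient × (L−1)`). Its importance share is its range over the sum
of ranges, in percent; ranks break ties by spec order. Shares are
invariant to shifting a factor's part-worths by a constant and strictly
increasing in the factor's own range.

Per-profile assessments decompose the utility
`V = β₀ + Σ_f pw_f(level_f) (+ interaction terms)` and report each
factor's contribution centered on its within-factor mean part-worth.
Centering is what lets both favourable and unfavourable levels appear
even though reference-zero coding makes all raw weights one-signed: a
level below the factor's mean shows red (negative), above it green
(positive), within ±1e−9 neutral. An optional significance mask
additionally forces factors to neutral when their smallest parameter
p-value is ≥ 0.05 ("did not contribute" in reporting terms); it is off
by default because contribution sign and statistical significance are
distinct statements.

## Numerical choices

* log-likelihoods use `log_expit` / `logsumexp`; finite for |V| ≤ 700.
* D-error via `slogdet`; non-positive determinants map to +∞ inside the
  search and to a `SingularDesignError` at the public surface.
* Exchange acceptance requires improvement > 1e−12 (absolute), so
  floating-point ties keep the incumbent and runs are deterministic.
* Wald coverage uses z = Φ⁻¹(0.975) = 1.959964.
* Censored published p-values ("<0.001") are stored in the fixture at
  0.0005, the midpoint of the censoring interval; any sub-0.001 value
  leaves masking behaviour unchanged.

## Problem sizes used in the shipped studies

The test suite and acceptance studies run at the bundled case study's
own scale — 35 scenarios, 15 experts, 525 observations, 22 parameters —
with 200 simulate-and-refit replicates for the coverage study and a
35-scenario design searched with 3 restarts × ≤10 passes. Small
synthetic specs (2–4 factors) back the exhaustive-search and
closed-form oracles.

## Known limitations

* Only binary and multinomial logit are estimated; nested logit, panel
  mixed logit, regret-minimisation and taboo-tradeoff families are out
  of scope, as are Firth-type separation repairs, clustered standard
  errors and likelihood-ratio inference.
* Constraints are conjunctive forbidden tuples; implications and range
  logic must be expanded into tuples by the user.
* D-efficiency is local (fixed priors), not Bayesian over a prior
  distribution, and designs are not blocked across experts — every
  expert is assumed to answer every scenario.
* The bundled fit fixture carries no covariance matrix (none was
  published), so Wald standard errors are unavailable for it; stored
  p-values support the significance mask instead.
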