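"""Relative importance of decision factors and explainable assessments.

Two outputs are derived from a fitted choice model:

* the conjoint part-worth-range importance ranking — a factor's range is
  the spread between its largest and smallest level part-worth, and its
  importance share is that range divided by the sum of all factors'
  ranges;
* a per-profile assessment — the predicted probability that a randomly
  sampled expert from the panel would recommend the action, together
  with a signed per-factor contribution. Contributions are centered on
  the factor's mean part-worth so that both favourable (positive/green)
  and unfavourable (negative/red) deviations appear even though
  reference-zero coding makes all raw weights one-signed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateModelError
from .experiment import ExperimentSpec, Factor, Profile

NEUTRAL_EPS = 1e-9

__all__ = [
    "ImportanceTable",
    "Assessment",
    "FactorContribution",
    "part_worths",
    "part_worth_range",
    "relative_importance",
    "assess_profile",
    "importance_report",
]


def _param_slices(spec: ExperimentSpec) -> dict[str, slice]:
    """Map each factor name to its slice of the parameter vector."""
    out = {}
    idx = 1  # skip intercept
    for f in spec.factors:
        out[f.name] = slice(idx, idx + f.n_params)
        idx += f.n_params
    return out


def part_worths(fit, factor: Factor) -> np.ndarray:
    """Per-level part-worth utilities of one factor (reference level = 0)."""
    sl = _param_slices(fit.spec)[factor.name]
    w = fit.params[sl]
    if factor.coding == "dummy":
        return np.concatenate([[0.0], w])
    return w[0] * np.arange(factor.n_levels, dtype=float)


def part_worth_range(fit, factor: Factor) -> float:
    """Spread of a factor's part-worths: max - min over its levels."""
    pw = part_worths(fit, factor)
    return float(pw.max() - pw.min())


@dataclass
class ImportanceTable:
    """Per-factor part-worth ranges, importance shares (%) and ranks."""

    factors: tuple[str, ...]
    ranges: np.ndarray
    shares: np.ndarray  # percent, sums to 100
    ranks: np.ndarray  # 1 = most important

    def __len__(self) -> int:
        return len(self.factors)

    def share(self, factor: str) -> float:
        return float(self.shares[self.factors.index(factor)])

    def rank(self, factor: str) -> int:
        return int(self.ranks[self.factors.index(factor)])

    def cumulative_share(self, k: int) -> float:
        """Summed share of the k most important factors."""
        order = np.argsort(self.ranks)
        return float(self.shares[order[:k]].sum())

    def to_dict(self) -> dict:
        by_rank = np.argsort(self.ranks)
        return {
            "factors": [
                {
                    "factor": self.factors[i],
                    "range": float(self.ranges[i]),
                    "share_pct": float(self.shares[i]),
                    "rank": int(self.ranks[i]),
                }
                for i in by_rank
            ],
            "cumulative_share_pct": [
                float(self.shares[by_rank[: k + 1]].sum())
                for k in range(len(self.factors))
            ],
        }


def relative_importance(fit) -> ImportanceTable:
    """Part-worth-range importance shares, ranked descending.

    Ties are broken by the spec's factor order (earlier factor gets the
    better rank). Raises :class:`DegenerateModelError` when every range
    is zero.
    """
    spec = fit.spec
    names = tuple(f.name for f in spec.factors)
    ranges = np.array([part_worth_range(fit, f) for f in spec.factors])
    total = ranges.sum()
    if total <= 0:
        raise DegenerateModelError(
            "all part-worth ranges are zero; importance shares undefined"
        )
    shares = ranges / total * 100.0
    # stable sort on negated shares preserves spec order among ties
    order = np.argsort(-shares, kind="stable")
    ranks = np.empty(len(names), dtype=int)
    ranks[order] = np.arange(1, len(names) + 1)
    return ImportanceTable(names, ranges, shares, ranks)


@dataclass
class FactorContribution:
    """One display row of an assessment."""

    name: str  # factor name, or interaction term label
    level: Optional[str]  # level shown (None for interaction rows)
    part_worth: float  # uncentered utility contribution
    centered: float  # contribution relative to the factor's mean part-worth
    color: str  # "positive" | "negative" | "neutral"
    p_value: Optional[float] = None


@dataclass
class Assessment:
    """Probabilistic, explained assessment of one decision profile."""

    profile: Profile
    utility: float
    probability: float
    intercept: float
    contributions: tuple[FactorContribution, ...]
    significance_mask: bool = False

    def to_dict(self) -> dict:
        return {
            "utility": self.utility,
            "probability": self.probability,
            "intercept": self.intercept,
            "significance_mask": self.significance_mask,
            "factors": [
                {
                    "name": c.name,
                    "level": c.level,
                    "part_worth": c.part_worth,
                    "centered_contribution": c.centered,
                    "color": c.color,
                    "p_value": c.p_value,
                }
                for c in self.contributions
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"P(recommend) = {self.probability:.3f}   (utility {self.utility:+.3f})",
            f"{'Factor':<42}{'Level':<30}{'Contribution':>13}  {'Color':>9}",
        ]
        for c in self.contributions:
            lines.append(
                f"{c.name:<42}{(c.level or ''):<30}{c.centered:>+13.3f}  {c.color:>9}"
            )
        return "\n".join(lines)


def _color(centered: float, eps: float = NEUTRAL_EPS) -> str:
    if centered > eps:
        return "positive"
    if centered < -eps:
        return "negative"
    return "neutral"


def _factor_pvalues(fit) -> Optional[dict[str, float]]:
    """Smallest parameter p-value per factor (None if no inference)."""
    pv = fit.pvalues
    if pv is None:
        return None
    slices = _param_slices(fit.spec)
    out = {}
    for name, sl in slices.items():
        vals = np.asarray(pv[sl], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.min()) if vals.size else np.nan
    return out


def assess_profile(fit, profile: Profile, significance_mask: bool = False) -> Assessment:
    """Decompose a profile's predicted probability into factor contributions.

    The centered contribution of a factor is its part-worth at the
    profile's level minus the mean part-worth over that factor's levels.
    Colors: positive / negative when the centered contribution exceeds
    +-1e-9, neutral otherwise. With ``significance_mask=True``, factors
    whose smallest parameter p-value is >= 0.05 are forced to neutral
    ("did not contribute").
    """
    spec = fit.spec
    spec.require_feasible(profile)
    utility = float(spec.encode(profile) @ fit.params)
    probability = 1.0 / (1.0 + np.exp(-utility))
    fac_p = _factor_pvalues(fit) if significance_mask else None
    if significance_mask and fac_p is None:
        raise ValueError(
            "significance mask requested but the fit carries no p-values"
        )
    contributions = []
    for f, level in zip(spec.factors, profile.levels):
        pw = part_worths(fit, f)
        at_level = float(pw[f.level_index(level)])
        centered = at_level - float(pw.mean())
        color = _color(centered)
        p = None if fac_p is None else fac_p[f.name]
        if fac_p is not None and (not np.isfinite(p) or p >= 0.05):
            color = "neutral"
        contributions.append(
            FactorContribution(f.name, level, at_level, centered, color, p)
        )
    # interaction terms are displayed as their own rows, centered over the
    # full cross of the two factors' levels (feasibility ignored for the mean)
    if spec.interactions:
        names = spec.param_names
        idx = 1 + sum(f.n_params for f in spec.factors)
        pv = fit.pvalues
        for a, b in spec.interactions:
            fa, fb = spec.factor(a), spec.factor(b)
            n_terms = fa.n_params * fb.n_params
            w = fit.params[idx : idx + n_terms]
            ca = fa.coded_columns(profile.levels[spec.factor_names.index(a)])
            cb = fb.coded_columns(profile.levels[spec.factor_names.index(b)])
            x = np.outer(ca, cb).ravel()
            value = float(w @ x)
            # mean of the term over all level combinations of a and b
            mean_val = 0.0
            for la in fa.levels:
                for lb in fb.levels:
                    xa = np.outer(fa.coded_columns(la), fb.coded_columns(lb)).ravel()
                    mean_val += float(w @ xa)
            mean_val /= fa.n_levels * fb.n_levels
            centered = value - mean_val
            color = _color(centered)
            p = None
            if pv is not None:
                vals = np.asarray(pv[idx : idx + n_terms], dtype=float)
                vals = vals[np.isfinite(vals)]
                p = float(vals.min()) if vals.size else None
            if significance_mask and (p is None or p >= 0.05):
                color = "neutral"
            contributions.append(
                FactorContribution(f"{a}:{b}", None, value, centered, color, p)
            )
            idx += n_terms
    return Assessment(
        profile=profile,
        utility=utility,
        probability=float(probability),
        intercept=float(fit.params[0]),
        contributions=tuple(contributions),
        significance_mask=significance_mask,
    )


def importance_report(table: ImportanceTable, as_json: bool = False) -> str:
    """Human- or machine-readable ranking with cumulative shares."""
    if as_json:
        return json.dumps(table.to_dict(), indent=2)
    lines = [f"{'Rank':>4}  {'Factor':<42}{'Range':>8}  {'Share':>7}  {'Cum.':>7}"]
    order = np.argsort(table.ranks)
    cum = 0.0
    for i in order:
        cum += table.shares[i]
        lines.append(
            f"{table.ranks[i]:>4}  {table.factors[i]:<42}"
            f"{table.ranges[i]:>8.3f}  {table.shares[i]:>6.1f}%  {cum:>6.1f}%"
        )
    return "\n".join(lines)
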