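"""End-to-end orchestration: design -> choices -> fit -> importance -> assessments.

One call runs the whole workflow on a spec, either simulating a panel
from supplied true weights or ingesting real choices, and returns a
consolidated report. With an output directory, every stage's inputs and
outputs are persisted (CSV/JSON, no timestamps, so identical inputs and
seed give byte-identical files).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as ecio
from .design import design_diagnostics, generate_design
from .estimation import ChoiceDataset, ChoiceLogit, predicted_observed_mad
from .experiment import ExperimentSpec, validate_spec
from .importance import assess_profile, relative_importance
from .simulate import SimulationConfig, simulate_choices

logger = logging.getLogger("expertchoice")

__all__ = ["run_pipeline"]


def _log_stage(stage: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)


def run_pipeline(
    spec: ExperimentSpec,
    n_scenarios: int = 35,
    n_experts: int = 15,
    true_weights=None,
    dataset: Optional[ChoiceDataset] = None,
    heterogeneity_sd: float = 0.0,
    seed: int = 0,
    n_starts: int = 10,
    outdir=None,
    assess_profiles=None,
) -> dict:
    """Run the full workflow; returns the consolidated report dict.

    Either ``true_weights`` (simulate a panel) or ``dataset`` (real
    choices) must be given. ``assess_profiles`` is an optional mapping
    of label -> Profile to assess with the fitted model; by default the
    all-reference and all-best profiles are assessed.
    """
    findings = validate_spec(spec)
    if findings:
        raise ValueError("invalid spec: " + "; ".join(findings))
    if (true_weights is None) == (dataset is None):
        raise ValueError("provide exactly one of true_weights or dataset")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    design = generate_design(
        spec, n_scenarios, seed=seed, n_starts=n_starts
    )
    _log_stage("design", t0, n=n_scenarios, seed=seed,
               d_error=f"{design.metadata['d_error']:.4f}")
    if outdir is not None:
        ecio.write_design(design, outdir / "design.csv")

    t0 = time.perf_counter()
    if dataset is None:
        config = SimulationConfig(
            spec=spec,
            design=design,
            true_weights=np.asarray(true_weights, dtype=float),
            n_experts=n_experts,
            heterogeneity_sd=heterogeneity_sd,
            seed=seed,
        )
        dataset = simulate_choices(config)
        _log_stage("simulate", t0, n=len(dataset), experts=n_experts, seed=seed)
    if outdir is not None:
        ecio.write_choices(dataset, outdir / "choices.csv")

    t0 = time.perf_counter()
    fit = ChoiceLogit(dataset).fit()
    _log_stage("fit", t0, n=len(dataset),
               llf=f"{fit.llf:.2f}", rho2=f"{fit.prsquared:.3f}")
    if outdir is not None:
        ecio.write_fit(fit, outdir / "fit.json")

    importance = relative_importance(fit)
    if assess_profiles is None:
        assess_profiles = {
            "all_reference": spec.reference_profile(),
            "all_best": spec.best_profile(),
        }
    assessments = {
        label: assess_profile(fit, profile).to_dict()
        for label, profile in assess_profiles.items()
    }
    report = {
        "decision_label": spec.decision_label,
        "design": {
            "n_scenarios": n_scenarios,
            "metadata": design.metadata,
            "diagnostics": design_diagnostics(design),
        },
        "data": {"n_observations": len(dataset), "n_experts": n_experts},
        "fit": fit.to_dict(),
        "importance": importance.to_dict(),
        "predicted_observed_mad_pct": predicted_observed_mad(fit, dataset),
        "assessments": assessments,
        "seed": int(seed),
    }
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
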