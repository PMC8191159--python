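"""Bundled case-study fixtures: the neonatal NEC surgery decision.

The package ships the published case study of the surgery-versus-
comfort-care decision for a critically ill preterm neonate with
necrotizing enterocolitis (NEC): the 14 decision criteria with their
ranges, the panel-estimated factor weights (binary logit, 15 experts x
35 scenarios = 525 observations), and three example patient profiles.
These fixtures let every part of the toolkit be exercised without any
real choice data; the stored weights also seed realistic simulations.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .estimation import ChoiceLogitResults
from .experiment import ExperimentSpec, Profile
from .io import _profiles_from_frame, fit_from_dict, spec_from_dict

import json

import yaml

__all__ = ["load_nec_spec", "load_nec_fit", "load_nec_example_profiles"]


def _fixture_text(name: str) -> str:
    return resources.files("expertchoice.fixtures").joinpath(name).read_text()


def load_nec_spec() -> ExperimentSpec:
    """The NEC decision problem: 14 factors with their level ranges."""
    doc = yaml.safe_load(_fixture_text("nec_spec.yaml"))
    return spec_from_dict(doc, context="nec_spec.yaml")


def load_nec_fit() -> ChoiceLogitResults:
    """Panel-estimated factor weights for the NEC decision.

    Carries the published weights, two-sided p-values, the model and
    null log-likelihoods (-245 and -364) and N = 525. No covariance
    matrix was published, so Wald standard errors are unavailable;
    significance masking uses the stored p-values. Printed p-values
    censored as "<0.001" are stored at 0.0005 (the midpoint of the
    censoring interval).
    """
    doc = json.loads(_fixture_text("nec_fit.json"))
    # the absence of a covariance matrix is a documented property of this
    # fixture, not a malformed file: skip the usual read warning
    logger = logging.getLogger("expertchoice")
    level = logger.level
    logger.setLevel(logging.ERROR)
    try:
        return fit_from_dict(doc, context="nec_fit.json")
    finally:
        logger.setLevel(level)


def load_nec_example_profiles() -> dict[str, Profile]:
    """Three example patients keyed 'worst', 'intermediate', 'best'.

    'worst' has every factor at its least favourable level (the
    all-reference profile), 'best' every factor at its most favourable.
    """
    import io as _io

    spec = load_nec_spec()
    df = pd.read_csv(_io.StringIO(_fixture_text("nec_profiles.csv")), dtype=str)
    profiles = _profiles_from_frame(df, spec, "nec_profiles.csv")
    return dict(zip(df["profile_id"], profiles))
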