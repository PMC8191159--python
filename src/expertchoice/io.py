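"""File formats: specs (YAML/JSON), designs and choices (CSV), fits (JSON).

Every format carries a ``schema_version`` field; unknown fields are
rejected with the offending key named, and all read/write pairs
round-trip losslessly. Tabular data (scenarios, choices) is CSV with
level labels as cell values; structured data (spec, fit, design
metadata) is YAML or JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .design import Design
from .estimation import ChoiceDataset, ChoiceLogitResults, ChoiceObservation
from .exceptions import FileFormatError
from .experiment import Constraint, ExperimentSpec, Factor, Profile

logger = logging.getLogger("expertchoice")

SCHEMA_VERSION = 1

_SPEC_KEYS = {
    "schema_version",
    "decision_label",
    "response_type",
    "factors",
    "constraints",
    "interactions",
}
_FACTOR_KEYS = {"name", "levels", "coding"}
_FIT_KEYS = {
    "schema_version",
    "spec",
    "model_kind",
    "weights",
    "p_values",
    "covariance",
    "log_likelihood",
    "null_log_likelihood",
    "mcfadden_rho2",
    "n_observations",
    "converged",
    "n_iterations",
    "gradient_max_norm",
}

PathLike = Union[str, Path]

_TRUE_CHOICES = {"1", "yes", "y", "true"}
_FALSE_CHOICES = {"0", "no", "n", "false"}


def _reject_unknown(keys, allowed, context: str) -> None:
    unknown = sorted(set(keys) - allowed)
    if unknown:
        raise FileFormatError(
            f"unknown field(s) in {context}: {', '.join(unknown)}"
        )


def _check_version(doc: dict, context: str) -> None:
    v = doc.get("schema_version")
    if v != SCHEMA_VERSION:
        raise FileFormatError(
            f"{context}: expected schema_version {SCHEMA_VERSION}, got {v!r}"
        )


# ----------------------------------------------------------------------
# spec


def spec_to_dict(spec: ExperimentSpec) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "decision_label": spec.decision_label,
        "response_type": spec.response_type,
        "factors": [
            {"name": f.name, "levels": list(f.levels), "coding": f.coding}
            for f in spec.factors
        ],
    }
    if spec.constraints:
        doc["constraints"] = [
            {"forbidden": [[f, l] for f, l in c.forbidden]}
            for c in spec.constraints
        ]
    if spec.interactions:
        doc["interactions"] = [[a, b] for a, b in spec.interactions]
    return doc


def spec_from_dict(doc: dict, context: str = "spec") -> ExperimentSpec:
    if not isinstance(doc, dict):
        raise FileFormatError(f"{context}: document must be a mapping")
    _reject_unknown(doc.keys(), _SPEC_KEYS, context)
    _check_version(doc, context)
    for key in ("decision_label", "factors"):
        if key not in doc:
            raise FileFormatError(f"{context}: missing required field {key!r}")
    factors = []
    for i, fd in enumerate(doc["factors"]):
        _reject_unknown(fd.keys(), _FACTOR_KEYS, f"{context}: factors[{i}]")
        try:
            factors.append(
                Factor(
                    name=str(fd["name"]),
                    levels=tuple(str(l) for l in fd["levels"]),
                    coding=str(fd.get("coding", "dummy")),
                )
            )
        except KeyError as e:
            raise FileFormatError(
                f"{context}: factors[{i}] missing field {e.args[0]!r}"
            ) from None
    constraints = []
    for i, cd in enumerate(doc.get("constraints") or []):
        _reject_unknown(cd.keys(), {"forbidden"}, f"{context}: constraints[{i}]")
        constraints.append(
            Constraint(tuple((str(f), str(l)) for f, l in cd["forbidden"]))
        )
    interactions = tuple(
        (str(a), str(b)) for a, b in (doc.get("interactions") or [])
    )
    return ExperimentSpec(
        decision_label=str(doc["decision_label"]),
        response_type=str(doc.get("response_type", "binary")),
        factors=tuple(factors),
        constraints=tuple(constraints),
        interactions=interactions,
    )


def read_spec(path: PathLike) -> ExperimentSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return spec_from_dict(doc, context=str(path))


def write_spec(spec: ExperimentSpec, path: PathLike) -> None:
    path = Path(path)
    doc = spec_to_dict(spec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ----------------------------------------------------------------------
# profiles / designs


def _profiles_from_frame(df: pd.DataFrame, spec: ExperimentSpec, context: str):
    missing = [n for n in spec.factor_names if n not in df.columns]
    if missing:
        raise FileFormatError(f"{context}: missing factor column(s) {missing}")
    profiles = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # header = line 1
        assignment = {}
        for f in spec.factors:
            label = str(row[f.name])
            if label not in f.levels:
                raise FileFormatError(
                    f"{context}: line {row_no}: unknown level {label!r} "
                    f"for factor {f.name!r}"
                )
            assignment[f.name] = label
        profiles.append(spec.profile(assignment))
    return profiles


def read_profiles(path: PathLike, spec: ExperimentSpec) -> list[Profile]:
    df = pd.read_csv(path, dtype=str)
    return _profiles_from_frame(df, spec, str(path))


def write_profiles(profiles, spec: ExperimentSpec, path: PathLike) -> None:
    df = pd.DataFrame(
        [p.as_dict(spec) for p in profiles], columns=list(spec.factor_names)
    )
    df.to_csv(path, index=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_design(design: Design, path: PathLike) -> None:
    """Scenario CSV plus a ``<path>.meta.json`` sidecar with metadata."""
    path = Path(path)
    write_profiles(design.scenarios, design.spec, path)
    meta = {"schema_version": SCHEMA_VERSION, "metadata": design.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_design(path: PathLike, spec: ExperimentSpec) -> Design:
    path = Path(path)
    scenarios = read_profiles(path, spec)
    metadata = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        _reject_unknown(doc.keys(), {"schema_version", "metadata"}, str(sidecar))
        _check_version(doc, str(sidecar))
        metadata = doc["metadata"]
    return Design(spec, tuple(scenarios), metadata)


# ----------------------------------------------------------------------
# choices


def _parse_choice(raw, context: str) -> int:
    token = str(raw).strip().lower()
    if token in _TRUE_CHOICES:
        return 1
    if token in _FALSE_CHOICES:
        return 0
    raise FileFormatError(f"{context}: ambiguous choice value {raw!r}")


def read_choices(path: PathLike, spec: ExperimentSpec) -> ChoiceDataset:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("expert_id", "choice"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    profiles = _profiles_from_frame(df, spec, str(path))
    observations = []
    for row_no, ((_, row), profile) in enumerate(
        zip(df.iterrows(), profiles), start=2
    ):
        choice = _parse_choice(row["choice"], f"{path}: line {row_no}")
        observations.append(
            ChoiceObservation(str(row["expert_id"]), profile, choice)
        )
    return ChoiceDataset(spec, tuple(observations))


def write_choices(dataset: ChoiceDataset, path: PathLike) -> None:
    dataset.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# fits


def fit_to_dict(fit: ChoiceLogitResults) -> dict:
    doc = {"schema_version": SCHEMA_VERSION, "spec": spec_to_dict(fit.spec)}
    doc.update(fit.to_dict())
    return doc


def write_fit(fit: ChoiceLogitResults, path: PathLike) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")


def fit_from_dict(doc: dict, context: str = "fit") -> ChoiceLogitResults:
    if not isinstance(doc, dict):
        raise FileFormatError(f"{context}: document must be a mapping")
    _reject_unknown(doc.keys(), _FIT_KEYS, context)
    _check_version(doc, context)
    for key in ("spec", "weights"):
        if key not in doc:
            raise FileFormatError(f"{context}: missing required field {key!r}")
    spec = spec_from_dict(doc["spec"], context=f"{context}: spec")
    cov = doc.get("covariance")
    if cov is None:
        logger.warning(
            "%s: no covariance matrix stored; Wald inference disabled "
            "(stored p-values, if any, are used for significance masking)",
            context,
        )
    llf = doc.get("log_likelihood")
    llnull = doc.get("null_log_likelihood")
    stored_rho2 = doc.get("mcfadden_rho2")
    if stored_rho2 is not None and llf is not None and llnull is not None:
        recomputed = 1.0 - llf / llnull
        if abs(recomputed - stored_rho2) > 1e-6:
            raise FileFormatError(
                f"{context}: stored mcfadden_rho2 {stored_rho2} is "
                f"inconsistent with the stored log-likelihoods "
                f"(recomputed {recomputed:.6f})"
            )
    try:
        fit = ChoiceLogitResults.from_estimates(
            spec,
            doc["weights"],
            llf=llf,
            llnull=llnull,
            cov_params=cov,
            pvalues=doc.get("p_values"),
            n_obs=doc.get("n_observations"),
            model_kind=doc.get("model_kind", "binary logit"),
        )
    except ValueError as e:
        raise FileFormatError(f"{context}: {e}") from None
    fit.converged = doc.get("converged")
    fit.niter = doc.get("n_iterations")
    fit.grad_norm = doc.get("gradient_max_norm")
    return fit


def read_fit(path: PathLike) -> ChoiceLogitResults:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FileFormatError(f"{path}: malformed JSON at line {e.lineno}") from None
    return fit_from_dict(doc, context=str(path))
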