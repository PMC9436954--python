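"""Structured run configuration: schema, defaults, validation.

One YAML file drives an end-to-end experiment.  Sections:

``data``       input files (or null to simulate), drug names, dialect
``generator``  synthetic-stream settings (used when data.reports is null)
``screening``  window, methods, ML and disproportionality knobs
``targets``    pre-specified AEs (term groups) for the timeline
``evaluation`` which pair universe the performance summary uses
``seed``       master seed; stage seeds derive from it

:func:`validate_config` returns findings (strings) instead of raising, so
a CLI can show all problems at once.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .screening import METHODS

__all__ = ["default_config", "load_config", "validate_config"]


def default_config() -> dict:
    """The bundled end-to-end configuration (synthetic reference study)."""
    return {
        "seed": 0,
        "data": {
            "reports": None,  # null -> simulate
            "dialect": "generic_csv",
            "label_history": None,
            "study_drug": "infliximab",
            "comparator_drugs": ["methotrexate"],
            "class_drugs": ["etanercept", "adalimumab", "golimumab"],
        },
        "generator": {
            "scenario": "default",  # default | null
            "n_reports": 20000,
        },
        "screening": {
            "window": [2009, 2018],
            "methods": list(METHODS),
            "train_fraction": 0.75,
            "folds": 5,
            "smote_k": 5,
            "ror_covariates": [],
            "ic_level": 0.025,
            "ic_samples": 20000,
        },
        "targets": None,  # null -> emerging planted signals (synthetic runs)
        "evaluation": {"universe": "test_split"},
    }


def load_config(path_or_mapping: str | Path | Mapping) -> dict:
    """Load a config file (or pass a mapping through), merged over defaults."""
    if isinstance(path_or_mapping, Mapping):
        user = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as handle:
            user = yaml.safe_load(handle) or {}
    merged = default_config()
    for section, value in user.items():
        if isinstance(value, Mapping) and isinstance(merged.get(section), dict):
            merged[section] = {**merged[section], **value}
        else:
            merged[section] = copy.deepcopy(value)
    return merged


def _check(findings: list[str], ok: bool, message: str) -> None:
    if not ok:
        findings.append(message)


def validate_config(path_or_mapping: str | Path | Mapping) -> list[str]:
    """Schema-check every section; an empty list means the config is valid."""
    try:
        cfg = load_config(path_or_mapping)
    except Exception as err:  # unreadable/unparseable file is the finding
        return [f"config could not be loaded: {err}"]
    findings: list[str] = []

    known = {"seed", "data", "generator", "screening", "targets", "evaluation"}
    for key in cfg:
        _check(findings, key in known,
               f"unknown config section {key!r}; allowed: {sorted(known)}")

    _check(findings, isinstance(cfg.get("seed"), int),
           "seed must be an integer")

    data = cfg.get("data", {})
    _check(findings, data.get("dialect") in ("generic_csv", "faers_quarter"),
           "data.dialect must be generic_csv or faers_quarter")
    _check(findings, bool(data.get("study_drug")),
           "data.study_drug must be set")
    _check(findings, bool(data.get("comparator_drugs")),
           "data.comparator_drugs must be non-empty")
    _check(findings, bool(data.get("class_drugs")),
           "data.class_drugs must be non-empty")
    if data.get("reports") is not None:
        _check(findings, Path(str(data["reports"])).exists(),
               f"data.reports file not found: {data['reports']}")
        _check(findings, data.get("label_history") is not None,
               "data.label_history is required when data.reports is set")

    gen = cfg.get("generator", {})
    _check(findings, gen.get("scenario") in ("default", "null"),
           "generator.scenario must be 'default' or 'null'")
    _check(findings,
           isinstance(gen.get("n_reports"), int) and gen.get("n_reports", 0) > 0,
           "generator.n_reports must be a positive integer")

    scr = cfg.get("screening", {})
    window = scr.get("window")
    _check(
        findings,
        isinstance(window, (list, tuple)) and len(window) == 2
        and all(isinstance(y, int) for y in window) and window[0] <= window[1],
        "screening.window must be [start_year, end_year] with start <= end",
    )
    methods = scr.get("methods", [])
    unknown_methods = [m for m in methods if m not in METHODS]
    _check(findings, not unknown_methods,
           f"unknown screening.methods {unknown_methods}; allowed {list(METHODS)}")
    frac = scr.get("train_fraction")
    _check(findings, isinstance(frac, (int, float)) and 0.0 < frac < 1.0,
           "screening.train_fraction must lie strictly between 0 and 1")
    _check(findings, isinstance(scr.get("folds"), int) and scr.get("folds", 0) >= 2,
           "screening.folds must be an integer >= 2")
    _check(findings, scr.get("ic_level") in (0.025, 0.05),
           "screening.ic_level must be 0.025 or 0.05")
    _check(findings,
           isinstance(scr.get("ic_samples"), int) and scr.get("ic_samples", 0) >= 1,
           "screening.ic_samples must be a positive integer")

    targets = cfg.get("targets")
    if targets is not None:
        if not isinstance(targets, list):
            findings.append("targets must be a list of {name, members} entries")
        else:
            for i, entry in enumerate(targets):
                ok = (
                    isinstance(entry, Mapping)
                    and entry.get("name")
                    and isinstance(entry.get("members"), list)
                    and entry["members"]
                )
                _check(findings, bool(ok),
                       f"targets[{i}] must have a name and non-empty members list")

    ev = cfg.get("evaluation", {})
    _check(findings, ev.get("universe") in ("test_split", "all_gold"),
           "evaluation.universe must be test_split or all_gold")
    return findings
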