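"""Loaders for the shipped published reference values.

The national 1978/2003 sika deer survey data cannot be redistributed;
what IS in the public record are the fitted coefficients, the posterior
summary of the transition model, and the survey/scenario bookkeeping.
These ship as JSON fixtures and serve as generating values for synthetic
landscapes and as fixed inputs for worked-example computations.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .dynamics import DynamicsParams


def _load(name: str) -> dict:
    ref = resources.files("rangedyn.data").joinpath(name)
    with resources.as_file(ref) as path, open(path) as fh:
        return json.load(fh)


def load_survey_reference() -> dict:
    """Survey bookkeeping: cell counts, change contingency, scenario areas."""
    return _load("sika_survey_reference.json")


def load_dynamics_reference() -> dict:
    """Posterior summary of the published transition-model fit."""
    return _load("sika_dynamics_posterior.json")


def reference_dynamics_params() -> DynamicsParams:
    """Posterior medians of the published fit (the projection point)."""
    ref = load_dynamics_reference()["parameters"]
    return DynamicsParams(**{k: ref[k]["q50"] for k in ref})
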