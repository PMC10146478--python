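"""Packaged reference fixtures.

``norms_sample.csv`` holds the published sample of the normative table —
quadratic psych-score curves for the 25th, 50th and 75th percentiles over
ages 120–240 months, with coefficients derived exactly from the published
values (the printed cells have constant second differences, so the
quadratics reproduce them to four decimals).

``published_weights.json`` holds the published logistic B-weights
(intercept, psych, psych×age) for 30-day alcohol use, drunkenness and
vaping, calibrated on the evaluation's treatment pretests.  Cigarette
smoking had too few positive pretest cases to calibrate and is absent.
"""

from __future__ import annotations

import json
from importlib.resources import files

from ..calibration import BehaviorWeights
from ..norm_model import NormTable

__all__ = ["load_reference_norms", "load_reference_weights"]


def load_reference_norms() -> NormTable:
    """The published three-percentile sample of the normative table."""
    text = files(__package__).joinpath("norms_sample.csv").read_text()
    return NormTable.from_curves_text(text)


def load_reference_weights() -> dict[str, BehaviorWeights]:
    """Published logistic weights for alcohol, drunkenness and vaping."""
    raw = json.loads(files(__package__).joinpath("published_weights.json").read_text())
    return {
        behavior: BehaviorWeights(behavior=behavior, **coefs)
        for behavior, coefs in raw.items()
    }
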