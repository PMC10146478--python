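"""Logistic calibration of psych scores against 30-day behavior reports.

Each behavior (alcohol, drunkenness, cigarette, vaping) gets its own
logistic model fitted on treatment-group pretests:

    Pr(use) = expit(t),   t = B0 + B_psych * psych + B_psych_age * psych * age

with age in months.  The model deliberately has no age main effect — age
enters only through the psych × age product, exactly as the probability
formula is specified.  Behaviors with too few positive pretest cases are
not calibrated (a prevalence guard): with near-zero prevalence the maximum
likelihood weights are unstable, which is why cigarette smoking could not
be calibrated in the original evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "BEHAVIORS",
    "BehaviorWeights",
    "CalibrationReport",
    "fit_behavior_weights",
    "calibrate_all",
    "probability_of_use",
    "weights_to_json",
    "weights_from_json",
]

BEHAVIORS = ("alcohol", "drunkenness", "cigarette", "vaping")

GUARD_TOO_FEW_POSITIVE = "insufficient positive cases"
GUARD_NOT_CONVERGED = "optimizer did not converge"


@dataclass(frozen=True)
class BehaviorWeights:
    """Logistic coefficients for one behavior (age in months)."""

    behavior: str
    b_intercept: float
    b_psych: float
    b_psych_age: float

    def __post_init__(self) -> None:
        for name in ("b_intercept", "b_psych", "b_psych_age"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b_intercept, self.b_psych, self.b_psych_age])


@dataclass(frozen=True)
class CalibrationReport:
    """Outcome of one behavior's calibration attempt.

    ``weights`` is None whenever the prevalence guard trips or the fit does
    not converge; ``guard_reason`` then says why.  ``stderr`` holds the
    estimated standard errors (intercept, psych, psych×age) when available.
    """

    behavior: str
    n_cases: int
    n_positive: int
    converged: bool
    weights: BehaviorWeights | None = None
    stderr: tuple[float, float, float] | None = None
    guard_reason: str | None = None


def probability_of_use(
    weights: BehaviorWeights,
    psych: float | np.ndarray,
    age_months: float | np.ndarray,
):
    """Expected probability of the behavior at a psych score and age.

    Computes t = B0 + B_psych*psych + B_psych_age*(psych*age_months) and
    returns expit(t), strictly inside (0, 1).  Vectorized over inputs.
    """
    psych = np.asarray(psych, dtype=float)
    age = np.asarray(age_months, dtype=float)
    t = (
        weights.b_intercept
        + weights.b_psych * psych
        + weights.b_psych_age * psych * age
    )
    out = expit(t)
    if out.ndim == 0:
        return float(out)
    return out


def fit_behavior_weights(
    psych: np.ndarray,
    age_months: np.ndarray,
    behavior_flags: np.ndarray,
    behavior: str,
    min_positive: int = 20,
) -> CalibrationReport:
    """Fit the two-predictor logistic model on pretest records.

    Records with a missing psych score or missing flag are dropped.  Returns
    weights only when the number of positive cases reaches ``min_positive``
    and the optimizer converges.
    """
    psych = np.asarray(psych, dtype=float)
    age = np.asarray(age_months, dtype=float)
    y = np.asarray(behavior_flags, dtype=float)
    mask = ~(np.isnan(psych) | np.isnan(age) | np.isnan(y))
    psych, age, y = psych[mask], age[mask], y[mask]
    if np.any((y != 0) & (y != 1)):
        raise ValueError("behavior flags must be 0/1 (or missing)")
    if psych.size and (psych.min() < 0 or psych.max() > 10):
        raise ValueError("psych scores must lie in [0, 10]")
    n_cases = int(psych.size)
    n_positive = int(y.sum())
    if n_positive < min_positive:
        return CalibrationReport(
            behavior=behavior,
            n_cases=n_cases,
            n_positive=n_positive,
            converged=False,
            guard_reason=GUARD_TOO_FEW_POSITIVE,
        )
    X = np.column_stack([np.ones_like(psych), psych, psych * age])
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        finite = np.all(np.isfinite(params)) and np.all(np.isfinite(bse))
    except Exception:
        converged, finite = False, False
    if not (converged and finite):
        return CalibrationReport(
            behavior=behavior,
            n_cases=n_cases,
            n_positive=n_positive,
            converged=False,
            guard_reason=GUARD_NOT_CONVERGED,
        )
    return CalibrationReport(
        behavior=behavior,
        n_cases=n_cases,
        n_positive=n_positive,
        converged=True,
        weights=BehaviorWeights(behavior, *map(float, params)),
        stderr=tuple(map(float, bse)),
    )


def calibrate_all(
    pretests: pd.DataFrame,
    behaviors: tuple[str, ...] = BEHAVIORS,
    min_positive: int = 20,
    psych_col: str = "psych",
    age_col: str = "age_months",
) -> dict[str, CalibrationReport]:
    """Calibrate every behavior column present in a pretest table."""
    out = {}
    for behavior in behaviors:
        if behavior not in pretests.columns:
            continue
        out[behavior] = fit_behavior_weights(
            pretests[psych_col].to_numpy(dtype=float),
            pretests[age_col].to_numpy(dtype=float),
            pretests[behavior].to_numpy(dtype=float),
            behavior=behavior,
            min_positive=min_positive,
        )
    return out


def weights_to_json(reports: dict[str, CalibrationReport], path: str | Path) -> None:
    """Serialize calibration results (calibrated or guarded) to JSON."""
    payload = {}
    for behavior, rep in reports.items():
        entry: dict = {
            "n_cases": rep.n_cases,
            "n_positive": rep.n_positive,
            "converged": rep.converged,
        }
        if rep.weights is not None:
            entry.update(
                b_intercept=rep.weights.b_intercept,
                b_psych=rep.weights.b_psych,
                b_psych_age=rep.weights.b_psych_age,
            )
        if rep.guard_reason:
            entry["guard_reason"] = rep.guard_reason
        payload[behavior] = entry
    Path(path).write_text(json.dumps(payload, indent=2))


def weights_from_json(path: str | Path) -> dict[str, BehaviorWeights]:
    """Load calibrated weights from JSON, skipping guarded behaviors."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for behavior, entry in payload.items():
        if "b_intercept" in entry:
            out[behavior] = BehaviorWeights(
                behavior=behavior,
                b_intercept=entry["b_intercept"],
                b_psych=entry["b_psych"],
                b_psych_age=entry["b_psych_age"],
            )
    return out
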