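"""The virtual-controls matching algorithm.

A virtual control is an algorithmically generated counterfactual twin for a
treated student.  The student's *pretest* age and psych score peg the twin
to the normative percentile whose smoothed curve value at that age is
nearest the student's score; the twin then stays at that percentile
forever.  At each wave the treated student was actually surveyed, the
twin's psych score is read off the pegged curve at the student's age at
that wave, and its behavior probabilities follow from the calibrated
logistic weights.  The student's own posttest/follow-up psych scores and
self-reported behaviors are never consulted, and a twin value exists at
every wave the student was observed — differential attrition between the
conditions is impossible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import BehaviorWeights, probability_of_use
from .norm_model import NormTable

__all__ = [
    "WAVES",
    "WaveObs",
    "TreatmentCase",
    "VirtualWave",
    "VirtualCase",
    "Exclusion",
    "AgeBelowRangeError",
    "match_percentile",
    "build_virtual_case",
    "match_cohort",
    "cases_from_frame",
    "virtual_cases_to_frame",
]

logger = logging.getLogger(__name__)

WAVES = ("pretest", "posttest", "followup")

# machine-readable exclusion reason codes
REASON_AGE_BELOW_RANGE = "AGE_BELOW_RANGE"
REASON_MISSING_PRETEST_PSYCH = "MISSING_PRETEST_PSYCH"
REASON_MISSING_PRETEST = "MISSING_PRETEST"


class AgeBelowRangeError(ValueError):
    """Pretest age below the normative table's range (case must be excluded)."""


@dataclass(frozen=True)
class WaveObs:
    """A treated student's observation at one wave."""

    age_months: int
    psych: float | None = None
    behaviors: Mapping[str, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class TreatmentCase:
    """One treated student across waves, with demographics and cluster IDs."""

    student_id: str
    classroom_id: str
    school_id: str
    gender: str | None = None
    hispanic: bool | None = None
    race: str | None = None
    waves: Mapping[str, WaveObs] = field(default_factory=dict)


@dataclass(frozen=True)
class VirtualWave:
    age_months: int
    psych: float
    probabilities: Mapping[str, float]


@dataclass(frozen=True)
class VirtualCase:
    """The pegged-percentile counterfactual twin of one treatment case.

    Demographics and classroom/school identifiers are inherited from the
    matched treatment case, enabling clustered and subgroup analyses; the
    matched percentile is identical at every wave.
    """

    student_id: str
    classroom_id: str
    school_id: str
    matched_percentile: float
    gender: str | None = None
    hispanic: bool | None = None
    race: str | None = None
    waves: Mapping[str, VirtualWave] = field(default_factory=dict)


@dataclass(frozen=True)
class Exclusion:
    student_id: str
    reason: str
    detail: str


def match_percentile(table: NormTable, age_months: int, psych: float) -> float:
    """Grid percentile whose curve value at ``age_months`` is nearest ``psych``.

    Ties break toward the lower percentile (lower percentile = lower psych
    = higher risk, the conservative choice).  Ages below the table range
    raise :class:`AgeBelowRangeError`; ages above it are clamped to the top
    of the range with a logged warning.
    """
    if not 0 <= psych <= 10:
        raise ValueError(f"psych score {psych} outside [0, 10]")
    if age_months < table.age_min:
        raise AgeBelowRangeError(
            f"age {age_months} months below table minimum {table.age_min}"
        )
    if age_months > table.age_max:
        logger.warning(
            "age %d months above table maximum %d; clamping", age_months, table.age_max
        )
        age_months = table.age_max
    col = table.column(age_months)
    # np.argmin returns the first minimizer; the column is ascending in
    # percentile, so exact ties resolve to the lower percentile.
    idx = int(np.argmin(np.abs(col - psych)))
    return float(table.percentiles[idx])


def build_virtual_case(
    table: NormTable,
    weights: Mapping[str, BehaviorWeights],
    case: TreatmentCase,
) -> VirtualCase:
    """Derive a treatment case's virtual control twin.

    The pegged percentile comes from the pretest only; each observed wave
    then contributes a curve psych score and one probability per calibrated
    behavior, evaluated at the treatment case's age at that wave (clamped to
    the table maximum if beyond it).
    """
    if not weights:
        raise ValueError("no calibrated behavior weights available")
    pre = case.waves.get("pretest")
    if pre is None:
        raise ValueError(f"case {case.student_id}: no pretest wave")
    if pre.psych is None or np.isnan(pre.psych):
        raise ValueError(f"case {case.student_id}: missing pretest psych score")
    pct = match_percentile(table, pre.age_months, float(pre.psych))
    vwaves = {}
    for wave, obs in case.waves.items():
        if obs.age_months is None:
            continue
        age = int(min(obs.age_months, table.age_max))
        vpsych = table.eval(pct, age)
        probs = {
            b: float(probability_of_use(w, vpsych, age)) for b, w in weights.items()
        }
        vwaves[wave] = VirtualWave(age_months=obs.age_months, psych=vpsych, probabilities=probs)
    return VirtualCase(
        student_id=case.student_id,
        classroom_id=case.classroom_id,
        school_id=case.school_id,
        matched_percentile=pct,
        gender=case.gender,
        hispanic=case.hispanic,
        race=case.race,
        waves=vwaves,
    )


def match_cohort(
    table: NormTable,
    weights: Mapping[str, BehaviorWeights],
    cases: Sequence[TreatmentCase],
) -> tuple[list[VirtualCase], list[Exclusion]]:
    """Match every eligible treatment case; log exclusions with reasons."""
    virtual: list[VirtualCase] = []
    exclusions: list[Exclusion] = []
    for case in cases:
        pre = case.waves.get("pretest")
        if pre is None:
            exclusions.append(
                Exclusion(case.student_id, REASON_MISSING_PRETEST, "no pretest wave")
            )
            continue
        if pre.psych is None or np.isnan(pre.psych):
            exclusions.append(
                Exclusion(
                    case.student_id,
                    REASON_MISSING_PRETEST_PSYCH,
                    "pretest psych score missing",
                )
            )
            continue
        try:
            virtual.append(build_virtual_case(table, weights, case))
        except AgeBelowRangeError as err:
            exclusions.append(
                Exclusion(case.student_id, REASON_AGE_BELOW_RANGE, str(err))
            )
    for exc in exclusions:
        logger.warning("excluded %s: %s (%s)", exc.student_id, exc.reason, exc.detail)
    if not virtual:
        raise ValueError("no eligible treatment cases; nothing to match")
    return virtual, exclusions


# -- DataFrame adapters -------------------------------------------------------


def cases_from_frame(df: pd.DataFrame, behaviors: Sequence[str]) -> list[TreatmentCase]:
    """Build TreatmentCase objects from a scored long survey table.

    Expects one row per student × wave with columns ``student_id``, ``wave``,
    ``age_months``, ``psych``, cluster IDs, demographics and one column per
    behavior flag.
    """
    if "psych" not in df.columns:
        raise KeyError("survey frame has no psych column; score it first")
    df = df.sort_values("student_id", kind="mergesort")
    n = len(df)
    sids = df["student_id"].to_numpy()
    wave_arr = df["wave"].to_numpy()
    ages = df["age_months"].to_numpy(dtype=float)
    psychs = df["psych"].to_numpy(dtype=float)

    def _col(name):
        return df[name].to_numpy() if name in df.columns else None

    cls_arr, sch_arr = _col("classroom_id"), _col("school_id")
    gender_arr, hisp_arr, race_arr = _col("gender"), _col("hispanic"), _col("race")
    beh_arrs = {
        b: df[b].to_numpy(dtype=float) for b in behaviors if b in df.columns
    }

    unknown = set(np.unique(wave_arr)) - set(WAVES)
    if unknown:
        raise ValueError(f"unknown wave {unknown.pop()!r}")

    cases = []
    start = 0
    for i in range(1, n + 1):
        if i < n and sids[i] == sids[start]:
            continue
        waves = {}
        for j in range(start, i):
            if np.isnan(ages[j]):
                continue
            flags = {
                b: (None if np.isnan(arr[j]) else float(arr[j]))
                for b, arr in beh_arrs.items()
            }
            psych = None if np.isnan(psychs[j]) else float(psychs[j])
            waves[wave_arr[j]] = WaveObs(
                age_months=int(ages[j]), psych=psych, behaviors=flags
            )
        hisp = hisp_arr[start] if hisp_arr is not None else None
        cases.append(
            TreatmentCase(
                student_id=str(sids[start]),
                classroom_id=str(cls_arr[start]) if cls_arr is not None else "",
                school_id=str(sch_arr[start]) if sch_arr is not None else "",
                gender=gender_arr[start] if gender_arr is not None else None,
                hispanic=None if pd.isna(hisp) else bool(hisp),
                race=race_arr[start] if race_arr is not None else None,
                waves=waves,
            )
        )
        start = i
    return cases


def virtual_cases_to_frame(virtual: Iterable[VirtualCase]) -> pd.DataFrame:
    """One row per virtual case × wave, with a probability column per behavior."""
    rows = []
    for vc in virtual:
        for wave, vw in vc.waves.items():
            row = {
                "student_id": vc.student_id,
                "classroom_id": vc.classroom_id,
                "school_id": vc.school_id,
                "wave": wave,
                "matched_percentile": vc.matched_percentile,
                "age_months": vw.age_months,
                "psych": vw.psych,
                "gender": vc.gender,
                "hispanic": vc.hispanic,
                "race": vc.race,
            }
            for b, p in vw.probabilities.items():
                row[f"p_{b}"] = p
            rows.append(row)
    return pd.DataFrame(rows)


def write_exclusion_log(exclusions: Sequence[Exclusion], path) -> None:
    """Plain-text exclusion log: one ``student_id<TAB>REASON<TAB>detail`` line."""
    with open(path, "w") as fh:
        for exc in exclusions:
            fh.write(f"{exc.student_id}\t{exc.reason}\t{exc.detail}\n")
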