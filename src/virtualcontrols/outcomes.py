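"""Treatment vs. virtual-control comparisons.

Treated students contribute 0/1 self-reports of each 30-day behavior;
their virtual twins contribute model probabilities.  Both are values in
[0, 1], compared with Welch two-sample t-tests and Cohen's *d* at three
levels of aggregation — individual students, classroom means, and school
means — plus two-proportion z-tests within demographic subgroups (each
virtual twin inherits its treatment case's demographics, so subgroup sides
are equal-sized by construction).

Sign conventions: both the t statistic and Cohen's d are oriented
control-minus-treatment, so positive values mean the counterfactual
estimate exceeds the treated group's self-reports (a protective program
effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .virtual_match import TreatmentCase, VirtualCase, WAVES

__all__ = [
    "SUBGROUPS",
    "OutcomeCell",
    "ComparisonResult",
    "SubgroupResult",
    "cells_from_treatment",
    "cells_from_virtual",
    "aggregate",
    "compare",
    "subgroup_compare",
    "dichotomize_increase",
]

LEVELS = ("student", "class", "school")

SUBGROUPS = ("boys", "girls", "hispanic", "non_hispanic", "white", "non_white")

_CELL_COLUMNS = [
    "unit_id",
    "classroom_id",
    "school_id",
    "condition",
    "behavior",
    "wave",
    "value",
]


@dataclass(frozen=True)
class OutcomeCell:
    unit_id: str
    condition: str  # "treatment" | "virtual_control"
    behavior: str
    wave: str
    value: float  # self-report 0/1, model probability, or a mean thereof


@dataclass(frozen=True)
class ComparisonResult:
    """One treatment-vs-control contrast at one level × behavior × wave."""

    level: str
    behavior: str
    wave: str
    mean_treatment: float
    mean_control: float
    t_stat: float
    df: float
    p_value: float
    cohens_d: float
    n_treatment: int
    n_control: int
    degenerate: bool = False


@dataclass(frozen=True)
class SubgroupResult:
    subgroup: str
    behavior: str
    wave: str
    prevalence_treatment: float
    prevalence_control: float
    z_stat: float
    p_value: float
    significant_at_95: bool
    n: int


# -- building student-level cells --------------------------------------------


def cells_from_treatment(
    cases: Sequence[TreatmentCase], behaviors: Sequence[str]
) -> pd.DataFrame:
    """Student-level cells from treated students' 0/1 self-reports."""
    rows = []
    for case in cases:
        for wave, obs in case.waves.items():
            for b in behaviors:
                v = obs.behaviors.get(b)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    continue
                rows.append(
                    (
                        case.student_id,
                        case.classroom_id,
                        case.school_id,
                        "treatment",
                        b,
                        wave,
                        float(v),
                    )
                )
    return pd.DataFrame(rows, columns=_CELL_COLUMNS)


def cells_from_virtual(
    virtual: Sequence[VirtualCase], behaviors: Sequence[str]
) -> pd.DataFrame:
    """Student-level cells from virtual twins' model probabilities."""
    rows = []
    for vc in virtual:
        for wave, vw in vc.waves.items():
            for b in behaviors:
                if b not in vw.probabilities:
                    continue
                rows.append(
                    (
                        vc.student_id,
                        vc.classroom_id,
                        vc.school_id,
                        "virtual_control",
                        b,
                        wave,
                        float(vw.probabilities[b]),
                    )
                )
    return pd.DataFrame(rows, columns=_CELL_COLUMNS)


# -- aggregation --------------------------------------------------------------


def aggregate(
    cells: pd.DataFrame, level: str, school_weighting: str = "student"
) -> pd.DataFrame:
    """Aggregate student-level cells to classroom or school means.

    Values are unweighted means over member students with non-missing
    values.  For the school level, ``school_weighting="student"`` averages
    over all students in the school directly (the default), while
    ``"class_means"`` averages the classroom means instead — the two differ
    when classes are unequal in size.
    """
    if level == "student":
        return cells.copy()
    if level == "class":
        keys = ["classroom_id", "school_id", "condition", "behavior", "wave"]
        out = cells.groupby(keys, as_index=False)["value"].mean()
        return out.rename(columns={"classroom_id": "unit_id"})
    if level == "school":
        if school_weighting == "student":
            base = cells
        elif school_weighting == "class_means":
            base = aggregate(cells, "class").rename(columns={"unit_id": "classroom_id"})
        else:
            raise ValueError(f"unknown school_weighting {school_weighting!r}")
        keys = ["school_id", "condition", "behavior", "wave"]
        out = base.groupby(keys, as_index=False)["value"].mean()
        return out.rename(columns={"school_id": "unit_id"})
    raise ValueError(f"unknown level {level!r}")


# -- two-sample comparison ----------------------------------------------------


def compare(
    treatment_values: np.ndarray,
    control_values: np.ndarray,
    level: str,
    behavior: str,
    wave: str,
) -> ComparisonResult:
    """Welch two-sample t-test plus Cohen's d for one contrast.

    t is oriented control-minus-treatment (Welch–Satterthwaite df,
    two-sided p); d = (mean_control − mean_treatment) / pooled SD.  With
    zero variance on both sides, equal means give t = d = 0 and unequal
    means are flagged degenerate (the statistics are undefined).
    """
    x_t = np.asarray(treatment_values, dtype=float)
    x_c = np.asarray(control_values, dtype=float)
    x_t, x_c = x_t[~np.isnan(x_t)], x_c[~np.isnan(x_c)]
    n_t, n_c = x_t.size, x_c.size
    if n_t < 2 or n_c < 2:
        raise ValueError("need >= 2 units per condition")
    m_t, m_c = x_t.mean(), x_c.mean()
    v_t, v_c = x_t.var(ddof=1), x_c.var(ddof=1)
    if v_t == 0 and v_c == 0:
        if m_t == m_c:
            return ComparisonResult(
                level, behavior, wave, m_t, m_c, 0.0, float(n_t + n_c - 2), 1.0,
                0.0, n_t, n_c,
            )
        return ComparisonResult(
            level, behavior, wave, m_t, m_c, math.nan, float(n_t + n_c - 2),
            math.nan, math.nan, n_t, n_c, degenerate=True,
        )
    t_stat, p_value = stats.ttest_ind(x_c, x_t, equal_var=False)
    df = (v_t / n_t + v_c / n_c) ** 2 / (
        (v_t / n_t) ** 2 / (n_t - 1) + (v_c / n_c) ** 2 / (n_c - 1)
    )
    pooled_sd = math.sqrt(((n_t - 1) * v_t + (n_c - 1) * v_c) / (n_t + n_c - 2))
    d = (m_c - m_t) / pooled_sd
    return ComparisonResult(
        level=level,
        behavior=behavior,
        wave=wave,
        mean_treatment=float(m_t),
        mean_control=float(m_c),
        t_stat=float(t_stat),
        df=float(df),
        p_value=float(p_value),
        cohens_d=float(d),
        n_treatment=n_t,
        n_control=n_c,
    )


def compare_cells(
    treatment_cells: pd.DataFrame,
    control_cells: pd.DataFrame,
    levels: Sequence[str] = LEVELS,
    school_weighting: str = "student",
) -> list[ComparisonResult]:
    """All level × behavior × wave contrasts present in both cell tables."""
    results = []
    for level in levels:
        agg_t = aggregate(treatment_cells, level, school_weighting)
        agg_c = aggregate(control_cells, level, school_weighting)
        combos = sorted(
            set(map(tuple, agg_t[["behavior", "wave"]].drop_duplicates().to_numpy()))
            & set(map(tuple, agg_c[["behavior", "wave"]].drop_duplicates().to_numpy()))
        )
        for behavior, wave in combos:
            vt = agg_t.query("behavior == @behavior and wave == @wave")["value"]
            vc = agg_c.query("behavior == @behavior and wave == @wave")["value"]
            if min(vt.notna().sum(), vc.notna().sum()) < 2:
                continue  # too few units at this level for a test
            results.append(compare(vt.to_numpy(), vc.to_numpy(), level, behavior, wave))
    return results


# -- subgroup z-tests ---------------------------------------------------------


def _in_subgroup(case, subgroup: str) -> bool:
    if subgroup == "boys":
        return case.gender == "male"
    if subgroup == "girls":
        return case.gender == "female"
    if subgroup == "hispanic":
        return case.hispanic is True
    if subgroup == "non_hispanic":
        return case.hispanic is False
    if subgroup == "white":
        return case.race == "white"
    if subgroup == "non_white":
        return case.race is not None and case.race != "white"
    raise ValueError(f"unknown subgroup {subgroup!r}")


def subgroup_compare(
    cases: Sequence[TreatmentCase],
    virtual: Sequence[VirtualCase],
    subgroup: str,
    behavior: str,
    wave: str,
    alpha: float = 0.05,
) -> SubgroupResult:
    """Two-proportion z-test within one demographic subgroup.

    Treatment prevalence (share of 1-flags) is compared against the mean
    virtual-control probability for the same students, using the pooled
    two-proportion z statistic with equal n on both sides.
    """
    vmap = {vc.student_id: vc for vc in virtual}
    flags, probs = [], []
    for case in cases:
        if not _in_subgroup(case, subgroup):
            continue
        vc = vmap.get(case.student_id)
        if vc is None:
            continue
        obs = case.waves.get(wave)
        vw = vc.waves.get(wave)
        if obs is None or vw is None:
            continue
        v = obs.behaviors.get(behavior)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if behavior not in vw.probabilities:
            continue
        flags.append(float(v))
        probs.append(float(vw.probabilities[behavior]))
    n = len(flags)
    if n == 0:
        raise ValueError(f"subgroup {subgroup!r} is empty at wave {wave!r}")
    p_t = float(np.mean(flags))
    p_c = float(np.mean(probs))
    p_bar = (p_t + p_c) / 2.0
    se = math.sqrt(p_bar * (1.0 - p_bar) * (2.0 / n))
    if se == 0:
        z, p_value = 0.0, 1.0
    else:
        z = (p_c - p_t) / se
        p_value = 2.0 * stats.norm.sf(abs(z))
    return SubgroupResult(
        subgroup=subgroup,
        behavior=behavior,
        wave=wave,
        prevalence_treatment=p_t,
        prevalence_control=p_c,
        z_stat=float(z),
        p_value=float(p_value),
        significant_at_95=bool(p_value < alpha),
        n=n,
    )


# -- dichotomized change table ------------------------------------------------


def dichotomize_increase(
    cells: pd.DataFrame, baseline_wave: str = "pretest", later_wave: str = "posttest"
) -> pd.DataFrame:
    """Flag units whose value rose from baseline to a later wave.

    Input is a long cell table; output has one row per unit × condition ×
    behavior with ``increase`` = 1 when the later value strictly exceeds
    the baseline value, 0 otherwise.  Units missing either wave are
    omitted.  This is the analysis-ready table handed to external
    multi-level modelling software.
    """
    keys = ["unit_id", "condition", "behavior"]
    wide = cells.pivot_table(
        index=keys, columns="wave", values="value", aggfunc="first"
    )
    if baseline_wave not in wide.columns or later_wave not in wide.columns:
        return pd.DataFrame(columns=keys + ["increase"])
    wide = wide.dropna(subset=[baseline_wave, later_wave])
    out = wide.reset_index()[keys]
    out["increase"] = (
        wide[later_wave].to_numpy() > wide[baseline_wave].to_numpy()
    ).astype(int)
    return out


def results_to_frame(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Comparison results as a table with percent columns to two decimals."""
    rows = []
    for r in results:
        rows.append(
            {
                "level": r.level,
                "behavior": r.behavior,
                "wave": r.wave,
                "treatment_pct": round(100 * r.mean_treatment, 2),
                "control_pct": round(100 * r.mean_control, 2),
                "t": r.t_stat,
                "df": r.df,
                "p": r.p_value,
                "cohens_d": r.cohens_d,
                "n_treatment": r.n_treatment,
                "n_control": r.n_control,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def subgroup_results_to_frame(results: Iterable[SubgroupResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "subgroup": r.subgroup,
                "behavior": r.behavior,
                "wave": r.wave,
                "treatment_pct": round(100 * r.prevalence_treatment, 2),
                "control_pct": round(100 * r.prevalence_control, 2),
                "z": r.z_stat,
                "p": r.p_value,
                "significant_at_95": r.significant_at_95,
                "n_per_side": r.n,
            }
        )
    return pd.DataFrame(rows)
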