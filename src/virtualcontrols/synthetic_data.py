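"""Synthetic inputs: normative pools and nested longitudinal trial cohorts.

Everything the pipeline consumes can be generated here, so every stage is
testable end to end without external downloads.

The normative pool generator draws survey records whose psych scores
decline with age at every percentile, fastest in the lower percentiles —
the qualitative structure of the pooled cross-sectional norms.  Its curve
family anchors the 25th/50th/75th percentiles at the published sample
curves and brackets them with plausible lower/upper curves, all verified
non-crossing over ages 120–240 months.

The trial generator emulates the evaluation's design: students nested in
classrooms nested in schools, three waves (pretest near 130 months,
posttest ≈ +2 months, follow-up ≈ +10 months), the study's demographic
mix, Bernoulli behavior flags driven by the psych → log-odds link under
"true" weights, a configurable program effect after pretest, and two-part
attrition (whole schools dropping out, plus independent student dropout)
matching the study's overall retention of 33.5% at posttest and 24.3% at
follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import BEHAVIORS, BehaviorWeights, probability_of_use
from .norm_model import AGE_MAX, AGE_MIN, NormTable, default_grid
from .psych_scale import ItemBattery

__all__ = [
    "DEFAULT_ANCHORS",
    "NormPoolSpec",
    "TrialSpec",
    "default_true_weights",
    "default_family_table",
    "generate_norm_pool",
    "generate_trial",
    "item_responses_from_psych",
    "write_survey",
    "read_survey",
]

# Anchor percentile curves (percentile, a, b, c with psych = a*age^2+b*age+c).
# The 25/50/75 entries reproduce the published sample curves exactly; the
# others bracket them and were checked non-crossing over [120, 240] months.
DEFAULT_ANCHORS: tuple[tuple[float, float, float, float], ...] = (
    (0.5, 0.0, -0.05, 13.0),
    (10.0, -0.7 / 7200, -0.35 / 60, 10.0),
    (25.0, 7.5e-05, -0.3995 / 6, 15.6701),
    (50.0, -0.0158 / 72, 0.2543 / 6, 7.3618),
    (75.0, -0.37 / 7200, 0.595 / 60, 9.08),
    (90.0, -0.3 / 7200, 0.65 / 60, 9.1),
    (99.5, -0.05 / 7200, 0.075 / 60, 9.9),
)

# Observed psych noise presets: "study_like" mirrors the weak pretest
# psych-behavior coupling seen in the live evaluation; "norms_like" the much
# tighter coupling in the pooled norms.
PSYCH_NOISE_PRESETS = {"study_like": 0.9, "norms_like": 0.3}


def default_true_weights() -> dict[str, BehaviorWeights]:
    """Generating ('true') weights for the four behaviors.

    Alcohol, drunkenness and vaping use the published calibrated weights;
    cigarette smoking gets weights producing ~0.1% prevalence so that the
    calibration prevalence guard trips, as it did in the evaluation.
    """
    return {
        "alcohol": BehaviorWeights("alcohol", 1.361, -2.421, 0.014),
        "drunkenness": BehaviorWeights("drunkenness", 2.092, -0.9, 0.0),
        "vaping": BehaviorWeights("vaping", 1.684, -0.801, 0.0),
        "cigarette": BehaviorWeights("cigarette", -4.0, -0.3, 0.0),
    }


def _anchor_values(anchors, ages: np.ndarray) -> np.ndarray:
    arr = np.asarray(anchors, dtype=float)
    a, b, c = arr[:, 1][:, None], arr[:, 2][:, None], arr[:, 3][:, None]
    return np.clip(a * ages.astype(float) ** 2 + b * ages + c, 0.0, 10.0)


def _validate_anchors(anchors, age_min: int, age_max: int) -> None:
    arr = np.asarray(anchors, dtype=float)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError("anchor percentiles must be strictly increasing")
    ages = np.arange(age_min, age_max + 1)
    vals = _anchor_values(anchors, ages)
    if np.any(np.diff(vals, axis=0) < 0):
        raise ValueError("generating percentile curves cross within the age range")


def default_family_table(
    grid: np.ndarray | None = None,
    anchors=DEFAULT_ANCHORS,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> NormTable:
    """The generating curve family expanded onto a full percentile grid.

    Quadratic coefficients are interpolated linearly between anchors
    (evaluation is linear in the coefficients, so curve values interpolate
    identically); grid percentiles beyond the anchor range take the end
    anchor's curve.
    """
    _validate_anchors(anchors, age_min, age_max)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    arr = np.asarray(anchors, dtype=float)
    pcts = arr[:, 0]
    coefs = np.column_stack(
        [np.interp(grid, pcts, arr[:, k]) for k in (1, 2, 3)]
    )
    return NormTable(grid, coefs, age_min=age_min, age_max=age_max)


# -- normative pool -----------------------------------------------------------


@dataclass(frozen=True)
class NormPoolSpec:
    """Specification of a synthetic normative pool."""

    n_records: int = 100_000
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX
    anchors: tuple = DEFAULT_ANCHORS
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _validate_anchors(self.anchors, self.age_min, self.age_max)


def generate_norm_pool(spec: NormPoolSpec) -> pd.DataFrame:
    """Draw a synthetic normative pool (record_id, age_months, psych).

    Ages are uniform over the range; each record draws a latent percentile
    uniform on (0.5, 99.5), takes its curve-family value at its age, adds
    Gaussian noise, and clamps to [0, 10].  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.integers(spec.age_min, spec.age_max + 1, size=spec.n_records)
    u = rng.uniform(0.5, 99.5, size=spec.n_records)
    arr = np.asarray(spec.anchors, dtype=float)
    pcts = arr[:, 0]
    coefs = np.column_stack([np.interp(u, pcts, arr[:, k]) for k in (1, 2, 3)])
    vals = coefs[:, 0] * ages.astype(float) ** 2 + coefs[:, 1] * ages + coefs[:, 2]
    psych = np.clip(
        np.clip(vals, 0.0, 10.0) + rng.normal(0.0, spec.noise_sd, size=spec.n_records),
        0.0,
        10.0,
    )
    return pd.DataFrame(
        {
            "record_id": [f"N{i:07d}" for i in range(spec.n_records)],
            "age_months": ages,
            "psych": psych,
        }
    )


# -- item responses -----------------------------------------------------------


def item_responses_from_psych(
    psych: np.ndarray,
    battery: ItemBattery | None = None,
    reliability: float = 0.681,
    rng: np.random.Generator | None = None,
    between_var: float | None = None,
) -> np.ndarray:
    """Simulate coded item values whose battery hits a target reliability.

    Items are modelled as essentially parallel: item = psych + independent
    Gaussian noise, clamped to [0, 10].  The per-item noise variance is the
    closed-form value that makes the expected Cronbach's alpha of the
    k-item battery equal ``reliability``, given the between-student psych
    variance: with rho = alpha / (k − alpha(k−1)),
    noise_var = between_var * (1 − rho) / rho.

    Returns an (n_students × k) array of coded (continuous) item values.
    Clamping at the scale ends slightly erodes the achieved alpha when
    psych scores sit near 0 or 10.
    """
    battery = battery or ItemBattery.default()
    psych = np.asarray(psych, dtype=float)
    if np.any((psych < 0) | (psych > 10)):
        raise ValueError("psych scores must lie in [0, 10]")
    if not 0.0 < reliability < 1.0:
        raise ValueError("reliability target must lie in (0, 1)")
    rng = rng or np.random.default_rng()
    k = len(battery)
    if between_var is None:
        between_var = float(np.var(psych, ddof=1)) if psych.size > 1 else 1.0
    if between_var <= 0:
        raise ValueError(
            "between-student psych variance must be positive to hit a "
            "reliability target"
        )
    rho = reliability / (k - reliability * (k - 1))
    noise_var = between_var * (1.0 - rho) / rho
    noise = rng.normal(0.0, math.sqrt(noise_var), size=(psych.size, k))
    return np.clip(psych[:, None] + noise, 0.0, 10.0)


# -- trial cohorts ------------------------------------------------------------


@dataclass(frozen=True)
class TrialSpec:
    """Specification of a synthetic nested trial cohort.

    Defaults emulate the evaluation's combined two-cohort sample: ~6,160
    students in 4-classroom schools of 20, pretest ages near 130 months
    (10.8 years), posttest ≈ 2 months and follow-up ≈ 10 months later, the
    study's demographic mix, and overall retention 33.5% / 24.3% split into
    school-level × student-level components (0.67 × 0.50 and 0.60 × 0.405),
    reflecting attrition driven primarily by whole schools.

    The program effect is ``effect_psych`` (additive psych-score lift after
    pretest, >= 0 protective) and ``effect_log_odds`` (additive shift on
    each behavior's log-odds after pretest, negative = protective).
    """

    n_schools: int = 77
    classes_per_school: int = 4
    students_per_class: int = 20
    pretest_age_mean: float = 130.0
    pretest_age_sd: float = 5.0
    posttest_offset_mean: float = 2.0
    followup_offset_mean: float = 10.0
    offset_jitter_sd: float = 0.7
    p_male: float = 0.485
    p_hispanic: float = 0.149
    p_white: float = 0.594
    p_black: float = 0.173
    psych_noise_preset: str = "study_like"
    reliability: float = 0.681
    percentile_preset: str = "uniform"  # or "topheavy" (mass near the top)
    effect_psych: float = 0.0
    effect_log_odds: float = 0.0
    school_retention_posttest: float = 0.67
    student_retention_posttest: float = 0.50
    school_retention_followup: float = 0.60
    student_retention_followup: float = 0.405
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_schools, self.classes_per_school, self.students_per_class) <= 0:
            raise ValueError("cohort counts must be positive")
        for name in (
            "p_male",
            "p_hispanic",
            "p_white",
            "p_black",
            "school_retention_posttest",
            "student_retention_posttest",
            "school_retention_followup",
            "student_retention_followup",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_white + self.p_black > 1.0 + 1e-12:
            raise ValueError("race proportions exceed 1")
        if self.psych_noise_preset not in PSYCH_NOISE_PRESETS:
            raise ValueError(
                f"unknown psych_noise_preset {self.psych_noise_preset!r}"
            )
        if self.percentile_preset not in ("uniform", "topheavy"):
            raise ValueError(f"unknown percentile_preset {self.percentile_preset!r}")

    @property
    def n_students(self) -> int:
        return self.n_schools * self.classes_per_school * self.students_per_class


def _draw_latent_percentiles(
    rng: np.random.Generator, n: int, preset: str
) -> np.ndarray:
    if preset == "uniform":
        return rng.uniform(0.5, 99.5, size=n)
    # "topheavy": ~13% at the very top, the rest spread low — roughly the
    # assigned-percentile distribution seen in the live evaluation.
    top = rng.random(n) < 0.13
    u = rng.uniform(0.5, 72.0, size=n)
    u[top] = rng.uniform(95.0, 99.5, size=int(top.sum()))
    return u


def generate_trial(
    spec: TrialSpec,
    table: NormTable,
    weights: Mapping[str, BehaviorWeights] | None = None,
) -> pd.DataFrame:
    """Generate a treatment cohort in the pipeline's survey input format.

    Returns a long table, one row per student × observed wave, with nested
    IDs, demographics, ages, raw item responses (integer levels derived
    from each wave's realized psych score at the target reliability) and
    0/1 behavior flags drawn under the true weights at the realized psych.
    Deterministic given ``spec.seed``.
    """
    weights = weights if weights is not None else default_true_weights()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_students
    battery = ItemBattery.default()

    school_idx = np.repeat(np.arange(spec.n_schools), spec.classes_per_school * spec.students_per_class)
    class_idx = np.repeat(
        np.arange(spec.n_schools * spec.classes_per_school), spec.students_per_class
    )
    student_id = np.array([f"S{i:06d}" for i in range(n)])
    school_id = np.array([f"SCH{j:03d}" for j in school_idx])
    classroom_id = np.array([f"CLS{j:04d}" for j in class_idx])

    gender = np.where(rng.random(n) < spec.p_male, "male", "female")
    hispanic = (rng.random(n) < spec.p_hispanic).astype(int)
    r = rng.random(n)
    race = np.where(r < spec.p_white, "white", np.where(r < spec.p_white + spec.p_black, "black", "other"))

    pre_age = np.round(rng.normal(spec.pretest_age_mean, spec.pretest_age_sd, size=n)).astype(int)
    post_age = pre_age + np.maximum(
        1, np.round(rng.normal(spec.posttest_offset_mean, spec.offset_jitter_sd, size=n))
    ).astype(int)
    fu_age = pre_age + np.maximum(
        3, np.round(rng.normal(spec.followup_offset_mean, spec.offset_jitter_sd, size=n))
    ).astype(int)
    wave_ages = {"pretest": pre_age, "posttest": post_age, "followup": fu_age}
    for wave, ages in wave_ages.items():
        if ages.max() > table.age_max:
            raise ValueError(
                f"{wave} ages exceed the normative table range "
                f"({ages.max()} > {table.age_max}); regenerate with younger ages "
                "or a wider table"
            )

    u = _draw_latent_percentiles(rng, n, spec.percentile_preset)
    noise_sd = PSYCH_NOISE_PRESETS[spec.psych_noise_preset]

    # wave-level observation masks (attrition); pretest always observed
    observed = {"pretest": np.ones(n, dtype=bool)}
    for wave, school_ret, student_ret in (
        ("posttest", spec.school_retention_posttest, spec.student_retention_posttest),
        ("followup", spec.school_retention_followup, spec.student_retention_followup),
    ):
        school_alive = rng.random(spec.n_schools) < school_ret
        observed[wave] = school_alive[school_idx] & (rng.random(n) < student_ret)

    frames = []
    for wave in ("pretest", "posttest", "followup"):
        ages = wave_ages[wave]
        # ages can fall slightly below the table floor at pretest (young
        # fifth-graders); evaluate the curve at the clamped age, keep the
        # true age in the output so the pipeline applies its exclusion rule.
        ages_cl = np.clip(ages, table.age_min, table.age_max)
        base = table.interp_many(u, ages_cl)
        lift = spec.effect_psych if wave != "pretest" else 0.0
        psych = np.clip(base + lift + rng.normal(0.0, noise_sd, size=n), 0.0, 10.0)
        shift = spec.effect_log_odds if wave != "pretest" else 0.0
        flags = {}
        for b, w in weights.items():
            t = w.b_intercept + w.b_psych * psych + w.b_psych_age * psych * ages_cl + shift
            p = expit(t)
            flags[b] = (rng.random(n) < p).astype(int)
        items = item_responses_from_psych(
            psych, battery, reliability=spec.reliability, rng=rng
        )
        # emit integer raw response levels (11-point items: level == coded value)
        raw_items = np.clip(np.round(items), 0, 10).astype(int)
        mask = observed[wave]
        df = pd.DataFrame(
            {
                "student_id": student_id[mask],
                "wave": wave,
                "age_months": ages[mask],
                "classroom_id": classroom_id[mask],
                "school_id": school_id[mask],
                "gender": gender[mask],
                "hispanic": hispanic[mask],
                "race": race[mask],
            }
        )
        for j, item_id in enumerate(battery.item_ids):
            df[item_id] = raw_items[mask, j]
        for b in weights:
            df[b] = flags[b][mask]
        # generator transparency: the latent percentile and the realized
        # (pre-item-noise) psych driving the behavior draws
        df["latent_percentile"] = u[mask]
        df["psych_true"] = psych[mask]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# -- survey I/O ---------------------------------------------------------------


def write_survey(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a survey table as CSV with the seed embedded in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV (comment lines ignored, empty fields as missing)."""
    return pd.read_csv(path, comment="#")
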