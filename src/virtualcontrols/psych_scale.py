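"""Scoring of psychosocial survey items onto the 0–10 protective scale.

Student surveys carry a battery of ordered-response items tapping four
constructs: beliefs about the consequences of use, intentions to avoid use,
normative beliefs about peer use, and ease of refusing offers.  Each item is
coded so that 10 is the most theoretically desirable (protective) response
and 0 the least; the per-student *psych score* is the arithmetic mean of the
coded items.  Higher psych scores indicate lower substance-use risk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONSTRUCTS",
    "CodingError",
    "ItemSpec",
    "ItemBattery",
    "PsychScore",
    "code_item",
    "compute_psych_score",
    "cronbach_alpha",
    "score_survey",
]

CONSTRUCTS = frozenset(
    {"belief_consequences", "intention_avoid", "normative_belief", "refusal_ease"}
)


class CodingError(ValueError):
    """Raised when a raw response cannot be coded for its item."""


@dataclass(frozen=True)
class ItemSpec:
    """One survey item: an ordered response scale mapped linearly onto [0, 10].

    Parameters
    ----------
    item_id:
        Unique identifier, used as the survey column name.
    construct:
        One of ``CONSTRUCTS``.
    n_response_levels:
        Number of ordered response options (>= 2).
    desirable_high:
        True when the highest raw level is the most desirable response
        (codes to 10).  False reverses the order before mapping, so the
        lowest raw level codes to 10.
    """

    item_id: str
    construct: str
    n_response_levels: int = 11
    desirable_high: bool = True

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(
                f"unknown construct {self.construct!r}; expected one of {sorted(CONSTRUCTS)}"
            )
        if self.n_response_levels < 2:
            raise ValueError("n_response_levels must be >= 2")


def code_item(raw_response: float | None, spec: ItemSpec) -> float:
    """Map an ordered raw response level onto the 0–10 desirability scale.

    The ordered levels ``0 .. n-1`` are mapped linearly onto [0, 10]; the
    most desirable level codes to exactly 10.0 and the least desirable to
    exactly 0.0.  Missing responses (None or NaN) pass through as NaN.
    """
    if raw_response is None:
        return math.nan
    raw = float(raw_response)
    if math.isnan(raw):
        return math.nan
    n = spec.n_response_levels
    if not raw.is_integer() or not 0 <= raw <= n - 1:
        raise CodingError(
            f"item {spec.item_id!r}: raw response {raw_response!r} outside levels 0..{n - 1}"
        )
    level = raw if spec.desirable_high else (n - 1) - raw
    return 10.0 * level / (n - 1)


def _default_items() -> tuple[ItemSpec, ...]:
    # 13 items: 3 beliefs, 3 intentions, 4 normative beliefs, 3 refusal ease,
    # each on an 11-point (0-10) response format.
    counts = {
        "belief_consequences": 3,
        "intention_avoid": 3,
        "normative_belief": 4,
        "refusal_ease": 3,
    }
    prefixes = {
        "belief_consequences": "belief",
        "intention_avoid": "intent",
        "normative_belief": "norm",
        "refusal_ease": "refuse",
    }
    items = []
    for construct, k in counts.items():
        for i in range(1, k + 1):
            items.append(
                ItemSpec(
                    item_id=f"{prefixes[construct]}_{i}",
                    construct=construct,
                    n_response_levels=11,
                    desirable_high=True,
                )
            )
    return tuple(items)


@dataclass(frozen=True)
class ItemBattery:
    """An ordered collection of items averaged into one psych score."""

    items: tuple[ItemSpec, ...] = field(default_factory=_default_items)
    min_items_required: int = 7

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        if not 1 <= self.min_items_required <= len(self.items):
            raise ValueError("min_items_required must be in 1..len(items)")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def default(cls) -> "ItemBattery":
        """The default 13-item battery (3+3+4+3 items, 11 levels each)."""
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemBattery":
        """Load a battery from a JSON config file.

        Expected shape::

            {"min_items_required": 7,
             "items": [{"item_id": ..., "construct": ...,
                        "n_response_levels": 11, "desirable_high": true}, ...]}
        """
        cfg = json.loads(Path(path).read_text())
        items = tuple(ItemSpec(**spec) for spec in cfg["items"])
        return cls(items=items, min_items_required=cfg.get("min_items_required", 7))

    def to_json(self, path: str | Path) -> None:
        cfg = {
            "min_items_required": self.min_items_required,
            "items": [
                {
                    "item_id": it.item_id,
                    "construct": it.construct,
                    "n_response_levels": it.n_response_levels,
                    "desirable_high": it.desirable_high,
                }
                for it in self.items
            ],
        }
        Path(path).write_text(json.dumps(cfg, indent=2))


@dataclass(frozen=True)
class PsychScore:
    """A single student-wave psych score (NaN value when unscoreable)."""

    value: float
    n_items_used: int

    @property
    def missing(self) -> bool:
        return math.isnan(self.value)


def compute_psych_score(
    coded_items: Sequence[float], battery: ItemBattery
) -> PsychScore:
    """Average coded items into one psych score.

    Items must align positionally with ``battery.items``.  The score is the
    arithmetic mean of non-missing coded values; when fewer than
    ``battery.min_items_required`` items are present the score is flagged
    missing (NaN), never coerced to zero.
    """
    arr = np.asarray(coded_items, dtype=float)
    if arr.shape != (len(battery),):
        raise ValueError(
            f"expected {len(battery)} coded items, got shape {arr.shape}"
        )
    present = ~np.isnan(arr)
    vals = arr[present]
    if vals.size and (vals.min() < 0 or vals.max() > 10):
        raise ValueError("coded item values must lie in [0, 10]")
    n_used = int(present.sum())
    if n_used < battery.min_items_required:
        return PsychScore(value=math.nan, n_items_used=n_used)
    return PsychScore(value=float(vals.mean()), n_items_used=n_used)


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha for a records × items matrix of coded values.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    using sample (ddof=1) variances over complete records only.

    Raises
    ------
    ValueError
        If fewer than 2 items or 3 complete records, or if the total-score
        variance is zero (alpha undefined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("need >= 3 complete records")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_survey(
    df: pd.DataFrame, battery: ItemBattery | None = None
) -> pd.Series:
    """Score every row of a survey table, returning a psych-score Series.

    ``df`` must contain one column per battery item (raw response levels;
    NaN for missing).  Vectorized equivalent of per-row
    :func:`compute_psych_score` after :func:`code_item`.
    """
    battery = battery or ItemBattery.default()
    missing_cols = [c for c in battery.item_ids if c not in df.columns]
    if missing_cols:
        raise KeyError(f"survey is missing item columns: {missing_cols}")
    coded = np.empty((len(df), len(battery)), dtype=float)
    for j, spec in enumerate(battery.items):
        raw = df[spec.item_id].to_numpy(dtype=float)
        n = spec.n_response_levels
        ok = np.isnan(raw) | ((raw >= 0) & (raw <= n - 1) & (raw == np.floor(raw)))
        if not ok.all():
            bad = raw[~ok][0]
            raise CodingError(
                f"item {spec.item_id!r}: raw response {bad!r} outside levels 0..{n - 1}"
            )
        level = raw if spec.desirable_high else (n - 1) - raw
        coded[:, j] = 10.0 * level / (n - 1)
    n_used = (~np.isnan(coded)).sum(axis=1)
    sums = np.nansum(coded, axis=1)
    score = np.divide(sums, n_used, out=np.full(len(df), np.nan), where=n_used > 0)
    score[n_used < battery.min_items_required] = np.nan
    return pd.Series(score, index=df.index, name="psych")
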