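"""Age × percentile normative psych-score table.

The normative model describes how psych scores are distributed across
adolescence (ages 120–240 months) in a large pooled cross-sectional sample:
for each percentile of the psych-score distribution, the score's dependence
on age is smoothed with a quadratic in age-months.  The resulting table —
one smoothed curve per percentile on a fixed grid — is what treatment cases
are matched against and where a pegged virtual case's later-wave psych
scores are read off.

Scores decline with age at every percentile, fastest in the lower
percentiles; the upper curves are nearly flat and are clamped at the scale
ceiling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "NormPoolRecord",
    "PercentileCurve",
    "NormTable",
    "default_grid",
    "empirical_percentiles",
    "fit_percentile_curves",
    "eval_norm",
    "cumulative_difference",
]

AGE_MIN = 120  # 10 years; no pooled study surveyed younger participants
AGE_MAX = 240  # 20 years

_PCT_ATOL = 1e-9


def default_grid() -> np.ndarray:
    """Default percentile grid: 0.5 to 99.0 in steps of 0.5 (198 values)."""
    return np.arange(1, 199) * 0.5


@dataclass(frozen=True)
class NormPoolRecord:
    """One pooled normative survey: an age in months and a psych score."""

    record_id: str
    age_months: int
    psych: float


@dataclass(frozen=True)
class PercentileCurve:
    """Quadratic psych(age) = a*age**2 + b*age + c, clamped to [0, 10]."""

    percentile: float
    a: float
    b: float
    c: float

    def evaluate(self, age_months: float) -> float:
        raw = self.a * age_months**2 + self.b * age_months + self.c
        return float(np.clip(raw, 0.0, 10.0))


class NormTable:
    """Smoothed normative psych scores on a percentile × age-month grid.

    Built from per-percentile quadratic coefficients.  Evaluated values are
    clamped to [0, 10] and made non-crossing by re-sorting each monthly age
    column in percentile order, so that at every age the psych score is
    non-decreasing in percentile — a coherent ordering the matching step
    relies on.
    """

    def __init__(
        self,
        percentiles: Sequence[float],
        coefficients: np.ndarray,
        age_min: int = AGE_MIN,
        age_max: int = AGE_MAX,
    ) -> None:
        pct = np.asarray(percentiles, dtype=float)
        coef = np.asarray(coefficients, dtype=float)
        if pct.ndim != 1 or pct.size == 0:
            raise ValueError("percentiles must be a non-empty 1-D sequence")
        if np.any(np.diff(pct) <= 0):
            raise ValueError("percentile grid must be strictly increasing")
        if np.any((pct <= 0) | (pct >= 100)):
            raise ValueError("percentiles must lie in (0, 100)")
        if coef.shape != (pct.size, 3):
            raise ValueError(f"coefficients must have shape ({pct.size}, 3)")
        if not (age_min < age_max):
            raise ValueError("age_min must be below age_max")
        self.percentiles = pct
        self.coefficients = coef
        self.age_min = int(age_min)
        self.age_max = int(age_max)
        self.ages = np.arange(self.age_min, self.age_max + 1)
        raw = (
            coef[:, [0]] * self.ages.astype(float) ** 2
            + coef[:, [1]] * self.ages
            + coef[:, [2]]
        )
        # clamp, then enforce non-crossing by sorting each age column
        self.grid = np.sort(np.clip(raw, 0.0, 10.0), axis=0)

    # -- indexing -----------------------------------------------------------

    @property
    def n_cells(self) -> int:
        """Number of (percentile × monthly age) cells in the table."""
        return int(self.percentiles.size * self.ages.size)

    def _age_index(self, age_months: int) -> int:
        age = int(age_months)
        if age != age_months:
            raise ValueError(f"age_months must be integral, got {age_months!r}")
        if not self.age_min <= age <= self.age_max:
            raise ValueError(
                f"age {age} months outside table range [{self.age_min}, {self.age_max}]"
            )
        return age - self.age_min

    def _pct_index(self, percentile: float) -> int:
        i = int(np.searchsorted(self.percentiles, percentile))
        for j in (i - 1, i):
            if 0 <= j < self.percentiles.size and abs(
                self.percentiles[j] - percentile
            ) <= _PCT_ATOL:
                return j
        raise ValueError(f"percentile {percentile} is not on the table grid")

    # -- evaluation ---------------------------------------------------------

    def eval(self, percentile: float, age_months: int) -> float:
        """Smoothed, non-crossing, clamped psych score at one grid cell."""
        return float(self.grid[self._pct_index(percentile), self._age_index(age_months)])

    def column(self, age_months: int) -> np.ndarray:
        """All grid percentile values at one age (ascending in percentile)."""
        return self.grid[:, self._age_index(age_months)]

    def cumulative_difference(
        self, percentile: float, age_from: int, age_to: int
    ) -> float:
        """Change in the smoothed psych score from ``age_from`` to ``age_to``."""
        return self.eval(percentile, age_to) - self.eval(percentile, age_from)

    def interp_many(self, latent_percentiles: np.ndarray, age_months: np.ndarray) -> np.ndarray:
        """Vectorized evaluation at arbitrary (continuous) percentiles.

        Linearly interpolates the grid in the percentile direction, clamping
        latent percentiles beyond the grid ends to the end curves.  Used by
        the synthetic-data generator; matching itself is grid-restricted.
        """
        u = np.asarray(latent_percentiles, dtype=float)
        ages = np.asarray(age_months)
        idx_age = ages - self.age_min
        if np.any((idx_age < 0) | (idx_age > self.age_max - self.age_min)):
            raise ValueError("age_months outside table range")
        cols = self.grid[:, idx_age]  # (P, n)
        p = self.percentiles
        u_cl = np.clip(u, p[0], p[-1])
        hi = np.clip(np.searchsorted(p, u_cl), 1, p.size - 1)
        lo = hi - 1
        w = (u_cl - p[lo]) / (p[hi] - p[lo])
        rows = np.arange(u.size)
        return (1.0 - w) * cols[lo, rows] + w * cols[hi, rows]

    # -- serialization ------------------------------------------------------

    def curves(self) -> list[PercentileCurve]:
        return [
            PercentileCurve(float(p), *map(float, abc))
            for p, abc in zip(self.percentiles, self.coefficients)
        ]

    def to_curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "a": self.coefficients[:, 0],
                "b": self.coefficients[:, 1],
                "c": self.coefficients[:, 2],
            }
        )

    def save_curves(self, path: str | Path) -> None:
        """Write the curve-form table (percentile, a, b, c) as CSV.

        Coefficients are written with 17 significant digits so a read-back
        table evaluates bit-identically.
        """
        df = self.to_curves_frame()
        with open(path, "w") as fh:
            fh.write(f"# age_range={self.age_min},{self.age_max}\n")
            df.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def load_curves(cls, path: str | Path) -> "NormTable":
        return cls.from_curves_text(Path(path).read_text())

    @classmethod
    def from_curves_text(cls, text: str) -> "NormTable":
        age_min, age_max = AGE_MIN, AGE_MAX
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                if "age_range=" in line:
                    lo, hi = line.split("age_range=")[1].split(",")
                    age_min, age_max = int(lo), int(hi)
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), float_precision="round_trip")
        return cls(
            percentiles=df["percentile"].to_numpy(),
            coefficients=df[["a", "b", "c"]].to_numpy(),
            age_min=age_min,
            age_max=age_max,
        )

    def save_grid(self, path: str | Path) -> None:
        """Write the expanded grid (percentile, age_months, psych) as CSV."""
        pct = np.repeat(self.percentiles, self.ages.size)
        age = np.tile(self.ages, self.percentiles.size)
        pd.DataFrame(
            {"percentile": pct, "age_months": age, "psych": self.grid.ravel()}
        ).to_csv(path, index=False, float_format="%.17g")


# -- building the table from a normative pool --------------------------------


def _pool_frame(pool: pd.DataFrame | Iterable[NormPoolRecord]) -> pd.DataFrame:
    if isinstance(pool, pd.DataFrame):
        df = pool
    else:
        df = pd.DataFrame(
            [(r.record_id, r.age_months, r.psych) for r in pool],
            columns=["record_id", "age_months", "psych"],
        )
    if df.empty:
        raise ValueError("normative pool is empty")
    return df


def empirical_percentiles(
    pool: pd.DataFrame | Iterable[NormPoolRecord],
    grid: np.ndarray | None = None,
    min_records_per_age: int = 20,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> pd.DataFrame:
    """Empirical psych quantiles per age-month at each grid percentile.

    Records outside [age_min, age_max] are excluded before computation.
    Age-months with fewer than ``min_records_per_age`` records are omitted
    (the quadratic smoothing covers them).  Quantiles use the linear
    interpolation definition.

    Returns a DataFrame indexed by age_months with one column per grid
    percentile.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    df = _pool_frame(pool)
    df = df[(df["age_months"] >= age_min) & (df["age_months"] <= age_max)]
    if df.empty:
        raise ValueError("no pool records within the age range")
    rows = {}
    for age, sub in df.groupby("age_months"):
        vals = sub["psych"].dropna().to_numpy()
        if vals.size >= min_records_per_age:
            rows[int(age)] = np.quantile(vals, grid / 100.0)
    if not rows:
        raise ValueError(
            f"every age-month has fewer than {min_records_per_age} records"
        )
    out = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    return out.sort_index()


def fit_percentile_curves(
    cells: pd.DataFrame,
    grid: np.ndarray | None = None,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> NormTable:
    """Fit one quadratic-in-age curve per percentile by ordinary least squares.

    ``cells`` is the output of :func:`empirical_percentiles` (age-month index,
    percentile columns).  Each percentile needs values at >= 3 distinct ages.
    """
    grid = (
        np.asarray(cells.columns, dtype=float)
        if grid is None
        else np.asarray(grid, dtype=float)
    )
    ages = cells.index.to_numpy(dtype=float)
    coefs = np.empty((grid.size, 3))
    for j, pct in enumerate(grid):
        col = cells[pct] if pct in cells.columns else cells.iloc[:, j]
        mask = ~np.isnan(col.to_numpy(dtype=float))
        if np.unique(ages[mask]).size < 3:
            raise ValueError(
                f"percentile {pct}: need >= 3 distinct ages with data to fit a quadratic"
            )
        coefs[j] = np.polyfit(ages[mask], col.to_numpy(dtype=float)[mask], deg=2)
    return NormTable(grid, coefs, age_min=age_min, age_max=age_max)


# -- functional aliases mirroring the table methods ---------------------------


def eval_norm(table: NormTable, percentile: float, age_months: int) -> float:
    """Smoothed, non-crossing, clamped psych score at one table cell."""
    return table.eval(percentile, age_months)


def cumulative_difference(
    table: NormTable, percentile: float, age_from: int, age_to: int
) -> float:
    """eval_norm(age_to) − eval_norm(age_from) at one percentile."""
    return table.cumulative_difference(percentile, age_from, age_to)
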