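"""Age/sex-stratified rates, populations, and direct standardization.

Incidence is held as age- and sex-specific rates per 100,000 person-years
in 5-year age groups; populations as person counts on the same strata.
Expected case counts are ``rate * count / 100,000`` per stratum.  Direct
age standardization weighs the age-specific rates by a fixed standard
population — by default the Segi world standard — so that rates are
comparable across populations with different age structures:

    ASR = sum_a w_a r_a / sum_a w_a    (per 100,000 person-years)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, CoverageError, DomainError

__all__ = [
    "StratifiedRateTable",
    "PopulationTable",
    "StandardPopulation",
    "segi_standard",
    "expected_cases",
    "age_standardize",
]

# Segi (1960) world standard population per 100,000, 5-year groups 0-4 .. 85+.
SEGI_WEIGHTS: tuple[tuple[int, float], ...] = (
    (0, 12000), (5, 10000), (10, 9000), (15, 9000), (20, 8000), (25, 8000),
    (30, 6000), (35, 6000), (40, 6000), (45, 6000), (50, 5000), (55, 4000),
    (60, 4000), (65, 3000), (70, 2000), (75, 1000), (80, 500), (85, 500),
)


def _age_high_eff(age_high) -> float:
    """Inclusive upper bound of a group; open-ended groups extend to +inf."""
    if age_high is None or (isinstance(age_high, float) and math.isnan(age_high)):
        return math.inf
    return float(age_high)


def _parse_age_high(value):
    if value is None:
        return None
    if isinstance(value, str) and value.strip() in {"+", ""}:
        return None
    v = float(value)
    return None if math.isnan(v) else int(v)


def _format_age_high(value):
    return "+" if value is None or (isinstance(value, float) and math.isnan(value)) else int(value)


class _StratifiedTable:
    """Shared validation for tables keyed by (sex, age_low, age_high)."""

    value_col: str = "value"

    def __init__(self, df: pd.DataFrame):
        required = {"sex", "age_low", "age_high", self.value_col}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["age_high"] = [_parse_age_high(v) for v in df["age_high"]]
        df["age_low"] = df["age_low"].astype(int)
        df[self.value_col] = df[self.value_col].astype(float)
        if (df[self.value_col] < 0).any():
            raise DomainError(f"{self.value_col} must be non-negative")
        for sex, grp in df.groupby("sex"):
            grp = grp.sort_values("age_low")
            highs = [_age_high_eff(h) for h in grp["age_high"]]
            lows = list(grp["age_low"])
            for i in range(len(lows) - 1):
                if highs[i] == math.inf or lows[i + 1] != highs[i] + 1:
                    raise DomainError(
                        f"age groups for sex {sex!r} do not partition the age "
                        f"range: gap or overlap after [{lows[i]}, {highs[i]}]"
                    )
        self.df = df.sort_values(["sex", "age_low"]).reset_index(drop=True)

    @property
    def sexes(self) -> list[str]:
        return sorted(self.df["sex"].unique())

    def strata(self) -> set[tuple]:
        return {
            (r.sex, r.age_low, _age_high_eff(r.age_high))
            for r in self.df.itertuples()
        }

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["age_high"] = [_format_age_high(v) for v in out["age_high"]]
        out.to_csv(path, index=False)


class StratifiedRateTable(_StratifiedTable):
    """Age/sex-specific rates per 100,000 person-years.

    CSV columns: ``sex, age_low, age_high, rate_per_100k`` with ``+`` (or
    blank) in ``age_high`` for the open-ended top group.
    """

    value_col = "rate_per_100k"

    def scale(self, factors: dict[tuple, float]) -> "StratifiedRateTable":
        """Return a copy with each stratum rate multiplied by its factor."""
        df = self.df.copy()
        keys = list(zip(df["sex"], df["age_low"]))
        df[self.value_col] = [
            r * factors.get(k, 1.0) for k, r in zip(keys, df[self.value_col])
        ]
        return StratifiedRateTable(df)


class PopulationTable(_StratifiedTable):
    """Age/sex-specific person counts (CSV columns sex, age_low, age_high, count)."""

    value_col = "count"


@dataclass(frozen=True)
class StandardPopulation:
    """A standard population: weight (persons per 100,000) per 5-year group."""

    name: str
    weights: tuple[tuple[int, float], ...]  # (age_low, weight), ascending

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.weights)
        if abs(total - 100_000) > 1e-6:
            raise DomainError(
                f"standard population weights must sum to 100,000, got {total}"
            )

    @classmethod
    def from_csv(cls, path, name: str = "custom") -> "StandardPopulation":
        df = pd.read_csv(path)
        return cls(name, tuple(zip(df["age_low"].astype(int), df["weight"].astype(float))))


def segi_standard() -> StandardPopulation:
    """The canonical Segi world standard population."""
    return StandardPopulation("segi", SEGI_WEIGHTS)


def expected_cases(
    rates: StratifiedRateTable, pop: PopulationTable
) -> pd.DataFrame:
    """Expected annual case counts per stratum: ``rate * count / 100,000``.

    Returns a DataFrame with one row per stratum (sex, age_low, age_high,
    rate_per_100k, count, cases).  Raises :class:`AlignmentError` if the
    two tables do not share identical strata.
    """
    missing = rates.strata() ^ pop.strata()
    if missing:
        raise AlignmentError(
            "rate and population tables do not share strata; mismatched: "
            + ", ".join(sorted(map(str, missing)))
        )
    merged = rates.df.merge(
        pop.df, on=["sex", "age_low", "age_high"], how="inner"
    )
    merged["cases"] = merged["rate_per_100k"] * merged["count"] / 100_000.0
    return merged


def total_cases_by_sex(case_table: pd.DataFrame) -> pd.Series:
    """Sum an :func:`expected_cases` table to totals per sex."""
    return case_table.groupby("sex")["cases"].sum()


def age_standardize(
    rates: StratifiedRateTable,
    std: StandardPopulation | None = None,
    zero_fill: bool = False,
) -> dict[str, float]:
    """Directly age-standardized rate per sex, per 100,000 person-years.

    Each standard age group is matched to the rate-table group containing
    its lower bound (so a table topping out at 80+ absorbs the standard's
    80-84 and 85+ weights).  A standard group not covered by the table
    raises :class:`CoverageError` unless ``zero_fill`` is set, in which
    case it contributes a zero rate.
    """
    std = std or segi_standard()
    out: dict[str, float] = {}
    for sex in rates.sexes:
        sub = rates.df[rates.df["sex"] == sex]
        lows = sub["age_low"].to_numpy()
        highs = np.array([_age_high_eff(h) for h in sub["age_high"]])
        vals = sub["rate_per_100k"].to_numpy()
        num = den = 0.0
        for age_low, w in std.weights:
            hit = (lows <= age_low) & (age_low <= highs)
            if not hit.any():
                if not zero_fill:
                    raise CoverageError(
                        f"rate table for sex {sex!r} does not cover standard "
                        f"age group starting at {age_low}"
                    )
                rate = 0.0
            else:
                rate = float(vals[hit][0])
            num += w * rate
            den += w
        out[sex] = num / den  # rates are already per 100,000
    return out
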