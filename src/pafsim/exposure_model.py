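"""Stratified consumption distributions and their discretization.

Dietary surveys report consumption as a mean and standard deviation of
g/day per sex and (broad) age group.  To combine such a summary with a
log-linear risk function we posit a non-negative distribution family for
intake — gamma by default, matched by the method of moments
(``k = mean^2/sd^2``, ``theta = sd^2/mean``) — and discretize it on a
uniform dose grid (default 20 g/day).  The population-average relative
risk of a stratum is then

    E[RR] = sum_i p_i * exp(beta * x_i)

over category prevalences ``p_i`` and representative doses ``x_i``.  For
the gamma family this quantity has the closed form of the moment
generating function, ``(1 - beta*theta)**(-k)``, which serves as an
independent check on the discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError
from .risk_model import DEFAULT_STEP_G_DAY, LogLinearRiskFunction

__all__ = [
    "ExposureDistribution",
    "ExposureCategories",
    "discretize",
    "mean_rr",
    "transform_exposure",
    "assign_to_age_group",
]

FAMILIES = ("gamma", "truncated_normal", "point_mass")


@dataclass(frozen=True)
class ExposureDistribution:
    """Per-stratum consumption summary: mean/SD of g/day plus a family.

    For ``gamma`` the mean and SD parameterize the distribution by the
    method of moments.  For ``truncated_normal`` they are the location and
    scale of the underlying normal, truncated at zero and renormalized.
    ``point_mass`` places all mass at ``mean`` and requires ``sd == 0``.
    """

    sex: str
    age_low: int
    age_high: int  # inclusive; open-ended groups use a large sentinel
    mean: float
    sd: float
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DomainError(
                f"unknown exposure family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.mean < 0 or self.sd < 0:
            raise DomainError(
                f"mean and sd must be non-negative, got mean={self.mean}, sd={self.sd}"
            )
        if self.family == "point_mass" and self.sd != 0:
            raise DomainError("point_mass family requires sd = 0")
        if self.family != "point_mass" and self.sd == 0:
            raise DomainError(
                f"{self.family} family with sd = 0; use family='point_mass'"
            )
        if self.family == "gamma" and self.mean <= 0:
            raise DomainError("gamma family requires mean > 0")

    @property
    def stratum(self) -> tuple[str, int, int]:
        return (self.sex, self.age_low, self.age_high)

    def frozen_dist(self):
        """The scipy frozen distribution for non-degenerate families."""
        if self.family == "gamma":
            k = (self.mean / self.sd) ** 2
            theta = self.sd ** 2 / self.mean
            return stats.gamma(k, scale=theta)
        if self.family == "truncated_normal":
            a = (0.0 - self.mean) / self.sd
            return stats.truncnorm(a, np.inf, loc=self.mean, scale=self.sd)
        raise DomainError("point_mass has no continuous distribution")


@dataclass(frozen=True)
class ExposureCategories:
    """A discretized exposure distribution on a uniform dose grid.

    ``bin_edges`` are the left edges 0, step, 2*step, ... of each category
    (the last category is unbounded above); ``midpoints`` are the
    representative doses; ``prevalences`` sum to one.
    """

    bin_edges: np.ndarray
    midpoints: np.ndarray
    prevalences: np.ndarray
    step: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        prev = np.asarray(self.prevalences, dtype=float)
        mids = np.asarray(self.midpoints, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "prevalences", prev)
        object.__setattr__(self, "midpoints", mids)
        if not (len(edges) == len(prev) == len(mids)):
            raise DomainError("edges, midpoints and prevalences must align")
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise DomainError("bin edges must start at 0 and increase strictly")
        if np.any(prev < -1e-12):
            raise DomainError("prevalences must be non-negative")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise DomainError(f"prevalences must sum to 1, got {prev.sum()!r}")


def _tail_mean_gamma(dist: ExposureDistribution, q: float) -> float:
    # E[X | X > q] = mean * S_{k+1}(q) / S_k(q) for gamma(k, theta)
    k = (dist.mean / dist.sd) ** 2
    theta = dist.sd ** 2 / dist.mean
    num = stats.gamma.sf(q, k + 1, scale=theta)
    den = stats.gamma.sf(q, k, scale=theta)
    if den <= 0:
        return q
    return dist.mean * num / den


def _tail_mean_truncnorm(dist: ExposureDistribution, q: float) -> float:
    # conditioning a zero-truncated normal on X > q >= 0 re-truncates at q
    a = (q - dist.mean) / dist.sd
    return float(stats.truncnorm.mean(a, np.inf, loc=dist.mean, scale=dist.sd))


def discretize(
    dist: ExposureDistribution,
    step: float = DEFAULT_STEP_G_DAY,
    upper_quantile: float = 0.999,
) -> ExposureCategories:
    """Bin a consumption distribution into uniform dose categories.

    Bins are ``[0, step), [step, 2*step), ...`` out to the distribution's
    ``upper_quantile`` quantile; the final bin absorbs the remaining tail
    mass and uses the conditional tail mean as its representative dose,
    which keeps the discretization honest under an exponentially growing
    risk function.  Interior bins use their centers.
    """
    if step <= 0:
        raise DomainError(f"step must be positive, got {step}")
    if not (0.99 <= upper_quantile < 1):
        raise DomainError(
            f"upper_quantile must lie in [0.99, 1), got {upper_quantile}"
        )

    if dist.family == "point_mass":
        n = int(math.floor(dist.mean / step)) + 1
        edges = np.arange(n, dtype=float) * step
        prev = np.zeros(n)
        prev[-1] = 1.0
        mids = edges + step / 2.0
        mids[-1] = dist.mean
        return ExposureCategories(edges, mids, prev, step)

    frozen = dist.frozen_dist()
    upper = float(frozen.ppf(upper_quantile))
    n = max(1, int(math.ceil(upper / step)))
    edges = np.arange(n, dtype=float) * step
    cdf = frozen.cdf(np.append(edges, np.inf))
    prev = np.diff(cdf)
    prev = np.clip(prev, 0.0, None)
    prev /= prev.sum()
    mids = edges + step / 2.0
    tail_lo = edges[-1]
    if dist.family == "gamma":
        mids[-1] = _tail_mean_gamma(dist, tail_lo)
    else:
        mids[-1] = _tail_mean_truncnorm(dist, tail_lo)
    return ExposureCategories(edges, mids, prev, step)


def mean_rr(cats: ExposureCategories, rf: LogLinearRiskFunction) -> float:
    """Population-average relative risk, ``sum_i p_i exp(beta x_i)``.

    Equals 1 when ``beta = 0`` and is >= 1 whenever ``beta >= 0`` because
    every representative dose is non-negative.
    """
    return float(np.sum(cats.prevalences * np.exp(rf.beta * cats.midpoints)))


def transform_exposure(dist: ExposureDistribution, transform) -> ExposureDistribution:
    """Apply a counterfactual transform to a stratum distribution.

    ``transform`` is ``"zero"`` (eliminate consumption), a scale factor in
    [0, 1] (proportional reduction), ``"identity"``/``None``, or a
    replacement :class:`ExposureDistribution` (target distribution set).
    """
    if transform is None or transform == "identity":
        return dist
    if transform == "zero":
        return replace(dist, mean=0.0, sd=0.0, family="point_mass")
    if isinstance(transform, ExposureDistribution):
        return replace(
            transform, sex=dist.sex, age_low=dist.age_low, age_high=dist.age_high
        )
    try:
        c = float(transform)
    except (TypeError, ValueError):
        raise DomainError(f"invalid exposure transform {transform!r}") from None
    if not (0.0 <= c <= 1.0):
        raise DomainError(f"scale factor must lie in [0, 1], got {c}")
    if c == 0.0:
        return replace(dist, mean=0.0, sd=0.0, family="point_mass")
    return replace(dist, mean=dist.mean * c, sd=dist.sd * c)


def assign_to_age_group(
    exposures: Sequence[ExposureDistribution], sex: str, age_low: int
) -> ExposureDistribution:
    """Pick the exposure stratum covering a (finer) demographic age group.

    Survey strata are broad (e.g. 0-14, 15-44, 45-54, 55-64) while
    incidence and population tables use 5-year groups extending past the
    surveyed range.  A finer group is assigned to the stratum containing
    its lower bound; groups above the surveyed range inherit the oldest
    stratum and groups below it inherit the youngest.
    """
    same_sex = sorted(
        (e for e in exposures if e.sex == sex), key=lambda e: e.age_low
    )
    if not same_sex:
        raise DomainError(f"no exposure strata for sex {sex!r}")
    for e in same_sex:
        if e.age_low <= age_low <= e.age_high:
            return e
    if age_low > same_sex[-1].age_high:
        return same_sex[-1]
    return same_sex[0]
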