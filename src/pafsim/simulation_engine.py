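"""Reference vs counterfactual scenario runs and PAF computation.

The engine treats the observed incidence of each sex/age stratum as the
product of a baseline (zero-exposure) rate and the stratum's
population-average relative risk under the observed consumption
distribution:

    r_obs = r0 * E[RR | observed exposure]   =>   r0 = r_obs / E[RR]

An intervention scenario transforms the exposure distribution (to zero
for a pure PAF, or a partial reduction for a potential impact fraction)
and re-applies the risk function:

    r_int = r0 * E[RR | transformed exposure]

Cases are aggregated over strata per sex, incidence is directly
standardized to the Segi world standard, and the attributable fraction is
the relative case reduction, PAF = (cases_ref - cases_int) / cases_ref.
With zero counterfactual exposure and a single stratum this reduces to
the textbook formula PAF = 1 - 1/E[RR].  Sensitivity runs repeat the
whole pipeline with the risk function calibrated to the lower and upper
confidence bounds of the relative risk.

The engine is deterministic; all randomness lives in the synthetic-data
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .demography import (
    PopulationTable,
    StandardPopulation,
    StratifiedRateTable,
    age_standardize,
    expected_cases,
    segi_standard,
)
from .errors import DomainError
from .exposure_model import (
    ExposureDistribution,
    assign_to_age_group,
    discretize,
    mean_rr,
    transform_exposure,
)
from .risk_model import (
    LogLinearRiskFunction,
    RelativeRiskSpec,
    fit_loglinear,
    round_half_up,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "calibrate_baseline",
    "run_scenario",
    "paf_from_counts",
    "format_percent",
    "sensitivity_run",
    "apply_latency",
]


@dataclass(frozen=True)
class Scenario:
    """A counterfactual exposure scenario.

    ``exposure_transform`` is ``"identity"`` (reference), ``"zero"``
    (eliminate consumption), a scale factor in [0, 1], or a target
    :class:`ExposureDistribution`.  ``latency_years = 0`` means the
    exposure change takes effect immediately, reducing the model to a pure
    PAF calculation on a single year.
    """

    name: str = "intervention"
    exposure_transform: object = "zero"
    year: int = 2010
    latency_years: int = 0

    def __post_init__(self) -> None:
        if self.latency_years < 0:
            raise DomainError(
                f"latency_years must be non-negative, got {self.latency_years}"
            )
        t = self.exposure_transform
        if isinstance(t, (int, float)) and not isinstance(t, bool):
            if not (0.0 <= float(t) <= 1.0):
                raise DomainError(f"scale factor must lie in [0, 1], got {t}")
        elif not (t in ("identity", "zero") or isinstance(t, ExposureDistribution)):
            raise DomainError(f"invalid exposure transform {t!r}")


@dataclass
class ScenarioResult:
    """Aggregated output of one scenario run.

    ``by_sex`` has one row per sex with reference/intervention expected
    cases, Segi-standardized rates, avoided cases and the PAF (optionally
    bracketed by sensitivity bounds).  ``strata`` keeps the per-stratum
    detail (observed rate, mean RR, calibrated baseline, intervention
    rate).  ``calibration`` records the risk-function constants.
    """

    scenario: Scenario
    by_sex: pd.DataFrame
    strata: pd.DataFrame
    calibration: dict

    @property
    def paf(self) -> dict[str, float]:
        return self.by_sex["paf"].to_dict()


def calibrate_baseline(observed_rate: float, pop_mean_rr: float) -> float:
    """Baseline (zero-exposure) rate such that re-applying the observed
    exposure reproduces the observed rate exactly: ``r0 = r_obs / E[RR]``."""
    if pop_mean_rr <= 0:
        raise DomainError(
            f"population mean RR must be positive, got {pop_mean_rr}"
        )
    if observed_rate < 0:
        raise DomainError(f"observed rate must be non-negative, got {observed_rate}")
    return observed_rate / pop_mean_rr


def paf_from_counts(reference_cases: float, intervention_cases: float) -> float:
    """Attributable fraction from aggregated case counts."""
    if reference_cases <= 0:
        raise DomainError(
            "PAF undefined: reference case count must be positive, got "
            f"{reference_cases}"
        )
    if not (0 <= intervention_cases <= reference_cases):
        raise DomainError(
            "intervention cases must lie in [0, reference cases], got "
            f"{intervention_cases} vs {reference_cases}"
        )
    return (reference_cases - intervention_cases) / reference_cases


def format_percent(fraction: float) -> int:
    """Integer percent, ties rounded up (table display convention)."""
    return int(round_half_up(fraction * 100.0))


def run_scenario(
    exposures: Sequence[ExposureDistribution],
    risk_function: LogLinearRiskFunction,
    rates: StratifiedRateTable,
    pop: PopulationTable,
    scenario: Scenario,
    std: StandardPopulation | None = None,
    upper_quantile: float = 0.999,
) -> ScenarioResult:
    """Run one reference-vs-intervention comparison on a single year.

    For every stratum of the incidence table the covering exposure
    stratum is discretized, the baseline rate calibrated, the scenario's
    exposure transform applied, and the intervention rate recomputed.
    Results are aggregated to expected cases and age-standardized rates
    per sex.
    """
    std = std or segi_standard()
    rows = []
    factors: dict[tuple, float] = {}
    for r in rates.df.itertuples():
        exp_dist = assign_to_age_group(exposures, r.sex, int(r.age_low))
        cats_ref = discretize(exp_dist, risk_function.step, upper_quantile)
        mrr_ref = mean_rr(cats_ref, risk_function)
        r0 = calibrate_baseline(r.rate_per_100k, mrr_ref)
        if scenario.exposure_transform == "identity":
            mrr_int = mrr_ref  # bitwise identical reference run
        else:
            t_dist = transform_exposure(exp_dist, scenario.exposure_transform)
            cats_int = discretize(t_dist, risk_function.step, upper_quantile)
            mrr_int = mean_rr(cats_int, risk_function)
        rate_int = r0 * mrr_int
        factors[(r.sex, int(r.age_low))] = (
            rate_int / r.rate_per_100k if r.rate_per_100k > 0 else 1.0
        )
        rows.append(
            {
                "sex": r.sex,
                "age_low": int(r.age_low),
                "age_high": r.age_high,
                "observed_rate": r.rate_per_100k,
                "mean_rr_reference": mrr_ref,
                "baseline_rate": r0,
                "mean_rr_intervention": mrr_int,
                "intervention_rate": rate_int,
            }
        )
    strata = pd.DataFrame(rows)

    rates_int = rates.scale(factors)
    cases_ref = expected_cases(rates, pop)
    cases_int = expected_cases(rates_int, pop)
    asr_ref = age_standardize(rates, std, zero_fill=True)
    asr_int = age_standardize(rates_int, std, zero_fill=True)

    per_stratum_avoided = (
        cases_ref.set_index(["sex", "age_low"])["cases"]
        - cases_int.set_index(["sex", "age_low"])["cases"]
    )
    strata = strata.merge(
        per_stratum_avoided.rename("avoided_cases").reset_index(),
        on=["sex", "age_low"],
    )

    by_sex_rows = []
    for sex in rates.sexes:
        ref = cases_ref.loc[cases_ref["sex"] == sex, "cases"].sum()
        inter = cases_int.loc[cases_int["sex"] == sex, "cases"].sum()
        by_sex_rows.append(
            {
                "sex": sex,
                "reference_cases": ref,
                "intervention_cases": inter,
                "avoided_cases": ref - inter,
                "paf": paf_from_counts(ref, inter) if ref > 0 else 0.0,
                "reference_asr": asr_ref[sex],
                "intervention_asr": asr_int[sex],
            }
        )
    by_sex = pd.DataFrame(by_sex_rows).set_index("sex")

    calibration = {
        "risk_factor": risk_function.risk_factor,
        "beta_per_g_day": risk_function.beta,
        "intercept": risk_function.intercept,
        "reference_dose_g_day": risk_function.reference_dose,
        "step_g_day": risk_function.step,
        "mean_rr_by_stratum": {
            f"{row['sex']}:{row['age_low']}": row["mean_rr_reference"]
            for row in rows
        },
    }
    return ScenarioResult(scenario, by_sex, strata, calibration)


def sensitivity_run(
    exposures: Sequence[ExposureDistribution],
    rr_spec: RelativeRiskSpec,
    rates: StratifiedRateTable,
    pop: PopulationTable,
    scenario: Scenario,
    std: StandardPopulation | None = None,
    step: float | None = None,
    upper_quantile: float = 0.999,
) -> dict[str, ScenarioResult]:
    """Three full scenario runs at the lower/central/upper RR bounds.

    Returns ``{"lower": ..., "central": ..., "upper": ...}``; the central
    result's ``by_sex`` gains ``paf_lower``/``paf_upper`` and
    ``intervention_cases_lower``/``_upper`` columns.  A higher RR gives a
    higher PAF and fewer intervention cases, so the lower case count pairs
    with the upper PAF bound.
    """
    results: dict[str, ScenarioResult] = {}
    for which in ("lower", "central", "upper"):
        kwargs = {} if step is None else {"step": step}
        rf = fit_loglinear(rr_spec, which, **kwargs)
        results[which] = run_scenario(
            exposures, rf, rates, pop, scenario, std, upper_quantile
        )
    central = results["central"].by_sex
    central["paf_lower"] = results["lower"].by_sex["paf"]
    central["paf_upper"] = results["upper"].by_sex["paf"]
    central["intervention_cases_lower"] = results["upper"].by_sex["intervention_cases"]
    central["intervention_cases_upper"] = results["lower"].by_sex["intervention_cases"]
    return results


def apply_latency(result_stream: pd.DataFrame, latency_years: int) -> pd.DataFrame:
    """Delay an intervention's effect in a multi-year result stream.

    ``result_stream`` has columns ``year``, ``reference`` and
    ``intervention`` (any per-year quantity).  For the first
    ``latency_years`` years the intervention value is replaced by the
    reference value; latency 0 returns an identical copy, which is the
    configuration used for a pure PAF.
    """
    if latency_years < 0:
        raise DomainError(f"latency must be non-negative, got {latency_years}")
    out = result_stream.sort_values("year").reset_index(drop=True).copy()
    n = min(latency_years, len(out))
    out.loc[: n - 1, "intervention"] = out.loc[: n - 1, "reference"]
    return out
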